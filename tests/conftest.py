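"""Shared fixtures: small cohorts for unit tests and the Monte-Carlo study
runs (10 seeds, n=200 patients, 24x24x12 grid) shared by the acceptance
checks."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle module

from htpipe.cohort import (
    CohortConfig,
    clinical_frame,
    generate_cohort,
    null_prevalences,
)
from htpipe.features import extract_cohort
from htpipe.modeling import RFSpec, SmoteSpec, SplitSpec, train_and_evaluate
from htpipe.selection import LassoSpec, fuse_and_reselect, lasso_rank, screen_clinical

#: problem size of the Monte-Carlo studies (cohort size as in the reference
#: protocol; grid scaled down from the 32x32x16 default for tractability)
MC_GRID = (24, 24, 12)
MC_N = 200
MC_SEEDS = tuple(range(10))


@pytest.fixture(scope="session")
def small_cohort():
    """12 patients on a tiny grid for fast structural checks."""
    return generate_cohort(CohortConfig(n_patients=12, grid_shape=(16, 16, 8), seed=7))


@pytest.fixture(scope="session")
def one_patient():
    """One default-grid patient (32x32x16, 1.8x1.8x4.0 mm voxels)."""
    return generate_cohort(CohortConfig(n_patients=2, seed=3))[0]


def study_tables(cohort_cfg: CohortConfig):
    """Generate a cohort and return (radiomics table, clinical table, labels)."""
    patients = generate_cohort(cohort_cfg)
    table = extract_cohort(patients)
    y = table.pop("HT").to_numpy()
    clinical = clinical_frame([p.clinical for p in patients])
    clinical.index = table.index
    return table, clinical, y


def model_aucs(table, clinical, y, seed, models=("clinical", "abnormal", "all", "combined")):
    """Select features and report each requested model's validation AUC."""
    lasso = LassoSpec(seed=seed)
    split = SplitSpec(seed=seed + 1)
    smote = SmoteSpec(seed=seed + 2)
    rf = RFSpec(seed=seed + 3)

    def _auc(X, cols):
        return train_and_evaluate(X, y, cols, split, smote, rf).mean["AUC"]

    aucs = {}
    sel_all = None
    if {"abnormal", "all", "combined"} & set(models):
        sel_all = lasso_rank(table, y, lasso)
    if "clinical" in models:
        aucs["clinical"] = _auc(clinical, list(clinical.columns))
    if "abnormal" in models:
        abn_cols = [c for c in table.columns if "_normal_" not in c]
        aucs["abnormal"] = _auc(table, lasso_rank(table[abn_cols], y, lasso).names)
    if "all" in models:
        aucs["all"] = _auc(table, sel_all.names)
    if "combined" in models:
        screen = screen_clinical(clinical, y)
        fusion = fuse_and_reselect(sel_all, screen.selected, table, clinical, y, lasso)
        aucs["combined"] = _auc(pd.concat([table, clinical], axis=1), fusion.names)
    return aucs


@pytest.fixture(scope="session")
def null_study_aucs():
    """Validation AUCs of all four models on 10 zero-effect cohorts
    (imaging effect sizes 0 and no clinical group contrast)."""
    rows = []
    for seed in MC_SEEDS:
        cfg = CohortConfig(
            n_patients=MC_N, grid_shape=MC_GRID, seed=seed,
            effect_size_abnormal=0.0, effect_size_ht_abnormal=0.0,
            effect_size_ht_normal=0.0, prevalences=null_prevalences(),
        )
        rows.append(model_aucs(*study_tables(cfg), seed=seed))
    return pd.DataFrame(rows, index=list(MC_SEEDS))


@pytest.fixture(scope="session")
def effect_tables():
    """Extracted feature tables of 10 default-effect cohorts (lesion effect
    2.0, HT effect 1.0 abnormal / 0.5 contralateral), keyed by seed."""
    return {
        seed: study_tables(CohortConfig(n_patients=MC_N, grid_shape=MC_GRID, seed=seed))
        for seed in MC_SEEDS
    }


@pytest.fixture(scope="session")
def effect_study_aucs(effect_tables):
    """Validation AUCs of the two radiomics models per default-effect seed."""
    rows = []
    for seed in MC_SEEDS:
        table, clinical, y = effect_tables[seed]
        rows.append(model_aucs(table, clinical, y, seed=seed, models=("abnormal", "all")))
    return pd.DataFrame(rows, index=list(MC_SEEDS))
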