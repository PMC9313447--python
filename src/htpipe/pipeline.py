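"""End-to-end orchestration: simulate → ROI → extract → select → train → report.

A single :class:`RunConfig` (one global seed) determines every artifact.
The global seed fans out to per-stage seeds by fixed offsets so one number
reproduces a whole study while stages stay independently re-runnable.
Stage outputs are cached in the output directory keyed by the config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from htpipe.cohort import (
    SEQUENCES,
    CohortConfig,
    clinical_frame,
    generate_cohort,
    null_prevalences,
)
from htpipe.features import DiscretizationSpec, GLCMSpec, extract_cohort
from htpipe.modeling import (
    METRIC_NAMES,
    RFSpec,
    SmoteSpec,
    SplitSpec,
    run_model_suite,
)
from htpipe.selection import LassoSpec, fuse_and_reselect, lasso_rank, screen_clinical

log = logging.getLogger("htpipe")

ALL_CONDITIONS = ("clinical", "abnormal", "all", "combined", "single_sequence", "sweep", "roc")


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    disc: DiscretizationSpec = field(default_factory=DiscretizationSpec)
    glcm: GLCMSpec = field(default_factory=GLCMSpec)
    lasso: LassoSpec = field(default_factory=LassoSpec)
    split: SplitSpec = field(default_factory=SplitSpec)
    smote: SmoteSpec = field(default_factory=SmoteSpec)
    rf: RFSpec = field(default_factory=RFSpec)
    conditions: tuple[str, ...] = ALL_CONDITIONS
    out_dir: str = "results/run"
    seed: int = 0
    pooled_smote: bool = False
    sweep_ks: tuple[int, ...] = tuple(range(5, 21))
    roc_seeds: tuple[int, ...] = (100, 200, 300)

    def __post_init__(self) -> None:
        unknown = set(self.conditions) - set(ALL_CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions: {sorted(unknown)}")
        # fan the global seed out to the stages by fixed offsets
        self.cohort.seed = self.seed
        self.lasso.seed = self.seed
        self.split.seed = self.seed + 1
        self.smote.seed = self.seed + 2
        self.rf.seed = self.seed + 3

    def to_dict(self) -> dict:
        d = asdict(self)
        d["glcm"]["directions"] = [list(x) for x in d["glcm"]["directions"]]
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def default_study_config(seed: int = 0, out_dir: str = "results/run") -> RunConfig:
    """The default synthetic study: 200 patients at lesion effect 2.0."""
    return RunConfig(cohort=CohortConfig(n_patients=200, seed=seed), out_dir=out_dir, seed=seed)


def null_study_config(seed: int = 0, out_dir: str = "results/null") -> RunConfig:
    """Zero-effect study: no imaging effects and no clinical group contrast."""
    cohort = CohortConfig(
        n_patients=200,
        effect_size_abnormal=0.0,
        effect_size_ht_abnormal=0.0,
        effect_size_ht_normal=0.0,
        prevalences=null_prevalences(),
        seed=seed,
    )
    return RunConfig(cohort=cohort, out_dir=out_dir, seed=seed)


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for key, cls in (
        ("cohort", CohortConfig), ("disc", DiscretizationSpec), ("glcm", GLCMSpec),
        ("lasso", LassoSpec), ("split", SplitSpec), ("smote", SmoteSpec), ("rf", RFSpec),
    ):
        if key in raw:
            kwargs[key] = cls(**raw.pop(key))
    kwargs.update(raw)
    if "conditions" in kwargs:
        kwargs["conditions"] = tuple(kwargs["conditions"])
    return RunConfig(**kwargs)


def _needs_radiomics(conditions) -> bool:
    return any(c != "clinical" for c in conditions)


def compute_selections(features: pd.DataFrame, clinical: pd.DataFrame, labels, config: RunConfig) -> dict:
    """All feature selections the requested conditions require."""
    selections: dict = {}
    rank_k = max(config.lasso.top_k, max(config.sweep_ks) if "sweep" in config.conditions else 0)
    spec = LassoSpec(config.lasso.alpha, config.lasso.standardize, config.lasso.max_iter,
                     config.lasso.tol, rank_k, config.lasso.seed)

    all_sel = lasso_rank(features, labels, spec, stage="radiomics")
    selections["all"] = all_sel.names

    abnormal_cols = [c for c in features.columns if "_normal_" not in c]
    selections["abnormal"] = lasso_rank(
        features[abnormal_cols], labels, spec, stage="abnormal-only"
    ).names

    screen = screen_clinical(clinical, labels)
    selections["screen"] = screen
    top_sel = lasso_rank(features, labels, config.lasso, stage="radiomics")
    fusion = fuse_and_reselect(top_sel, screen.selected, features, clinical, labels, config.lasso)
    selections["fusion"] = fusion.names

    if "single_sequence" in config.conditions:
        single = {}
        for seq in SEQUENCES:
            cols = [c for c in features.columns if c.startswith(f"{seq}_")]
            if not cols:
                log.warning("sequence %s missing from feature table; ablation skipped", seq)
                continue
            single[seq] = lasso_rank(features[cols], labels, config.lasso, stage=f"single-{seq}").names
        selections["single_sequence"] = single
    return selections


def run_all(config: RunConfig) -> dict:
    """Execute the configured study end to end; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest_path = out / "manifest.json"
    cached = {}
    if manifest_path.exists():
        prev = json.loads(manifest_path.read_text())
        if prev.get("config_hash") == chash:
            cached = prev.get("outputs", {})

    manifest = {
        "config_hash": chash,
        "config": config.to_dict(),
        "seed": config.seed,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": {},
    }

    def _stage(name: str, path: Path, compute, reader, writer):
        if name in cached and Path(cached[name]).exists():
            log.info("stage %s: cached", name)
            manifest["outputs"][name] = cached[name]
            return reader(cached[name])
        log.info("stage %s: computing", name)
        value = compute()
        writer(value, path)
        manifest["outputs"][name] = str(path)
        return value

    log.info("simulate: n=%d grid=%s", config.cohort.n_patients, config.cohort.grid_shape)
    patients = generate_cohort(config.cohort)
    labels = np.array([p.ht_label for p in patients])
    clinical = clinical_frame([p.clinical for p in patients])
    clinical.index = pd.Index([p.patient_id for p in patients], name="patient_id")

    clin_path = out / "clinical.csv"
    clinical.assign(HT=labels).to_csv(clin_path)
    manifest["outputs"]["clinical"] = str(clin_path)

    results: dict = {}
    if _needs_radiomics(config.conditions):
        features_with_labels = _stage(
            "features",
            out / "features.csv",
            lambda: extract_cohort(patients, config.disc, config.glcm),
            lambda p: pd.read_csv(p, index_col="patient_id"),
            lambda df, p: df.to_csv(p),
        )
        features = features_with_labels.drop(columns=["HT"])

        selections = compute_selections(features, clinical, labels, config)
        sel_path = out / "selection.json"
        sel_payload = {
            "all": selections["all"],
            "abnormal": selections["abnormal"],
            "fusion": selections["fusion"],
            "clinical_pair": list(selections["screen"].selected),
            "single_sequence": selections.get("single_sequence", {}),
        }
        sel_path.write_text(json.dumps(sel_payload, indent=2))
        manifest["outputs"]["selection"] = str(sel_path)

        suite = run_model_suite(
            features, clinical, labels, selections,
            config.split, config.smote, config.rf,
            roc_seeds=config.roc_seeds if "roc" in config.conditions else (),
            sweep_ks=config.sweep_ks if "sweep" in config.conditions else (),
            n_model_features=config.lasso.top_k,
            pooled_smote=config.pooled_smote,
        )
        results.update(suite)

        for key, fname in (("models", "models.csv"), ("single_sequence", "single_sequence.csv"),
                           ("sweep", "sweep.csv")):
            df = suite.get(key)
            if df is not None and len(df):
                df.to_csv(out / fname)
                manifest["outputs"][key] = str(out / fname)
        for seed, per_model in suite.get("roc", {}).items():
            rows = []
            for model, folds in per_model.items():
                for k, (fpr, tpr) in enumerate(folds):
                    rows.extend({"model": model, "fold": k, "fpr": f, "tpr": t}
                                for f, t in zip(fpr, tpr))
            roc_path = out / f"roc_seed{seed}.csv"
            pd.DataFrame(rows).to_csv(roc_path, index=False)
            manifest["outputs"][f"roc_seed{seed}"] = str(roc_path)
    else:
        # clinical-only study: no radiomics extraction performed
        from htpipe.modeling import train_and_evaluate

        res = train_and_evaluate(clinical, labels, list(clinical.columns),
                                 config.split, config.smote, config.rf,
                                 pooled_smote=config.pooled_smote)
        df = pd.DataFrame({
            "Clinical": {f"{m}_{s}": (res.mean if s == "mean" else res.std)[m]
                         for m in METRIC_NAMES for s in ("mean", "std")}
        }).T
        df.to_csv(out / "models.csv")
        manifest["outputs"]["models"] = str(out / "models.csv")
        results["models"] = df

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    results["manifest"] = manifest
    return results


def report(results: dict) -> str:
    """Human-readable Markdown summary with mean ± std formatting."""
    tables = {k: results.get(k) for k in ("models", "single_sequence", "sweep")}
    if all(t is None or len(t) == 0 for t in tables.values()):
        raise ValueError("no completed condition to report")
    lines = ["# HT prediction study report", ""]
    titles = {"models": "Model comparison", "single_sequence": "Single-sequence models",
              "sweep": "Feature-count sweep"}
    for key, df in tables.items():
        if df is None or not len(df):
            continue
        lines.append(f"## {titles[key]}")
        lines.append("")
        lines.append("| Model | " + " | ".join(METRIC_NAMES) + " |")
        lines.append("|" + "---|" * (len(METRIC_NAMES) + 1))
        for name, row in df.iterrows():
            cells = [f"{row[f'{m}_mean']:.3f} ± {row[f'{m}_std']:.3f}" for m in METRIC_NAMES]
            lines.append(f"| {name} | " + " | ".join(cells) + " |")
        lines.append("")
    return "\n".join(lines)
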