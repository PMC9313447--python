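#!/usr/bin/env python
"""Ablations: single-sequence models, the feature-count sweep (k = 5…20),
and ROC curves under seeds 100/200/300.

Writes results/study/single_sequence.csv, sweep.csv and roc_seed*.csv.
"""

import json

import pandas as pd

from htpipe.modeling import RFSpec, SmoteSpec, SplitSpec, run_model_suite
from htpipe.pipeline import report
from study_config import SEED, STUDY_DIR


def main() -> None:
    sel_path = STUDY_DIR / "selection.json"
    if not sel_path.exists():
        raise SystemExit("run 03_select_features.py first")
    table = pd.read_csv(STUDY_DIR / "features.csv", index_col="patient_id")
    y = table.pop("HT").to_numpy()
    clinical = pd.read_csv(STUDY_DIR / "cohort" / "clinical.csv",
                           index_col="patient_id").drop(columns=["HT"])
    selections = json.loads(sel_path.read_text())

    suite = run_model_suite(
        table, clinical, y, selections,
        SplitSpec(seed=SEED + 1), SmoteSpec(seed=SEED + 2), RFSpec(seed=SEED + 3),
    )
    suite["single_sequence"].to_csv(STUDY_DIR / "single_sequence.csv")
    suite["sweep"].to_csv(STUDY_DIR / "sweep.csv")
    for seed, per_model in suite["roc"].items():
        rows = []
        for model, folds in per_model.items():
            for k, (fpr, tpr) in enumerate(folds):
                rows.extend({"model": model, "fold": k, "fpr": f, "tpr": t}
                            for f, t in zip(fpr, tpr))
        pd.DataFrame(rows).to_csv(STUDY_DIR / f"roc_seed{seed}.csv", index=False)

    print(report({"single_sequence": suite["single_sequence"], "sweep": suite["sweep"]}))
    best = suite["single_sequence"]["AUC_mean"].idxmax()
    print(f"best single sequence: {best} "
          f"(AUC {suite['single_sequence'].loc[best, 'AUC_mean']:.3f})")


if __name__ == "__main__":
    main()
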