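#!/usr/bin/env python
"""Train and validate the four HT prediction models.

Splits the cohort 69/31 % (the 49/22 proportion), SMOTE-balances each
training fold, trains five random forests (70 trees, depth 5) per condition
by stratified 5-fold CV, and scores each fold model on the held-out
validation cohort.  Writes results/study/models.csv and report.md.
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
        roc_seeds=(), sweep_ks=(),
    )
    suite["models"].to_csv(STUDY_DIR / "models.csv")
    md = report({"models": suite["models"]})
    (STUDY_DIR / "report.md").write_text(md)
    print(md)


if __name__ == "__main__":
    main()
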