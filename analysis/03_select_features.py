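#!/usr/bin/env python
"""LASSO feature ranking + clinical screening + fusion reselection.

Ranks the 5400 radiomics features by |LASSO coefficient| (alpha = 1e-6,
standardized columns) for the All-ROIs and Abnormal-ROIs conditions, screens
the 16 clinical factors (Fisher exact / rank-sum + univariate AUC), and
reruns LASSO on the fused 14 + 2 columns.  Writes results/study/selection.json
and clinical_screen.csv.
"""

import json

import pandas as pd

from htpipe.selection import LassoSpec, fuse_and_reselect, lasso_rank, screen_clinical
from study_config import SEED, STUDY_DIR


def main() -> None:
    feats = STUDY_DIR / "features.csv"
    if not feats.exists():
        raise SystemExit("run 02_extract_features.py first")
    table = pd.read_csv(feats, index_col="patient_id")
    y = table.pop("HT").to_numpy()
    clinical = pd.read_csv(STUDY_DIR / "cohort" / "clinical.csv",
                           index_col="patient_id").drop(columns=["HT"])

    spec20 = LassoSpec(top_k=20, seed=SEED)
    sel_all = lasso_rank(table, y, spec20)
    abn = table[[c for c in table.columns if "_normal_" not in c]]
    sel_abn = lasso_rank(abn, y, spec20)

    screen = screen_clinical(clinical, y)
    top14 = lasso_rank(table, y, LassoSpec(seed=SEED))
    fusion = fuse_and_reselect(top14, screen.selected, table, clinical, y)

    single = {
        seq: lasso_rank(table[[c for c in table.columns if c.startswith(f"{seq}_")]],
                        y, LassoSpec(seed=SEED)).names
        for seq in ("ADC", "CBF", "CBV", "MTT", "TTP")
    }

    payload = {
        "all": sel_all.names, "abnormal": sel_abn.names, "fusion": fusion.names,
        "clinical_pair": list(screen.selected), "single_sequence": single,
    }
    (STUDY_DIR / "selection.json").write_text(json.dumps(payload, indent=2))
    pd.DataFrame({"p_value": screen.p_values, "auc": screen.aucs}).to_csv(
        STUDY_DIR / "clinical_screen.csv")

    n_normal = sum("_normal_" in n for n in sel_all.names[:14])
    print(f"All-ROIs top-14: {n_normal} features come from normal-side ROIs")
    print("  top 5:", ", ".join(sel_all.names[:5]))
    print(f"clinical pair selected: {screen.selected} "
          f"(AUC {screen.aucs[screen.selected[0]]:.3f} / {screen.aucs[screen.selected[1]]:.3f})")
    print(f"fusion kept {len(fusion.names)} of 16 columns")


if __name__ == "__main__":
    main()
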