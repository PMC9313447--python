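"""Feature selection: LASSO ranking, clinical screening, fusion reselection.

The radiomics stages rank features by the magnitude of L1-penalized linear
regression coefficients on the 0/1 HT label (squared loss, coordinate
descent).  At the default penalty ``alpha = 1e-6`` the fit is effectively a
minimum-norm least-squares solution and selection amounts to magnitude
ranking of near-OLS coefficients on standardized columns; the penalty is
exposed as configuration.

Clinical screening tests each binary factor with a one-sided Fisher exact
test (in the direction of the observed association) and age with a two-sided
rank-sum test, evaluates each factor as a single-feature classifier by
orientation-free AUC ``max(a, 1 - a)``, and selects the two factors with the
highest AUC among those with p below the threshold — falling back to the
top-2 AUC overall when fewer than two pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LinearRegression
from sklearn.metrics import roc_auc_score


@dataclass
class LassoSpec:
    alpha: float = 1e-6
    standardize: bool = True
    max_iter: int = 2000
    tol: float = 1e-4
    top_k: int = 14
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclass
class SelectionResult:
    names: list[str]
    coefficients: np.ndarray  # ordered by descending |coef|
    stage: str
    spec: LassoSpec
    converged: bool = True
    n_nonzero: int = 0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.names) != len(self.coefficients):
            raise ValueError("names and coefficients must align")


@dataclass
class ClinicalScreenResult:
    p_values: "pd.Series"
    aucs: "pd.Series"
    tests: dict[str, str]
    selected: tuple[str, str]
    p_threshold: float = 0.05


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0  # constant columns become all-zero (never selected)
    return (X - mu) / sd


def lasso_rank(
    feature_table: pd.DataFrame,
    labels: np.ndarray,
    spec: LassoSpec | None = None,
    stage: str = "radiomics",
) -> SelectionResult:
    """Rank columns by |LASSO coefficient| and keep the top ``spec.top_k``.

    Ties in magnitude are broken by column name (ascending) so the selection
    is fully deterministic for a given table.
    """
    spec = spec or LassoSpec()
    y = np.asarray(labels, dtype=float)
    if feature_table.isna().any().any():
        raise ValueError("feature table contains NaN columns")
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    X = feature_table.to_numpy(dtype=float)
    if spec.standardize:
        X = _standardize(X)

    converged = True
    if spec.alpha == 0:
        coef = LinearRegression().fit(X, y).coef_
    else:
        model = Lasso(alpha=spec.alpha, max_iter=spec.max_iter, tol=spec.tol)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            model.fit(X, y)
            converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
        coef = model.coef_

    cols = np.asarray(feature_table.columns)
    order = np.lexsort((cols, -np.abs(coef)))  # |coef| desc, then name asc
    order = order[: spec.top_k]
    return SelectionResult(
        names=[str(cols[k]) for k in order],
        coefficients=coef[order],
        stage=stage,
        spec=spec,
        converged=converged,
        n_nonzero=int(np.sum(coef != 0)),
    )


def _factor_auc(values: np.ndarray, y: np.ndarray) -> float:
    """Orientation-free single-feature AUC."""
    if len(np.unique(values)) < 2:
        return 0.5
    a = roc_auc_score(y, values)
    return float(max(a, 1.0 - a))


def screen_clinical(
    clinical_table: pd.DataFrame,
    labels: np.ndarray,
    p_threshold: float = 0.05,
) -> ClinicalScreenResult:
    """Screen the 16 clinical factors; select the best-classifying pair."""
    y = np.asarray(labels, dtype=int)
    pvals, aucs, tests = {}, {}, {}
    for col in clinical_table.columns:
        v = clinical_table[col].to_numpy(dtype=float)
        if len(np.unique(v)) < 2:  # constant column: uninformative by fiat
            pvals[col], aucs[col], tests[col] = 1.0, 0.5, "constant"
            continue
        if set(np.unique(v)) <= {0.0, 1.0}:
            a = int(((v == 1) & (y == 1)).sum())
            b = int(((v == 0) & (y == 1)).sum())
            c = int(((v == 1) & (y == 0)).sum())
            d = int(((v == 0) & (y == 0)).sum())
            p = min(
                stats.fisher_exact([[a, b], [c, d]], alternative="greater").pvalue,
                stats.fisher_exact([[a, b], [c, d]], alternative="less").pvalue,
            )
            tests[col] = "fisher-one-sided"
        else:
            p = stats.mannwhitneyu(v[y == 1], v[y == 0], alternative="two-sided").pvalue
            tests[col] = "rank-sum"
        pvals[col] = float(p)
        aucs[col] = _factor_auc(v, y)

    p_series = pd.Series(pvals)
    auc_series = pd.Series(aucs)
    informative = p_series.index[np.array([tests[c] != "constant" for c in p_series.index])]
    passing = [c for c in informative if p_series[c] < p_threshold]
    pool = passing if len(passing) >= 2 else list(informative)
    ranked = sorted(pool, key=lambda c: (-auc_series[c], c))
    selected = tuple(ranked[:2])

    return ClinicalScreenResult(
        p_values=p_series, aucs=auc_series, tests=tests, selected=selected,
        p_threshold=p_threshold,
    )


def fuse_and_reselect(
    radiomics_selection: SelectionResult,
    clinical_pair: tuple[str, str],
    feature_table: pd.DataFrame,
    clinical_table: pd.DataFrame,
    labels: np.ndarray,
    spec: LassoSpec | None = None,
) -> SelectionResult:
    """Second-stage LASSO on selected radiomics columns + the clinical pair.

    Keeps the features with nonzero coefficients, capped at the input size.
    """
    if not radiomics_selection.names:
        raise ValueError("radiomics selection is empty")
    spec = spec or LassoSpec()
    rad = feature_table[radiomics_selection.names]
    clin = clinical_table[list(clinical_pair)]
    if not clin.index.equals(rad.index):
        if len(clin) != len(rad):
            raise ValueError("feature and clinical tables must have one row per patient")
        clin = clin.set_axis(rad.index)  # rows correspond positionally
    dup = set(rad.columns) & set(clin.columns)
    if dup:
        raise ValueError(f"duplicate column names in fusion input: {sorted(dup)}")
    fused = pd.concat([rad, clin], axis=1)

    cap = fused.shape[1]
    inner = LassoSpec(
        alpha=spec.alpha, standardize=spec.standardize, max_iter=spec.max_iter,
        tol=spec.tol, top_k=cap, seed=spec.seed,
    )
    result = lasso_rank(fused, labels, inner, stage="fusion")
    keep = min(result.n_nonzero if result.n_nonzero > 0 else cap, cap)
    return SelectionResult(
        names=result.names[:keep],
        coefficients=result.coefficients[:keep],
        stage="fusion",
        spec=inner,
        converged=result.converged,
        n_nonzero=result.n_nonzero,
    )
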