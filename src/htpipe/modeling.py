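"""Model training and evaluation.

The cohort is split once into a primary (training) cohort and a held-out
validation cohort (defaults reproduce a 49/22 split of 71 patients).  On the
primary cohort the minority (HT) class is rebalanced with SMOTE and five
random forests are trained by stratified five-fold cross-validation; each
fold model is then scored on the untouched validation cohort, and metrics
are reported as mean ± std over the five fold models.

SMOTE is applied *inside* each training fold by default so no synthetic
point is interpolated from samples of the corresponding held-out fold;
``pooled_smote=True`` instead oversamples the whole primary cohort once
before folding (the order some workflows describe, which leaks synthetic
copies across folds and typically inflates in-primary CV scores —
validation-cohort metrics remain honest either way).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

METRIC_NAMES = ("AUC", "ACC", "SEN", "SPEC", "F1")


@dataclass
class SplitSpec:
    n_primary: int | None = None
    n_validation: int | None = None
    train_fraction: float = 49 / 71
    stratified: bool = True
    seed: int = 0


@dataclass
class SmoteSpec:
    k_neighbors: int = 5
    target_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.target_ratio <= 0:
            raise ValueError("target_ratio must be > 0")


@dataclass
class RFSpec:
    n_estimators: int = 70
    max_depth: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_estimators < 1 or self.max_depth < 1:
            raise ValueError("n_estimators and max_depth must be >= 1")


@dataclass
class EvaluationResult:
    """Per-metric mean ± std over the five fold models on the validation cohort."""

    mean: dict[str, float]
    std: dict[str, float]
    per_fold: pd.DataFrame  # folds x metrics
    roc_points: list[tuple[np.ndarray, np.ndarray]]

    def row(self) -> dict[str, str]:
        """Formatted "0.871 ± 0.019"-style row."""
        return {m: f"{self.mean[m]:.3f} ± {self.std[m]:.3f}" for m in METRIC_NAMES}


# ----------------------------------------------------------------------- split
def split_cohort(
    feature_table: pd.DataFrame,
    labels: np.ndarray,
    spec: SplitSpec | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic (seeded) primary/validation index split.

    With explicit sizes unset, the validation size is the complement of
    ``train_fraction`` (49/71 by default).  Stratification allocates the
    validation count per class proportionally (largest remainder), keeping
    at least one sample of each class on both sides.
    """
    spec = spec or SplitSpec()
    y = np.asarray(labels, dtype=int)
    n = len(feature_table)
    if n < 4:
        raise ValueError("cohort too small to split")
    if spec.n_primary is not None and spec.n_validation is not None:
        if spec.n_primary + spec.n_validation != n:
            raise ValueError("n_primary + n_validation must equal the cohort size")
        n_val = spec.n_validation
    else:
        n_val = n - int(round(spec.train_fraction * n))
    n_val = int(np.clip(n_val, 2, n - 2))

    rng = np.random.default_rng(spec.seed)
    classes = np.unique(y)
    if len(classes) < 2:
        if spec.stratified:
            raise ValueError("stratified split requires both classes present")
        perm = rng.permutation(n)
        return np.sort(perm[n_val:]), np.sort(perm[:n_val])

    # proportional validation allocation per class, largest remainder
    quotas = {c: n_val * (y == c).sum() / n for c in classes}
    counts = {c: int(np.floor(q)) for c, q in quotas.items()}
    for c in classes:
        counts[c] = max(1, min(counts[c], int((y == c).sum()) - 1))
    leftovers = sorted(classes, key=lambda c: quotas[c] - np.floor(quotas[c]), reverse=True)
    k = 0
    while sum(counts.values()) < n_val:
        c = leftovers[k % len(leftovers)]
        if counts[c] < (y == c).sum() - 1:
            counts[c] += 1
        k += 1
        if k > 10 * len(classes):
            break

    val_idx = []
    for c in classes:
        members = np.flatnonzero(y == c)
        val_idx.extend(rng.permutation(members)[: counts[c]])
    val_idx = np.sort(np.array(val_idx, dtype=int))
    primary_idx = np.setdiff1d(np.arange(n), val_idx)
    return primary_idx, val_idx


# ----------------------------------------------------------------------- SMOTE
def smote_oversample(
    X_minority: np.ndarray,
    n_majority: int,
    spec: SmoteSpec | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Generate synthetic minority samples by neighbour interpolation.

    Each synthetic point is ``x_i + u * (x_nn - x_i)`` with ``u ~ U(0, 1)``
    and ``x_nn`` one of the ``k`` nearest minority neighbours of a randomly
    chosen minority sample; generation continues until
    ``n_minority + n_synthetic >= target_ratio * n_majority``.  Returns the
    synthetic points only (the majority class is untouched).
    """
    spec = spec or SmoteSpec()
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    X = np.asarray(X_minority, dtype=float)
    n_min = len(X)
    if n_min <= spec.k_neighbors:
        raise ValueError(
            f"minority count {n_min} must exceed k_neighbors={spec.k_neighbors}; use a smaller k"
        )
    n_target = int(np.ceil(spec.target_ratio * n_majority))
    n_new = max(0, n_target - n_min)
    if n_new == 0:
        return np.empty((0, X.shape[1]))

    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=-1)
    np.fill_diagonal(d2, np.inf)
    nn = np.argsort(d2, axis=1, kind="stable")[:, : spec.k_neighbors]

    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, spec.k_neighbors, size=n_new)
    u = rng.random(n_new)
    neighbours = X[nn[base, pick]]
    return X[base] + u[:, None] * (neighbours - X[base])


def _augment(X: np.ndarray, y: np.ndarray, spec: SmoteSpec, rng: np.random.Generator):
    """SMOTE-balance a labelled set (minority = class 1)."""
    Xmin, Xmaj = X[y == 1], X[y == 0]
    if len(Xmin) <= spec.k_neighbors:
        # degrade k rather than fail on very small folds
        spec = SmoteSpec(max(1, len(Xmin) - 1), spec.target_ratio, spec.seed)
    if len(Xmin) < 2:
        return X, y
    synth = smote_oversample(Xmin, len(Xmaj), spec, rng)
    Xa = np.vstack([X, synth])
    ya = np.concatenate([y, np.ones(len(synth), dtype=int)])
    return Xa, ya


# ------------------------------------------------------------------- training
def crossval_train(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    smote_spec: SmoteSpec | None = None,
    rf_spec: RFSpec | None = None,
    folds: int = 5,
    pooled_smote: bool = False,
) -> tuple[list[RandomForestClassifier], pd.DataFrame]:
    """Five-fold stratified CV training of random forests with SMOTE.

    Returns the five fitted models and the in-primary fold metrics
    (evaluated on each held-out fold, averaged downstream).
    """
    smote_spec = smote_spec or SmoteSpec()
    rf_spec = rf_spec or RFSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("primary cohort must contain both classes")
    rng = np.random.default_rng(smote_spec.seed)

    if pooled_smote:  # oversample the whole primary cohort before folding
        X, y = _augment(X, y, smote_spec, rng)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rf_spec.seed)
    models, rows = [], []
    for k, (tr, te) in enumerate(skf.split(X, y)):
        Xtr, ytr = X[tr], y[tr]
        if not pooled_smote:
            Xtr, ytr = _augment(Xtr, ytr, smote_spec, rng)
        model = RandomForestClassifier(
            n_estimators=rf_spec.n_estimators,
            max_depth=rf_spec.max_depth,
            random_state=rf_spec.seed + k,
        )
        model.fit(Xtr, ytr)
        models.append(model)
        rows.append(_score(model, X[te], y[te])[0])
    return models, pd.DataFrame(rows, columns=list(METRIC_NAMES))


def _score(model, X, y) -> tuple[dict[str, float], tuple[np.ndarray, np.ndarray]]:
    prob = model.predict_proba(X)[:, 1]
    pred = (prob >= 0.5).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    sen = tp / (tp + fn) if tp + fn else 0.0
    spec_ = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / len(y)
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    if len(np.unique(y)) < 2 or len(np.unique(prob)) < 2:
        auc = 0.5  # degenerate scores or single-class fold
        fpr, tpr = np.array([0.0, 1.0]), np.array([0.0, 1.0])
    else:
        auc = float(roc_auc_score(y, prob))
        fpr, tpr, _ = roc_curve(y, prob)
    return (
        {"AUC": auc, "ACC": acc, "SEN": sen, "SPEC": spec_, "F1": f1},
        (fpr, tpr),
    )


def evaluate(models: list, X_val: pd.DataFrame | np.ndarray, y_val: np.ndarray) -> EvaluationResult:
    """Score each fold model on the untouched validation cohort."""
    X_val = np.asarray(X_val, dtype=float)
    y_val = np.asarray(y_val, dtype=int)
    if len(np.unique(y_val)) < 2:
        raise ValueError("validation cohort must contain both classes")
    rows, rocs = [], []
    for model in models:
        metrics, roc = _score(model, X_val, y_val)
        rows.append(metrics)
        rocs.append(roc)
    per_fold = pd.DataFrame(rows, columns=list(METRIC_NAMES))
    return EvaluationResult(
        mean={m: float(per_fold[m].mean()) for m in METRIC_NAMES},
        std={m: float(per_fold[m].std(ddof=0)) for m in METRIC_NAMES},
        per_fold=per_fold,
        roc_points=rocs,
    )


def run_model_suite(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    labels: np.ndarray,
    selections: dict,
    split: SplitSpec | None = None,
    smote: SmoteSpec | None = None,
    rf: RFSpec | None = None,
    roc_seeds: tuple[int, ...] = (100, 200, 300),
    sweep_ks: tuple[int, ...] = tuple(range(5, 21)),
    n_model_features: int = 14,
    pooled_smote: bool = False,
) -> dict:
    """Run the full model comparison: four models, single-sequence ablations,
    the feature-count sweep and per-seed ROC curves.

    ``selections`` maps condition names to ranked feature-name lists:
    ``"all"`` (ranked All-ROIs features, at least ``max(sweep_ks)`` long for
    the sweep), ``"abnormal"``, ``"fusion"``, and optionally
    ``"single_sequence"`` (sequence -> names).  The clinical model uses every
    clinical column.
    """
    split = split or SplitSpec()
    smote = smote or SmoteSpec()
    rf = rf or RFSpec()
    y = np.asarray(labels, dtype=int)
    if not clinical.index.equals(features.index):
        if len(clinical) != len(features):
            raise ValueError("feature and clinical tables must have one row per patient")
        clinical = clinical.set_axis(features.index)  # rows correspond positionally
    X = pd.concat([features, clinical], axis=1)

    all_names = list(selections["all"])
    abnormal_names = list(selections["abnormal"])
    leaked = [n for n in abnormal_names if "_normal_" in n]
    if leaked:  # guard: the Abnormal-ROIs condition must never see a mirror ROI
        raise ValueError(f"normal-side features in the abnormal condition: {leaked[:3]}")

    conditions = {
        "Clinical": list(clinical.columns),
        "Abnormal-ROIs": abnormal_names[:n_model_features],
        "All-ROIs": all_names[:n_model_features],
        "Combined": list(selections["fusion"]),
    }

    def _run(columns, seed_offset=0):
        sp = SplitSpec(split.n_primary, split.n_validation, split.train_fraction,
                       split.stratified, split.seed + seed_offset)
        sm = SmoteSpec(smote.k_neighbors, smote.target_ratio, smote.seed + seed_offset)
        rfs = RFSpec(rf.n_estimators, rf.max_depth, rf.seed + seed_offset)
        return train_and_evaluate(X, y, columns, sp, sm, rfs, pooled_smote=pooled_smote)

    def _table(results: dict[str, EvaluationResult]) -> pd.DataFrame:
        rows = {}
        for name, res in results.items():
            row = {}
            for m in METRIC_NAMES:
                row[f"{m}_mean"] = res.mean[m]
                row[f"{m}_std"] = res.std[m]
            rows[name] = row
        return pd.DataFrame(rows).T

    model_results = {name: _run(cols) for name, cols in conditions.items()}

    single_results = {}
    for seq, names in selections.get("single_sequence", {}).items():
        cols = [c for c in names[:n_model_features] if c in X.columns]
        if not cols:
            continue
        single_results[seq] = _run(cols)

    sweep_results = {}
    for k in sweep_ks:
        sweep_results[k] = _run(all_names[: min(k, len(all_names))])

    roc = {}
    for seed in roc_seeds:
        roc[seed] = {
            name: _run(cols, seed_offset=seed).roc_points
            for name, cols in conditions.items()
            if name != "Clinical"
        }

    return {
        "models": _table(model_results),
        "model_results": model_results,
        "single_sequence": _table(single_results) if single_results else pd.DataFrame(),
        "sweep": _table({f"{k}": r for k, r in sweep_results.items()}),
        "roc": roc,
    }


def train_and_evaluate(
    X: pd.DataFrame,
    y: np.ndarray,
    columns: list[str],
    split: SplitSpec | None = None,
    smote: SmoteSpec | None = None,
    rf: RFSpec | None = None,
    pooled_smote: bool = False,
) -> EvaluationResult:
    """Convenience: split, CV-train on ``columns``, evaluate on validation."""
    split = split or SplitSpec()
    pri, val = split_cohort(X, y, split)
    Xs = X[columns]
    models, _ = crossval_train(
        Xs.iloc[pri], np.asarray(y)[pri], smote, rf, pooled_smote=pooled_smote
    )
    return evaluate(models, Xs.iloc[val], np.asarray(y)[val])
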