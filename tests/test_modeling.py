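"""Modeling stage: cohort split, SMOTE, cross-validated training, metric
definitions, and leakage/degeneracy guards."""

import numpy as np
import pandas as pd
import pytest

from htpipe.modeling import (
    EvaluationResult,
    RFSpec,
    SmoteSpec,
    SplitSpec,
    crossval_train,
    evaluate,
    smote_oversample,
    split_cohort,
    train_and_evaluate,
)


class FixedScoreModel:
    """Stub classifier returning predetermined positive-class scores."""

    def __init__(self, scores):
        self.scores = np.asarray(scores, dtype=float)

    def predict_proba(self, X):
        s = self.scores[: len(X)]
        return np.column_stack([1 - s, s])


class TestSplit:
    def test_reference_cohort_sizes(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(71, 3)))
        y = np.array([1] * 11 + [0] * 60)
        pri, val = split_cohort(X, y, SplitSpec(seed=0))
        assert len(pri) == 49 and len(val) == 22
        assert set(pri) | set(val) == set(range(71))
        assert not set(pri) & set(val)
        assert y[val].sum() in (3, 4)  # proportional HT allocation

    def test_same_seed_identical_split(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(50, 2)))
        y = rng.integers(0, 2, 50)
        a = split_cohort(X, y, SplitSpec(seed=3))
        b = split_cohort(X, y, SplitSpec(seed=3))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_single_class_rejected_when_stratified(self):
        X = pd.DataFrame(np.zeros((10, 2)))
        with pytest.raises(ValueError, match="both classes"):
            split_cohort(X, np.zeros(10), SplitSpec(stratified=True))


class TestSmote:
    def test_two_point_minority_interpolates_the_segment(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        synth = smote_oversample(X, n_majority=6, spec=SmoteSpec(k_neighbors=1, seed=0))
        assert len(synth) == 4  # 6 - 2 existing
        # every synthetic point lies on the segment between the two samples
        assert np.allclose(synth[:, 0], synth[:, 1])
        assert (synth >= 0).all() and (synth <= 1).all()

    def test_count_arithmetic(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(8, 4))
        synth = smote_oversample(X, n_majority=40, spec=SmoteSpec(k_neighbors=5, seed=1))
        assert len(synth) == 32

    def test_synthetic_points_inside_minority_bounding_box(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(-2, 5, size=(20, 6))
        synth = smote_oversample(X, n_majority=60, spec=SmoteSpec(seed=2))
        assert (synth >= X.min(axis=0) - 1e-12).all()
        assert (synth <= X.max(axis=0) + 1e-12).all()

    def test_too_few_minority_samples_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError, match="smaller k"):
            smote_oversample(X, n_majority=10, spec=SmoteSpec(k_neighbors=5))


class TestCrossval:
    def _separable(self, n=49, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array(([1] * 10 + [0] * 39))[:n]
        X = rng.normal(size=(n, 3))
        X[:, 0] += 8.0 * y
        return pd.DataFrame(X), y

    def test_linearly_separable_folds_are_perfect(self):
        X, y = self._separable()
        models, fold_metrics = crossval_train(X, y)
        assert len(models) == 5
        assert (fold_metrics["ACC"] == 1.0).all()

    def test_fold_sizes_partition_49(self):
        X, y = self._separable()
        from sklearn.model_selection import StratifiedKFold

        sizes = sorted(len(te) for _, te in StratifiedKFold(5, shuffle=True,
                                                            random_state=0).split(X, y))
        assert sizes == [9, 10, 10, 10, 10]

    def test_same_seeds_identical_predictions(self):
        X, y = self._separable(seed=4)
        probe = np.random.default_rng(9).normal(size=(7, 3))
        a, _ = crossval_train(X, y, SmoteSpec(seed=5), RFSpec(seed=6))
        b, _ = crossval_train(X, y, SmoteSpec(seed=5), RFSpec(seed=6))
        for ma, mb in zip(a, b):
            assert np.array_equal(ma.predict_proba(probe), mb.predict_proba(probe))

    def test_pooled_smote_runs(self):
        X, y = self._separable()
        models, _ = crossval_train(X, y, pooled_smote=True)
        assert len(models) == 5


class TestEvaluate:
    def test_perfectly_ranked_scores(self):
        y = np.array([1, 1, 0, 0])
        res = evaluate([FixedScoreModel([0.9, 0.8, 0.4, 0.2])], np.zeros((4, 1)), y)
        assert res.mean["AUC"] == 1.0 and res.mean["ACC"] == 1.0

    def test_metric_definitions_on_stated_confusion_counts(self):
        """TP=3 FN=1 TN=16 FP=2 -> SEN .75, SPEC .889, ACC .864, F1 .667."""
        y = np.array([1] * 4 + [0] * 18)
        scores = np.array([0.9, 0.8, 0.7, 0.3] + [0.6, 0.55] + [0.1] * 16)
        res = evaluate([FixedScoreModel(scores)], np.zeros((22, 1)), y)
        assert res.mean["SEN"] == pytest.approx(0.75)
        assert res.mean["SPEC"] == pytest.approx(16 / 18, abs=1e-3)
        assert res.mean["ACC"] == pytest.approx(19 / 22, abs=1e-3)
        assert res.mean["F1"] == pytest.approx(2 * 3 / (2 * 3 + 2 + 1), abs=1e-3)

    def test_degenerate_constant_scores_give_auc_half(self):
        y = np.array([1, 0, 1, 0])
        res = evaluate([FixedScoreModel([0.5] * 4)], np.zeros((4, 1)), y)
        assert res.mean["AUC"] == 0.5

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(10)
        y = rng.integers(0, 2, 30)
        s = rng.random(30) * 0.5 + 0.25
        a = evaluate([FixedScoreModel(s)], np.zeros((30, 1)), y)
        b = evaluate([FixedScoreModel(s**3)], np.zeros((30, 1)), y)  # monotone
        assert a.mean["AUC"] == pytest.approx(b.mean["AUC"])

    def test_label_permutation_null(self):
        rng = np.random.default_rng(11)
        X, y = np.zeros((40, 1)), rng.integers(0, 2, 40)
        scores = rng.random(40)
        aucs = []
        for _ in range(20):
            perm = rng.permutation(40)
            aucs.append(evaluate([FixedScoreModel(scores)], X, y[perm]).mean["AUC"])
        assert abs(np.mean(aucs) - 0.5) < 0.15

    def test_row_formatting(self):
        y = np.array([1, 1, 0, 0])
        res = evaluate([FixedScoreModel([0.9, 0.8, 0.4, 0.2])], np.zeros((4, 1)), y)
        assert res.row()["AUC"] == "1.000 ± 0.000"


class TestEndToEnd:
    def test_train_and_evaluate_recovers_planted_signal(self):
        rng = np.random.default_rng(12)
        n = 120
        y = rng.integers(0, 2, n)
        X = pd.DataFrame(rng.normal(size=(n, 6)), columns=[f"f{i}" for i in range(6)])
        X["f0"] += 2.5 * y
        res = train_and_evaluate(X, y, ["f0", "f1"], SplitSpec(seed=1),
                                 SmoteSpec(seed=2), RFSpec(seed=3))
        assert res.mean["AUC"] > 0.85
        assert (res.per_fold.shape == (5, 5))
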