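"""Feature selection: LASSO closed forms and recovery, clinical screening
statistics, and fusion reselection."""

import numpy as np
import pandas as pd
import pytest

from htpipe.selection import (
    LassoSpec,
    fuse_and_reselect,
    lasso_rank,
    screen_clinical,
)


def orthonormal_design(n=60, p=8, seed=0):
    """Centred orthonormal columns (so the intercept does not disturb the
    soft-threshold closed form)."""
    rng = np.random.default_rng(seed)
    M = rng.normal(size=(n, p))
    M -= M.mean(axis=0)
    Q, _ = np.linalg.qr(M)
    return pd.DataFrame(Q, columns=[f"c{i}" for i in range(p)])


class TestLasso:
    def test_orthonormal_design_soft_threshold(self):
        """On an orthonormal design the LASSO solution is the soft-thresholded
        OLS coefficient sign(b) * max(|b| - n*alpha, 0)."""
        Q = orthonormal_design()
        rng = np.random.default_rng(1)
        beta = rng.normal(scale=0.2, size=Q.shape[1])
        y = Q.to_numpy() @ beta
        alpha = 0.002
        spec = LassoSpec(alpha=alpha, standardize=False, tol=1e-12, max_iter=100000,
                         top_k=Q.shape[1])
        res = lasso_rank(Q, y, spec)
        b_ols = Q.to_numpy().T @ y
        expected = np.sign(b_ols) * np.maximum(np.abs(b_ols) - len(Q) * alpha, 0.0)
        got = dict(zip(res.names, res.coefficients))
        for i, col in enumerate(Q.columns):
            assert got[col] == pytest.approx(expected[i], abs=1e-8)

    def test_alpha_zero_matches_least_squares(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
        y = rng.normal(size=40)
        res = lasso_rank(X, y, LassoSpec(alpha=0.0, standardize=False, top_k=5))
        Xc = X.to_numpy() - X.to_numpy().mean(axis=0)
        yc = y - y.mean()
        expected = np.linalg.lstsq(Xc, yc, rcond=None)[0]
        got = dict(zip(res.names, res.coefficients))
        for i, col in enumerate(X.columns):
            assert got[col] == pytest.approx(expected[i], abs=1e-8)

    def test_planted_columns_recovered(self):
        """3 informative columns (standardized effect 1.5) among 100 noise
        columns are ranked top-3 in at least 9 of 10 seeds."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 200
            y = rng.integers(0, 2, n)
            X = rng.normal(size=(n, 103))
            for j in range(3):
                X[:, j] += 1.5 * y
            cols = [f"planted{j}" if j < 3 else f"noise{j}" for j in range(103)]
            res = lasso_rank(pd.DataFrame(X, columns=cols), y, LassoSpec(top_k=3))
            if set(res.names) == {"planted0", "planted1", "planted2"}:
                hits += 1
        assert hits >= 9

    def test_positive_column_scaling_leaves_selection_unchanged(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(50, 10)), columns=[f"f{i}" for i in range(10)])
        y = rng.integers(0, 2, 50).astype(float)
        a = lasso_rank(X, y, LassoSpec(top_k=4))
        X2 = X.copy()
        X2["f3"] = X2["f3"] * 37.0
        b = lasso_rank(X2, y, LassoSpec(top_k=4))
        assert a.names == b.names

    def test_determinism(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(30, 20)), columns=[f"f{i}" for i in range(20)])
        y = rng.integers(0, 2, 30).astype(float)
        assert lasso_rank(X, y).names == lasso_rank(X, y).names

    def test_nan_rejected(self):
        X = pd.DataFrame({"a": [1.0, np.nan, 2.0], "b": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="NaN"):
            lasso_rank(X, np.array([0, 1, 1]))


def reference_cohort_clinical():
    """A clinical table realizing the reference 11/60 2x2 counts exactly."""
    y = np.array([1] * 11 + [0] * 60)

    def col(k_ht, k_noht):
        return np.array([1] * k_ht + [0] * (11 - k_ht) + [1] * k_noht + [0] * (60 - k_noht))

    rng = np.random.default_rng(0)
    table = pd.DataFrame({
        "age": rng.uniform(40, 85, size=71),
        "svs_1": col(11, 37),
        "location_M2": col(4, 35),
        "hypertension": col(7, 47),
        "diabetes": col(4, 13),
    })
    return table, y


class TestClinicalScreen:
    def test_svs1_fisher_p_matches_hypergeometric_tail(self):
        """11/11 vs 37/60 positives: one-sided Fisher p = C(48,11)/C(71,11)
        = 0.0088 (= the hypergeometric tail at the observed table)."""
        table, y = reference_cohort_clinical()
        res = screen_clinical(table, y)
        from math import comb

        expected = comb(48, 11) / comb(71, 11)
        assert res.p_values["svs_1"] == pytest.approx(expected, rel=1e-9)
        assert round(res.p_values["svs_1"], 3) == 0.009

    def test_orientation_free_auc_matches_reported_values(self):
        table, y = reference_cohort_clinical()
        res = screen_clinical(table, y)
        assert res.aucs["svs_1"] == pytest.approx(0.692, abs=0.001)
        assert res.aucs["location_M2"] == pytest.approx(0.610, abs=0.001)

    def test_selected_pair_is_svs1_and_m2(self):
        table, y = reference_cohort_clinical()
        res = screen_clinical(table, y)
        assert set(res.selected) == {"svs_1", "location_M2"}

    def test_factor_identical_to_label_has_auc_one(self):
        y = np.array([0, 1] * 20)
        table = pd.DataFrame({"oracle": y.astype(float), "noise": np.random.default_rng(0).normal(size=40)})
        res = screen_clinical(table, y)
        assert res.aucs["oracle"] == 1.0

    def test_independent_factor_auc_near_half(self):
        rng = np.random.default_rng(5)
        n = 10_000
        y = rng.integers(0, 2, n)
        table = pd.DataFrame({"coin": rng.integers(0, 2, n).astype(float),
                              "other": rng.normal(size=n)})
        res = screen_clinical(table, y)
        assert res.aucs["coin"] == pytest.approx(0.5, abs=0.02)

    def test_constant_column_never_selected(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 60)
        table = pd.DataFrame({
            "flat": np.ones(60),
            "a": rng.normal(size=60),
            "b": rng.integers(0, 2, 60).astype(float),
        })
        res = screen_clinical(table, y)
        assert res.p_values["flat"] == 1.0
        assert res.aucs["flat"] == 0.5
        assert "flat" not in res.selected


class TestFusion:
    def _radiomics(self, seed=7, n=80, p=20):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        X = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"ADC_a_abnormal_firstorder_F{i}" for i in range(p)])
        X.iloc[:, 0] += 1.0 * y
        return X, y

    def test_constant_clinical_pair_contributes_nothing(self):
        X, y = self._radiomics()
        clinical = pd.DataFrame({"c1": np.ones(len(X)), "c2": np.zeros(len(X))})
        sel = lasso_rank(X, y, LassoSpec(top_k=5))
        fused = fuse_and_reselect(sel, ("c1", "c2"), X, clinical, y)
        assert set(fused.names) <= set(sel.names)

    def test_strong_clinical_column_ranks_high(self):
        hits = 0
        for seed in range(10):
            X, y = self._radiomics(seed=seed)
            rng = np.random.default_rng(seed + 100)
            clinical = pd.DataFrame({
                "strong": y + 0.2 * rng.normal(size=len(y)),
                "weak": rng.normal(size=len(y)),
            })
            sel = lasso_rank(X, y, LassoSpec(top_k=5))
            fused = fuse_and_reselect(sel, ("strong", "weak"), X, clinical, y)
            if "strong" in fused.names[:3]:
                hits += 1
        assert hits >= 8

    def test_output_capped_at_input_size(self):
        X, y = self._radiomics()
        rng = np.random.default_rng(8)
        clinical = pd.DataFrame({"c1": rng.integers(0, 2, len(X)).astype(float),
                                 "c2": rng.integers(0, 2, len(X)).astype(float)})
        sel = lasso_rank(X, y, LassoSpec(top_k=14))
        fused = fuse_and_reselect(sel, ("c1", "c2"), X, clinical, y)
        assert len(fused.names) <= 16
        assert fused.stage == "fusion"

    def test_duplicate_columns_rejected(self):
        X, y = self._radiomics()
        clinical = X[[X.columns[0], X.columns[1]]]
        sel = lasso_rank(X, y, LassoSpec(top_k=5))
        with pytest.raises(ValueError, match="duplicate"):
            fuse_and_reselect(sel, tuple(clinical.columns), X, clinical, y)
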