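"""Differential LRT, FDR, correlation, t-test, PCA and set overlaps."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from editome.quantify import EditingMatrix
from editome.stats import (
    adjust_fdr,
    editing_expression_correlation,
    lrt_differential,
    overall_editing_level,
    overlap_sets,
    pca_editing,
    spearman,
    students_t,
)
from _oracles import bh_oracle, lrt_oracle, overlap_oracle, pca_eig_oracle, spearman_oracle

GROUPS = np.array(["a", "a", "b", "b"])


class TestLRT:
    def test_identical_groups_give_null_result(self):
        r = lrt_differential([5, 5, 5, 5], [50, 50, 50, 50], GROUPS)
        assert r.lrt_statistic == pytest.approx(0.0, abs=1e-10)
        assert r.p_value == pytest.approx(1.0)
        assert r.df == 1

    def test_strong_difference_matches_closed_form_oracle(self):
        ed = [2, 3, 20, 22]
        tot = [40, 40, 40, 40]
        r = lrt_differential(ed, tot, GROUPS)
        stat, p = lrt_oracle([2, 3], [40, 40], [20, 22], [40, 40])
        assert r.lrt_statistic == pytest.approx(stat, rel=1e-10)
        assert r.p_value == pytest.approx(p, rel=1e-10)
        assert p < 1e-4

    def test_matches_statsmodels_binomial_glm(self):
        """The closed-form group/pooled MLEs equal a logit-link binomial GLM
        fit with a group factor (the factor saturates the group means)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        for _ in range(5):
            tot = rng.integers(20, 80, size=6)
            ed = rng.binomial(tot, rng.uniform(0.05, 0.5, size=6))
            groups = np.array(["a"] * 3 + ["b"] * 3)
            r = lrt_differential(ed, tot, groups, min_depth=1)
            endog = np.column_stack([ed, tot - ed])
            x_full = sm.add_constant((groups == "b").astype(float))
            full = sm.GLM(endog, x_full, family=sm.families.Binomial()).fit()
            null = sm.GLM(endog, np.ones((6, 1)), family=sm.families.Binomial()).fit()
            assert r.lrt_statistic == pytest.approx(
                2 * (full.llf - null.llf), rel=1e-6, abs=1e-8)

    def test_uncovered_group_skips_test(self):
        r = lrt_differential([1, 2, 3, 4], [30, 30, 5, 5], GROUPS, min_depth=10)
        assert r.skipped is not None
        assert math.isnan(r.p_value)

    def test_three_groups_use_two_df(self):
        g = np.array(["a", "a", "b", "b", "c", "c"])
        r = lrt_differential([2, 3, 9, 8, 15, 14], [40] * 6, g)
        assert r.df == 2
        assert set(r.group_means) == {"a", "b", "c"}


class TestFDR:
    def test_closed_form_example(self):
        np.testing.assert_allclose(adjust_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones(self):
        np.testing.assert_allclose(adjust_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_matches_step_up_oracle_exactly(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 40)).round(4)
            np.testing.assert_array_equal(adjust_fdr(p), bh_oracle(list(p)))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(13)
        p = rng.uniform(size=50)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(adjust_fdr(p), q_sm, rtol=1e-12)

    def test_nan_propagates_and_does_not_count(self):
        q = adjust_fdr([0.01, np.nan, 0.02])
        assert math.isnan(q[1])
        np.testing.assert_allclose([q[0], q[2]], bh_oracle([0.01, 0.02]))

    @given(hst.lists(hst.floats(0, 1), min_size=2, max_size=25),
           hst.randoms(use_true_random=False))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_permutation(self, pvals, rnd):
        idx = list(range(len(pvals)))
        rnd.shuffle(idx)
        q = adjust_fdr(pvals)
        q_perm = adjust_fdr([pvals[i] for i in idx])
        np.testing.assert_allclose([q[i] for i in idx], q_perm, rtol=1e-12)


class TestSpearman:
    def test_monotone(self):
        assert spearman([1, 2, 3], [10, 20, 30])[0] == pytest.approx(1.0)
        assert spearman([1, 2, 3], [30, 20, 10])[0] == pytest.approx(-1.0)

    def test_ties_match_midrank_pearson_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            n = int(rng.integers(5, 30))
            x = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            y = rng.integers(0, 6, size=n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, _ = spearman(x, y)
            assert rho == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_large_n_p_value_matches_scipy(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(22)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        rho, p = spearman(x, y)
        ref = spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_zero_variance_undefined(self):
        rho, p = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(rho) and math.isnan(p)


class TestStudentsT:
    def test_identical_groups(self):
        assert students_t([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_shift_detected(self):
        t, p = students_t([1, 2, 3], [11, 12, 13])
        assert p < 0.01

    def test_antisymmetry(self):
        t1, p1 = students_t([1, 2, 3], [4, 6, 8])
        t2, p2 = students_t([4, 6, 8], [1, 2, 3])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)


def _matrix(levels: np.ndarray, groups=None) -> EditingMatrix:
    sites = [f"s{i}" for i in range(levels.shape[0])]
    samples = [f"c{j}" for j in range(levels.shape[1])]
    lv = pd.DataFrame(levels, index=sites, columns=samples)
    groups = groups or ["g"] * levels.shape[1]
    return EditingMatrix(lv, ~lv.isna(), pd.Series(groups, index=samples))


class TestPCA:
    def test_single_varying_site_captures_all_variance(self):
        lv = np.vstack([np.linspace(0, 1, 6), np.full(6, 0.3), np.full(6, 0.7)])
        res = pca_editing(_matrix(lv))
        assert res.variance_fraction[0] == pytest.approx(1.0, abs=1e-9)

    def test_matches_eigendecomposition_oracle_up_to_sign(self):
        rng = np.random.default_rng(31)
        X = rng.uniform(size=(20, 10))
        res = pca_editing(_matrix(X))
        scores_ref, frac_ref = pca_eig_oracle(X)
        np.testing.assert_allclose(res.variance_fraction,
                                   frac_ref[: res.variance_fraction.size], atol=1e-10)
        for k in range(5):
            a = res.scores.iloc[:, k].to_numpy()
            b = scores_ref[:, k]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_spectral_properties(self):
        rng = np.random.default_rng(32)
        X = rng.uniform(size=(12, 7))
        res = pca_editing(_matrix(X))
        assert res.variance_fraction.sum() <= 1 + 1e-9
        S = res.scores.to_numpy()
        norm = S / np.maximum(np.linalg.norm(S, axis=0), 1e-300)
        off = norm.T @ norm - np.eye(norm.shape[1])
        assert np.abs(off).max() < 1e-8

    def test_masked_cells_are_imputed(self):
        lv = np.array([[0.1, np.nan, 0.3, 0.2], [0.5, 0.6, np.nan, 0.4],
                       [0.2, 0.1, 0.3, 0.25]])
        res = pca_editing(_matrix(lv))
        assert np.isfinite(res.scores.to_numpy()).all()


class TestOverlaps:
    def test_two_sets(self):
        rep = overlap_sets({"x": {"A", "B"}, "y": {"B", "C"}})
        assert rep.count("x", "y") == 1
        assert rep.count("x") == 1 and rep.count("y") == 1
        assert rep.unique == {"x": ["A"], "y": ["C"]}

    def test_identical_sets(self):
        rep = overlap_sets({"x": {1, 2}, "y": {1, 2}})
        assert rep.count("x", "y") == 2
        assert rep.count("x") == 0

    def test_four_random_sets_match_powerset_oracle(self):
        rng = np.random.default_rng(41)
        sets = {n: set(rng.integers(0, 40, size=25).tolist()) for n in "abcd"}
        rep = overlap_sets(sets)
        oracle = overlap_oracle(sets)
        for combo, n in oracle.items():
            assert rep.region_counts.get(combo, 0) == n
        assert rep.shared_at_least[1] == len(set().union(*sets.values()))


def test_des_recovery_with_planted_group_shift():
    """With 100 shifted sites (0.10 vs 0.30) among 1000, the q < 0.05 list
    recovers at least 80% of the shifted sites and keeps the false-positive
    rate among null sites at or below 5%."""
    rng = np.random.default_rng(55)
    groups = np.array(["a"] * 3 + ["b"] * 3)
    pvals, shifted = [], []
    for i in range(1000):
        is_shifted = i < 100
        base = rng.uniform(0.05, 0.4)
        p = np.full(6, base)
        if is_shifted:
            p = np.where(groups == "a", 0.10, 0.30)
        total = np.maximum(1, rng.poisson(50, size=6))
        edited = rng.binomial(total, p)
        pvals.append(lrt_differential(edited, total, groups).p_value)
        shifted.append(is_shifted)
    q = adjust_fdr(pvals)
    shifted = np.array(shifted)
    called = q < 0.05
    assert called[shifted].mean() >= 0.80
    assert called[~shifted].mean() <= 0.05


class TestOverallAndCorrelation:
    def test_mean_levels(self):
        lv = np.array([[0.1, 0.0], [0.3, 0.0]])
        out = overall_editing_level(_matrix(lv))
        assert out["mean_level"].tolist() == [0.2, 0.0]

    def test_monotone_site_expression_pair(self):
        lv = np.array([[0.1, 0.2, 0.3, 0.4, 0.5, 0.6]])
        m = _matrix(lv)
        tpm = pd.DataFrame([[1.0, 2, 3, 4, 5, 6]], index=["gene1"],
                           columns=m.levels.columns)
        (res,) = editing_expression_correlation(m, tpm, {"s0": "gene1"})
        assert res.rho == pytest.approx(1.0)

    def test_constant_level_excluded(self):
        lv = np.array([[0.2] * 6])
        m = _matrix(lv)
        tpm = pd.DataFrame([[1.0, 2, 3, 4, 5, 6]], index=["gene1"],
                           columns=m.levels.columns)
        assert editing_expression_correlation(m, tpm, {"s0": "gene1"}) == []
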