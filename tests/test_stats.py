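"""Rank tests, bootstrap CIs, AUROC effects, BH-FDR."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from somnoscope import (
    auroc,
    auroc_effect,
    benjamini_hochberg,
    bootstrap_median_ci,
    mann_whitney,
    wilcoxon_signed_rank,
)
from somnoscope.stats import classifier_label


class TestMannWhitney:
    def test_complete_separation(self):
        u, _ = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    def test_identical_groups_p_one(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_u_matches_pair_counting(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a = rng.integers(0, 12, size=rng.integers(2, 8)).astype(float)
            b = rng.integers(0, 12, size=rng.integers(2, 8)).astype(float)
            u, _ = mann_whitney(a, b)
            brute = sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b)
            assert u == pytest.approx(brute)

    def test_exact_p_matches_permutation_oracle(self):
        """Exact two-sided p equals the proportion of group relabellings with
        |U - E[U]| at least as large as observed (no-ties case)."""
        rng = np.random.default_rng(1)
        for _ in range(10):
            pooled = rng.permutation(20)[:9].astype(float)
            a, b = pooled[:4], pooled[4:]
            _, p = mann_whitney(a, b)
            na, n = len(a), len(pooled)
            mu = na * (n - na) / 2.0
            obs = abs(auroc(a, b) * na * (n - na) - mu)
            count = 0
            combos = list(itertools.combinations(range(n), na))
            for idx in combos:
                sel = np.zeros(n, dtype=bool)
                sel[list(idx)] = True
                u = auroc(pooled[sel], pooled[~sel]) * na * (n - na)
                if abs(u - mu) >= obs - 1e-9:
                    count += 1
            assert p == pytest.approx(count / len(combos))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestWilcoxon:
    def test_all_positive_n6(self):
        _, p = wilcoxon_signed_rank([1, 2, 3, 4, 5, 6])
        assert p == pytest.approx(2 / 64)

    def test_n5_cannot_reach_005(self):
        _, p = wilcoxon_signed_rank([1, 2, 3, 4, 5])
        assert p == pytest.approx(0.0625)

    def test_antisymmetric_differences(self):
        _, p = wilcoxon_signed_rank([-3, -1, 1, 3])
        assert p == pytest.approx(1.0)

    def test_zeros_dropped(self):
        w1 = wilcoxon_signed_rank([0, 0, 1, 2, 3, 4, 5, 6])
        w2 = wilcoxon_signed_rank([1, 2, 3, 4, 5, 6])
        assert w1 == w2

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.0, 0.0])


class TestBootstrapMedianCI:
    def test_constant_vector(self):
        med, lo, hi = bootstrap_median_ci([4.2] * 10, n_iter=500, seed=0)
        assert med == lo == hi == 4.2

    def test_bounds_within_range(self):
        rng = np.random.default_rng(2)
        v = rng.standard_normal(15)
        med, lo, hi = bootstrap_median_ci(v, n_iter=2000, seed=1)
        assert v.min() <= lo <= med <= hi <= v.max()

    def test_seeded_reproducible(self):
        v = np.random.default_rng(3).standard_normal(12)
        assert bootstrap_median_ci(v, seed=7) == bootstrap_median_ci(v, seed=7)

    def test_coverage_near_nominal(self):
        """~95% of bootstrap CIs on n=20 normal samples cover the true median."""
        rng = np.random.default_rng(4)
        hits = 0
        reps = 400
        for _ in range(reps):
            v = rng.standard_normal(20)
            _, lo, hi = bootstrap_median_ci(v, n_iter=400, seed=rng)
            hits += lo <= 0.0 <= hi
        assert hits / reps == pytest.approx(0.95, abs=0.04)


class TestAUROC:
    def test_full_separation(self):
        assert auroc([3, 4, 5], [0, 1, 2]) == 1.0

    def test_identical_groups(self):
        assert auroc([1, 2, 3], [1, 2, 3]) == 0.5

    @given(
        st.lists(st.integers(0, 8), min_size=2, max_size=8),
        st.lists(st.integers(0, 8), min_size=2, max_size=8),
    )
    @settings(max_examples=150, deadline=None)
    def test_equals_u_statistic_and_antisymmetry(self, a, b):
        val = auroc(a, b)
        u, _ = mann_whitney(a, b)
        assert val == pytest.approx(u / (len(a) * len(b)))
        assert auroc(b, a) == pytest.approx(1.0 - val)

    def test_effect_result_invariants(self):
        rng = np.random.default_rng(5)
        eff = auroc_effect(rng.normal(2, 1, 9), rng.normal(0, 1, 9), n_iter=800, seed=0)
        assert eff.ci_lo <= eff.auc <= eff.ci_hi
        assert eff.label in ("strong", "good", "none")
        assert 0 <= eff.p_raw <= 1

    def test_labels(self):
        assert classifier_label(0.9, 0.7, 1.0) == "strong"
        assert classifier_label(0.9, 0.4, 1.0) == "good"
        assert classifier_label(0.1, 0.0, 0.3) == "strong"
        assert classifier_label(0.6, 0.4, 0.8) == "none"

    def test_null_strong_rate_controlled(self):
        """Under H0 (same distribution, n=5 vs 9) the strong-classifier rate
        stays below 10% of simulated bins."""
        rng = np.random.default_rng(6)
        strong = 0
        bins = 300
        for _ in range(bins):
            eff = auroc_effect(
                rng.standard_normal(5), rng.standard_normal(9), n_iter=300, seed=rng
            )
            strong += eff.label == "strong"
        assert strong / bins <= 0.10


class TestBenjaminiHochberg:
    def test_printed_formula_example(self):
        rejected, adjusted, k = benjamini_hochberg([0.01, 0.02, 0.04, 0.05], q=0.05)
        assert k == 4 and rejected.all()
        np.testing.assert_allclose(adjusted, [0.04, 0.04, 0.05, 0.05])

    def test_all_ones(self):
        rejected, adjusted, k = benjamini_hochberg([1.0, 1.0, 1.0])
        assert k == 0 and not rejected.any()
        assert (adjusted == 1.0).all()

    def test_single_test_reduces_to_raw(self):
        rejected, adjusted, k = benjamini_hochberg([0.04], q=0.05)
        assert k == 1 and rejected.all() and adjusted[0] == pytest.approx(0.04)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            p = rng.random(rng.integers(1, 40))
            rej, adj, _ = benjamini_hochberg(p)
            rej_sm, adj_sm, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
            np.testing.assert_allclose(adj, adj_sm)
            assert (rej == rej_sm).all()

    def test_adjusted_monotone_in_rank(self):
        rng = np.random.default_rng(8)
        p = rng.random(25)
        _, adj, _ = benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])
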