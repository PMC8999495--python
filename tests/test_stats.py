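"""Rank-test suite: exact Mann-Whitney, Kruskal-Wallis, Bonferroni pairs."""

from itertools import combinations
from math import comb

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from xray2fem.stats import (
    kruskal_wallis,
    mann_whitney_u,
    normality_check,
    pairwise_bonferroni,
)


def brute_force_exact_p(a, b):
    """Two-tailed exact Mann-Whitney p by full enumeration of labelings."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n, n_a = pooled.size, a.size

    def u_of(idx_a):
        sa = pooled_sorted[list(idx_a)]
        rest = np.delete(pooled_sorted, list(idx_a))
        return sum((x > rest).sum() for x in sa)

    pooled_sorted = np.sort(pooled)
    u_obs_a = sum((x > b).sum() for x in a)
    u_obs = min(u_obs_a, a.size * b.size - u_obs_a)
    us = [u_of(idx) for idx in combinations(range(n), n_a)]
    us = np.array(us)
    lo = (us <= u_obs).sum()
    hi = (us >= a.size * b.size - u_obs).sum()
    return min(1.0, (lo + hi) / comb(n, n_a))


class TestMannWhitney:
    def test_identical_samples_zero_z(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.z == 0.0
        assert res.p == 1.0

    def test_separated_pair_exact_third(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.U == 0
        assert res.method == "exact"
        assert res.p == pytest.approx(1 / 3)

    def test_exact_matches_enumeration_small_samples(self):
        rng = np.random.default_rng(5)
        for n1 in range(1, 5):
            for n2 in range(1, 5):
                for _ in range(3):
                    a = rng.normal(size=n1)
                    b = rng.normal(size=n2)
                    res = mann_whitney_u(a, b, method="exact")
                    assert res.p == pytest.approx(brute_force_exact_p(a, b))

    def test_exact_matches_scipy(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=5), rng.normal(size=6)
        ours = mann_whitney_u(a, b, method="exact")
        ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert ours.p == pytest.approx(ref.pvalue)

    def test_normal_approximation_matches_scipy(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=20), rng.normal(size=25, loc=0.5)
        ours = mann_whitney_u(a, b, method="normal")
        ref = scipy.stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-9)

    @given(
        st.lists(st.integers(0, 50), min_size=1, max_size=8),
        st.lists(st.integers(0, 50), min_size=1, max_size=8),
    )
    @settings(max_examples=100, deadline=None)
    def test_u_complement_identity(self, a, b):
        r1 = mann_whitney_u(a, b, method="normal")
        r2 = mann_whitney_u(b, a, method="normal")
        assert r1.U_a + r2.U_a == pytest.approx(len(a) * len(b))
        assert r1.U == r2.U

    def test_z_sign_follows_rank_means(self):
        hi_first = mann_whitney_u([10, 11, 12], [1, 2, 3], method="normal")
        lo_first = mann_whitney_u([1, 2, 3], [10, 11, 12], method="normal")
        assert hi_first.z > 0 > lo_first.z

    def test_continuity_corrected_z_small_samples(self):
        # U=0 at n=5,5: z = (12.5 - 0.5) / sqrt(275/12) = 2.507
        res = mann_whitney_u(np.arange(5), np.arange(10, 15), method="normal")
        assert res.U == 0
        assert res.z == pytest.approx(-12.0 / np.sqrt(275 / 12), rel=1e-9)
        assert res.p == pytest.approx(0.0122, abs=2e-4)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_exact_refuses_ties(self):
        with pytest.raises(ValueError, match="tie"):
            mann_whitney_u([1, 1], [1, 2], method="exact")


class TestKruskalWallis:
    def test_h_exact_fraction(self):
        res = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert res.H == pytest.approx(32 / 7, rel=1e-12)
        assert res.eta_squared == pytest.approx((32 / 7 - 2) / 3, rel=1e-12)

    def test_identical_groups_h_zero(self):
        res = kruskal_wallis([[5, 5], [5, 5], [5, 5]])
        assert res.H == 0.0
        assert res.p == 1.0
        assert res.eta_squared == 0.0

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(3)
        groups = [rng.integers(0, 6, size=7) for _ in range(3)]
        ours = kruskal_wallis(groups)
        ref = scipy.stats.kruskal(*groups)
        assert ours.H == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_eta_squared_floored_at_zero(self):
        # near-identical mean ranks give H < k - 1, so the raw effect size
        # would be negative
        res = kruskal_wallis([[1, 6], [2, 5], [3, 4]])
        assert res.eta_squared == 0.0

    def test_effect_size_consistency_with_reported_precision(self):
        # eta^2 = 0.46 at k=3, n=15 implies H = 0.46*12 + 2 = 7.52 and a
        # chi-square (2 df) tail of ~0.023
        H = 0.46 * 12 + 2
        assert H == pytest.approx(7.52)
        p = scipy.stats.chi2.sf(H, 2)
        assert p == pytest.approx(0.0233, abs=5e-4)

    def test_group_validation(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])


class TestPairwiseBonferroni:
    def test_three_groups_three_pairs_threshold(self):
        res = pairwise_bonferroni([[1, 2], [3, 4], [5, 6]], labels=["A1", "A2", "A3"])
        assert len(res) == 3
        assert all(r.threshold == pytest.approx(0.05 / 3) for r in res)
        assert {r.pair for r in res} == {("A1", "A2"), ("A1", "A3"), ("A2", "A3")}

    def test_identical_groups_nothing_flagged(self):
        res = pairwise_bonferroni([[1, 2, 3]] * 3)
        assert not any(r.significant for r in res)

    def test_well_separated_groups_all_flagged_at_exact_minimum(self):
        groups = [list(range(1, 6)), list(range(101, 106)), list(range(201, 206))]
        res = pairwise_bonferroni(groups)
        p_min = 2 / comb(10, 5)  # most extreme ranking, both tails
        for r in res:
            assert r.U == 0
            assert r.p == pytest.approx(p_min)
            assert r.significant


class TestNormalityCheck:
    def test_equally_spaced_triplet_near_perfect_w(self):
        w, _ = normality_check([1.0, 2.0, 3.0])
        assert w == pytest.approx(1.0, abs=1e-6)

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            normality_check([2.0, 2.0, 2.0])

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            normality_check([1.0, 2.0])
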