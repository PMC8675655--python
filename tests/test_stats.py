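"""Exact-test correctness against literal brute-force enumeration.

The package computes exact null distributions by dynamic programming; the
oracle here enumerates sign assignments / group splits literally, so the
two routes are independent.
"""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from discquant import (
    mann_whitney_u,
    mean_ci,
    one_sample_wilcoxon,
    wilcoxon_signed_rank,
)


def brute_force_signed_rank_p(d):
    """Two-sided exact p by enumeration of all 2^n sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws, dtype=float)
    p_le = np.mean(ws <= w_obs)
    p_ge = np.mean(ws >= w_obs)
    return min(1.0, 2 * min(p_le, p_ge)), w_obs, mu


def brute_force_mwu_p(x, y):
    """Two-sided exact p by enumeration of all C(n1+n2, n1) splits."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for combo in itertools.combinations(range(n1 + n2), n1):
        us.append(ranks[list(combo)].sum() - n1 * (n1 + 1) / 2)
    us = np.asarray(us)
    return min(1.0, 2 * min(np.mean(us <= u_obs), np.mean(us >= u_obs))), u_obs


class TestSignedRank:
    def test_all_positive_differences_n6(self):
        """Six concordant pairs: the most extreme table, p = 2/64."""
        x = [1.2, 1.3, 1.1, 1.4, 1.25, 1.15]
        res = wilcoxon_signed_rank(x, [1.0] * 6)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 64)

    @pytest.mark.parametrize("n", range(2, 9))
    def test_exhaustive_vs_bruteforce(self, n, rng):
        """DP null distribution equals literal enumeration for n <= 8."""
        for _ in range(20):
            d = rng.normal(size=n)
            p_oracle, _, _ = brute_force_signed_rank_p(d)
            res = wilcoxon_signed_rank(d, np.zeros(n))
            assert res.method == "exact"
            assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_matches_scipy_exact(self, rng):
        for n in (5, 9, 13):
            d = rng.normal(size=n)
            ours = wilcoxon_signed_rank(d, np.zeros(n)).p_value
            ref = sps.wilcoxon(d, mode="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_identical_pairs_error(self):
        with pytest.raises(ValueError, match="nonzero"):
            wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_two_sided_symmetry(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        assert wilcoxon_signed_rank(x, y).p_value == pytest.approx(
            wilcoxon_signed_rank(y, x).p_value
        )

    def test_zero_differences_dropped_and_counted(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]
        y = [1.0, 2.0, 2.5, 3.2, 4.1, 5.3, 6.1]
        res = wilcoxon_signed_rank(x, y)
        assert res.n_zero_dropped == 2
        assert res.n == 5

    def test_ties_fall_back_to_approximation(self):
        x = [1, 2, 3, 4, 5, 6, 7, 8]
        y = [0, 1, 2, 3, 4, 5, 6, 6.5]  # tied |differences|
        res = wilcoxon_signed_rank(x, y)
        assert res.method == "approximate"
        assert 0 <= res.p_value <= 1


class TestOneSampleWilcoxon:
    def test_worked_example_vs_one(self):
        vals = [1.2, 1.3, 1.1, 1.4, 1.25, 1.15]
        res = one_sample_wilcoxon(vals, mu0=1.0)
        assert res.p_value == pytest.approx(0.03125)
        assert res.method == "exact"

    def test_statistic_at_null_center_gives_p_one(self):
        # signed ranks of the positives sum to 14 = n(n+1)/4: dead center
        d = np.array([0.1, -0.2, -0.3, -0.4, -0.5, 0.6, 0.7])
        res = one_sample_wilcoxon(1.0 + d, mu0=1.0)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1.0)

    def test_translation_invariance(self, rng):
        vals = rng.normal(size=9)
        a = one_sample_wilcoxon(vals, mu0=0.3)
        b = one_sample_wilcoxon(vals + 10.0, mu0=10.3)
        assert a.p_value == pytest.approx(b.p_value)
        assert a.statistic == pytest.approx(b.statistic)

    def test_all_at_null_error(self):
        with pytest.raises(ValueError):
            one_sample_wilcoxon([1.0, 1.0, 1.0], mu0=1.0)


class TestMannWhitney:
    def test_worked_example_u0(self):
        """Complete separation of 3 vs 3: U = 0, p = 2/20."""
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "exact"

    @pytest.mark.parametrize("n1,n2", [(2, 2), (2, 4), (3, 3), (3, 5), (4, 4), (2, 6)])
    def test_exhaustive_vs_bruteforce(self, n1, n2, rng):
        for _ in range(15):
            x, y = rng.normal(size=n1), rng.normal(size=n2)
            p_oracle, u_obs = brute_force_mwu_p(x, y)
            res = mann_whitney_u(x, y)
            assert res.method == "exact"
            assert res.statistic == pytest.approx(u_obs)
            assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_matches_scipy_exact(self, rng):
        x, y = rng.normal(size=5), rng.normal(size=6)
        ours = mann_whitney_u(x, y).p_value
        ref = sps.mannwhitneyu(x, y, method="exact", alternative="two-sided").pvalue
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_u_identity(self, rng):
        x, y = rng.normal(size=7), rng.normal(size=9)
        ux = mann_whitney_u(x, y).statistic
        uy = mann_whitney_u(y, x).statistic
        assert ux + uy == pytest.approx(len(x) * len(y))

    def test_identical_groups_near_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = mann_whitney_u(x, list(x))
        assert res.p_value >= 0.99

    def test_empty_group_error(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_large_sample_uses_approximation(self, rng):
        x, y = rng.normal(size=13), rng.normal(size=13)
        res = mann_whitney_u(x, y)
        assert res.method == "approximate"


class TestMeanCI:
    def test_textbook_example(self):
        lo, hi = mean_ci([1, 2, 3, 4, 5])
        assert lo == pytest.approx(1.037, abs=1e-3)
        assert hi == pytest.approx(4.963, abs=1e-3)

    def test_constant_vector_zero_width(self):
        lo, hi = mean_ci([2.5, 2.5, 2.5])
        assert lo == hi == pytest.approx(2.5)

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            mean_ci([1.0])


def test_null_rejection_rate_is_calibrated(rng):
    """Both tests hold their size at alpha=0.05 under a continuous null."""
    n_sim = 400
    alpha = 0.05
    rej_w = rej_u = 0
    for _ in range(n_sim):
        x, y = rng.normal(size=13), rng.normal(size=13)
        rej_w += wilcoxon_signed_rank(x, y).p_value < alpha
        rej_u += mann_whitney_u(x, y).p_value < alpha
    assert 0.02 <= rej_w / n_sim <= 0.085
    assert 0.02 <= rej_u / n_sim <= 0.085
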