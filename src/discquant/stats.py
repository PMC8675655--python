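"""Nonparametric tests with exact small-sample null distributions.

All cohort comparisons in the pipeline go through three univariate tests:
the Wilcoxon matched-pairs signed-rank test (paired, within-disc designs),
its one-sample form (ratios tested against 1), and the Mann–Whitney U-test
(unpaired, between-genotype designs).  For small samples the null
distributions are computed exactly by dynamic programming over sign
assignments / rank splits; larger samples (or tied data) fall back to the
tie-corrected normal approximation.  No multiple-comparison correction is
applied anywhere — each test stands on its own.

Conventions: zero differences are dropped before ranking (their count is
reported); ties receive midranks; the exact path refuses tied ranks and
falls through to the corrected approximation; no continuity correction is
used in the approximate regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

#: largest n for which the signed-rank null is enumerated exactly
EXACT_SIGNED_RANK_N = 15
#: largest n1+n2 for which the U null is enumerated exactly
EXACT_MWU_N = 12


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    test_name: str
    statistic: float
    p_value: float
    n: int
    n2: int | None = None
    sidedness: str = "two-sided"
    method: str = "exact"
    n_zero_dropped: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _midranks(a: np.ndarray) -> np.ndarray:
    return sps.rankdata(a, method="average")


def _signed_rank_null_counts(n: int) -> np.ndarray:
    """Counts of the W+ null distribution for untied ranks 1..n.

    Entry ``c[w]`` is the number of the 2^n sign assignments with positive
    rank sum w.  Built by the subset-sum recurrence, equivalent to full
    enumeration but O(n³).
    """
    tot = n * (n + 1) // 2
    c = np.zeros(tot + 1, dtype=np.float64)
    c[0] = 1.0
    for r in range(1, n + 1):
        c[r:] = c[r:] + c[: tot + 1 - r]
    return c


def _two_sided_p_from_counts(counts: np.ndarray, stat: int) -> float:
    total = counts.sum()
    p_le = counts[: stat + 1].sum() / total
    p_ge = counts[stat:].sum() / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _one_sided_p_from_counts(counts: np.ndarray, stat: int, tail: str) -> float:
    total = counts.sum()
    if tail == "greater":
        return float(counts[stat:].sum() / total)
    return float(counts[: stat + 1].sum() / total)


def _signed_rank_core(d: np.ndarray, two_sided: bool, test_name: str) -> TestResult:
    d = np.asarray(d, dtype=float)
    n_zero = int(np.count_nonzero(d == 0))
    d = d[d != 0]
    n = len(d)
    if n < 2:
        raise ValueError("no nonzero pairs: need >= 2 nonzero differences")
    ranks = _midranks(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    has_ties = len(np.unique(np.abs(d))) != n
    sidedness = "two-sided" if two_sided else "greater"

    if n <= EXACT_SIGNED_RANK_N and not has_ties:
        counts = _signed_rank_null_counts(n)
        stat_int = int(round(w_pos))
        if two_sided:
            p = _two_sided_p_from_counts(counts, stat_int)
        else:
            p = _one_sided_p_from_counts(counts, stat_int, "greater")
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        # midrank tie correction on |d|
        _, t = np.unique(np.abs(d), return_counts=True)
        var -= (t**3 - t).sum() / 48.0
        if var <= 0:
            raise ValueError("degenerate signed-rank variance (all |differences| tied at one value)")
        z = (w_pos - mu) / np.sqrt(var)
        p = float(2 * sps.norm.sf(abs(z)) if two_sided else sps.norm.sf(z))
        method = "approximate"

    return TestResult(
        test_name=test_name,
        statistic=w_pos,
        p_value=min(1.0, p),
        n=n,
        sidedness=sidedness,
        method=method,
        n_zero_dropped=n_zero,
    )


def wilcoxon_signed_rank(x, y, two_sided: bool = True) -> TestResult:
    """Wilcoxon matched-pairs signed-rank test on paired samples.

    Zero differences are dropped (count recorded on the result).  The exact
    null distribution over all 2^n sign assignments is used for n <= 15 with
    untied |differences|; otherwise the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    return _signed_rank_core(x - y, two_sided, "wilcoxon_signed_rank")


def one_sample_wilcoxon(values, mu0: float = 0.0, two_sided: bool = True) -> TestResult:
    """One-sample Wilcoxon signed-rank test of the location against ``mu0``.

    Used on P/A intensity ratios tested against 1.
    """
    values = np.asarray(values, dtype=float)
    return _signed_rank_core(values - mu0, two_sided, "one_sample_wilcoxon")


def _mwu_null_counts(n1: int, n2: int) -> np.ndarray:
    """Counts of the U null distribution over all C(n1+n2, n1) rank splits.

    ``c[u]`` counts splits in which the first group attains U = u; built by
    the standard two-group recurrence.
    """
    max_u = n1 * n2
    # recurrence: f(n1, n2, u) = f(n1-1, n2, u-n2) + f(n1, n2-1, u)
    f = np.zeros((n1 + 1, n2 + 1, max_u + 1), dtype=np.float64)
    f[0, :, 0] = 1.0
    f[:, 0, 0] = 1.0
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            shifted = np.zeros(max_u + 1)
            shifted[j:] = f[i - 1, j, : max_u + 1 - j]
            f[i, j] = shifted + f[i, j - 1]
    return f[n1, n2]


def mann_whitney_u(x, y, two_sided: bool = True) -> TestResult:
    """Mann–Whitney U-test for two independent samples.

    Exact enumeration over rank splits for n1+n2 <= 12 without ties;
    tie-corrected normal approximation otherwise.  The reported statistic is
    U for the first sample (U_x + U_y = n1·n2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    has_ties = len(np.unique(pooled)) != n1 + n2
    sidedness = "two-sided" if two_sided else "greater"

    if n1 + n2 <= EXACT_MWU_N and not has_ties:
        counts = _mwu_null_counts(n1, n2)
        stat_int = int(round(u1))
        if two_sided:
            p = _two_sided_p_from_counts(counts, stat_int)
        else:
            p = _one_sided_p_from_counts(counts, stat_int, "greater")
        method = "exact"
    else:
        n = n1 + n2
        mu = n1 * n2 / 2.0
        _, t = np.unique(pooled, return_counts=True)
        tie_term = (t**3 - t).sum() / (n * (n - 1)) if n > 1 else 0.0
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            raise ValueError("degenerate U variance (all pooled values identical)")
        z = (u1 - mu) / np.sqrt(var)
        p = float(2 * sps.norm.sf(abs(z)) if two_sided else sps.norm.sf(z))
        method = "approximate"

    return TestResult(
        test_name="mann_whitney_u",
        statistic=u1,
        p_value=min(1.0, p),
        n=n1,
        n2=n2,
        sidedness=sidedness,
        method=method,
    )


def mean_ci(values, level: float = 0.95) -> tuple[float, float]:
    """Student-t confidence interval for the mean."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("confidence interval needs at least 2 values")
    m = values.mean()
    se = values.std(ddof=1) / np.sqrt(n)
    tcrit = sps.t.ppf(0.5 + level / 2.0, df=n - 1)
    return float(m - tcrit * se), float(m + tcrit * se)
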