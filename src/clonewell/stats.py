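"""Hypothesis tests used by the growth analysis.

Three procedures, implemented from their defining formulas: one-way
ANOVA, a weighted Welch's t-test for samples that are averages of
different numbers of underlying observations, and an exact two-sided
permutation test for a difference in means computed by subset-sum
dynamic programming with arbitrary-precision integer counts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "CensoredValue",
    "one_way_anova",
    "weighted_welch_t_test",
    "permutation_test_mean_exact",
    "permutation_test_mean_montecarlo",
    "permutation_test_mean",
    "count_subsets_sum_leq",
    "bonferroni",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test."""

    statistic: float
    p_value: float
    method: str
    df1: float | None = None
    df2: float | None = None
    extras: dict = field(default_factory=dict)


@dataclass(frozen=True)
class CensoredValue:
    """An integer day observation that may be interval- or right-censored.

    ``exact``: the value is ``low``.  ``interval``: somewhere in
    [low, high].  ``right_censored``: strictly greater than ``low``.
    """

    kind: str
    low: int
    high: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("exact", "interval", "right_censored"):
            raise ValueError(f"unknown censoring kind {self.kind!r}")
        if self.kind == "interval":
            if self.high is None or self.high < self.low:
                raise ValueError("interval needs low <= high")

    def resolve(self, strategy: str = "minimal", right_pad: int = 0) -> int:
        """Smallest (or largest) integer consistent with the record.

        A right-censored record has no finite maximum; ``right_pad``
        sets how far beyond ``low + 1`` the maximal resolution goes.
        """
        if self.kind == "exact":
            return self.low
        if strategy == "minimal":
            return self.low if self.kind == "interval" else self.low + 1
        if strategy == "maximal":
            return self.high if self.kind == "interval" else self.low + 1 + right_pad
        raise ValueError(f"unknown strategy {strategy!r}")


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way fixed-effects ANOVA F-test that k group means are equal.

    F = [sum_i N_i (xbar_i - xbar)^2 / (k-1)] /
        [sum_ij (x_ij - xbar_i)^2 / (N-k)],
    with the p-value from the upper tail of F(k-1, N-k).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    N = sum(len(g) for g in groups)
    if N <= k:
        raise ValueError("need total sample size larger than the number of groups")
    grand = sum(g.sum() for g in groups) / N
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = k - 1, N - k
    extras: dict = {}
    if ss_within == 0.0:
        if ss_between == 0.0:
            return TestResult(0.0, 1.0, "anova", df1, df2, {"degenerate": True})
        return TestResult(math.inf, 0.0, "anova", df1, df2, {"infinite_F": True})
    F = (ss_between / df1) / (ss_within / df2)
    p = float(sps.f.sf(F, df1, df2))
    return TestResult(float(F), p, "anova", df1, df2, extras)


def _weighted_moments(x: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    n = len(x)
    mean = float(np.sum(x * c) / np.sum(c))
    s2 = n * (float(np.sum(x ** 2 * c) / np.sum(c)) - mean ** 2) / (n - 1)
    return mean, s2


def weighted_welch_t_test(
    x1: Sequence[float],
    c1: Sequence[float],
    x2: Sequence[float],
    c2: Sequence[float],
) -> TestResult:
    """Welch's t-test where sample j of group i averages c_ij underlying
    observations.

    Weighted means xbar_iW = sum_j x_ij c_ij / sum_j c_ij, weighted
    variances s2_iW = N_i [sum_j x_ij^2 c_ij / sum_j c_ij - xbar_iW^2]
    / (N_i - 1), t = (xbar_1W - xbar_2W) / sqrt(s2_1W/N_1 + s2_2W/N_2),
    with Welch-Satterthwaite degrees of freedom.  With all weights equal
    this is the standard Welch test.
    """
    x1, c1 = np.asarray(x1, float), np.asarray(c1, float)
    x2, c2 = np.asarray(x2, float), np.asarray(c2, float)
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("each group needs at least two samples")
    if np.any(c1 <= 0) or np.any(c2 <= 0):
        raise ValueError("weights must be positive")
    n1, n2 = len(x1), len(x2)
    m1, s1 = _weighted_moments(x1, c1)
    m2, s2 = _weighted_moments(x2, c2)
    pooled = s1 / n1 + s2 / n2
    if pooled <= 0:
        return TestResult(0.0, 1.0, "weighted_welch", None, None, {"degenerate": True})
    t = (m1 - m2) / math.sqrt(pooled)
    nu = pooled ** 2 / (s1 ** 2 / (n1 ** 2 * (n1 - 1)) + s2 ** 2 / (n2 ** 2 * (n2 - 1)))
    p = float(2.0 * sps.t.sf(abs(t), nu))
    return TestResult(
        float(t),
        p,
        "weighted_welch",
        df1=float(nu),
        extras={"mean1": m1, "mean2": m2, "s2_1": s1, "s2_2": s2},
    )


def count_subsets_sum_leq(values: Sequence[int], m: int, s: int) -> int:
    """Exact number of size-``m`` subsets of ``values`` with sum <= s.

    Dynamic programming over (item, chosen count, sum) with Python
    integers, so counts stay exact far beyond 53-bit floats.
    """
    values = [int(v) for v in values]
    if any(v < 0 for v in values):
        raise ValueError("values must be non-negative integers")
    max_sum = min(s, sum(values))
    if max_sum < 0:
        return 0
    # dp[c][t] = number of ways to choose c items with sum exactly t
    dp = [[0] * (max_sum + 1) for _ in range(m + 1)]
    dp[0][0] = 1
    for v in values:
        for c in range(min(m, len(values)) - 1, -1, -1):
            row, nxt = dp[c], dp[c + 1]
            for t in range(max_sum - v, -1, -1):
                w = row[t]
                if w:
                    nxt[t + v] += w
    return sum(dp[m])


def _resolve_sample(sample, strategy: str, right_pad: int = 0) -> list[int]:
    out = []
    for v in sample:
        if isinstance(v, CensoredValue):
            out.append(v.resolve(strategy, right_pad=right_pad))
        else:
            if float(v) != int(v):
                raise ValueError(
                    "exact permutation test needs integer values; "
                    "use permutation_test_mean_montecarlo for real-valued data"
                )
            out.append(int(v))
    return out


def _tail_counts(vals1: list[int], vals2: list[int]) -> tuple[int, int, int]:
    m = len(vals1)
    pooled = vals1 + vals2
    s_obs = sum(vals1)
    total = math.comb(len(pooled), m)
    count_le = count_subsets_sum_leq(pooled, m, s_obs)
    count_lt = count_subsets_sum_leq(pooled, m, s_obs - 1)
    count_ge = total - count_lt
    return count_le, count_ge, total


def permutation_test_mean_exact(
    sample1: Sequence,
    sample2: Sequence,
    check_censoring_invariance: bool = True,
) -> TestResult:
    """Exact two-sided permutation test for a difference in means.

    All equal-probability splits of the pooled values into groups of the
    original sizes are counted exactly; the two-sided p-value is
    2 * min(#{mean' <= mean_obs}, #{mean' >= mean_obs}) / C(m+n, m),
    clamped to 1, with inclusive tails.  Censored values are resolved to
    their minimal consistent integers; when any censoring is present the
    tail counts are recomputed at the maximal consistent resolution and
    checked for agreement (flagged in ``extras`` otherwise).
    """
    if len(sample1) == 0 or len(sample2) == 0:
        raise ValueError("both samples must be non-empty")
    vals1 = _resolve_sample(sample1, "minimal")
    vals2 = _resolve_sample(sample2, "minimal")
    count_le, count_ge, total = _tail_counts(vals1, vals2)
    extras = {
        "count_le": count_le,
        "count_ge": count_ge,
        "total_combinations": total,
        "mean1": sum(vals1) / len(vals1),
        "mean2": sum(vals2) / len(vals2),
    }
    has_censoring = any(
        isinstance(v, CensoredValue) and v.kind != "exact"
        for v in list(sample1) + list(sample2)
    )
    if has_censoring and check_censoring_invariance:
        alt1 = _resolve_sample(sample1, "maximal", right_pad=30)
        alt2 = _resolve_sample(sample2, "maximal", right_pad=30)
        # the observed statistic must be evaluated at the same resolution
        alt_le = count_subsets_sum_leq(alt1 + alt2, len(alt1), sum(vals1))
        extras["resolution_invariant"] = alt_le == count_le
    p = 2.0 * min(count_le, count_ge) / total
    stat = extras["mean1"] - extras["mean2"]
    return TestResult(float(stat), min(p, 1.0), "permutation_exact", extras=extras)


def permutation_test_mean_montecarlo(
    sample1: Sequence[float],
    sample2: Sequence[float],
    n_perm: int = 10_000,
    rng=None,
) -> TestResult:
    """Monte-Carlo permutation test of the same null, with add-one
    smoothing per tail: p_tail = (b + 1) / (n_perm + 1)."""
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    rng = np.random.default_rng(rng)
    vals1 = np.array([v.resolve() if isinstance(v, CensoredValue) else v for v in sample1], float)
    vals2 = np.array([v.resolve() if isinstance(v, CensoredValue) else v for v in sample2], float)
    m = len(vals1)
    pooled = np.concatenate([vals1, vals2])
    mean_obs = vals1.mean()
    b_le = b_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        mu = perm[:m].mean()
        if mu <= mean_obs:
            b_le += 1
        if mu >= mean_obs:
            b_ge += 1
    p_le = (b_le + 1) / (n_perm + 1)
    p_ge = (b_ge + 1) / (n_perm + 1)
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return TestResult(
        float(mean_obs - vals2.mean()),
        p,
        "permutation_montecarlo",
        extras={"n_perm": n_perm, "b_le": b_le, "b_ge": b_ge},
    )


def permutation_test_mean(sample1, sample2, n_perm: int = 10_000, rng=None) -> TestResult:
    """Exact test when all values are integers (after censor
    resolution), otherwise the Monte-Carlo variant."""
    try:
        return permutation_test_mean_exact(sample1, sample2)
    except ValueError as err:
        if "integer" not in str(err):
            raise
        return permutation_test_mean_montecarlo(sample1, sample2, n_perm=n_perm, rng=rng)


def permutation_brute_force(sample1: Sequence[int], sample2: Sequence[int]) -> tuple[int, int, int]:
    """Tail counts by exhaustive enumeration of all C(m+n, m) subsets.

    Independent oracle for the dynamic program; only feasible for small
    pooled samples.
    """
    vals1 = [int(v) for v in sample1]
    vals2 = [int(v) for v in sample2]
    pooled = vals1 + vals2
    m = len(vals1)
    s_obs = sum(vals1)
    count_le = count_ge = total = 0
    for comb in itertools.combinations(range(len(pooled)), m):
        s = sum(pooled[i] for i in comb)
        total += 1
        if s <= s_obs:
            count_le += 1
        if s >= s_obs:
            count_ge += 1
    return count_le, count_ge, total


def bonferroni(p_values: Iterable[float], alpha: float = 0.05, m_tests: int | None = None) -> list[bool]:
    """Strict-inequality Bonferroni decisions: significant iff
    p < alpha / m_tests."""
    p_values = list(p_values)
    m = m_tests if m_tests is not None else len(p_values)
    if m < 1:
        raise ValueError("m_tests must be at least 1")
    return [p < alpha / m for p in p_values]
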