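"""Nonparametric comparison machinery.

Wilcoxon rank-sum (Mann-Whitney) and signed-rank tests in two modes:

* ``exact`` -- the full permutation null distribution, computed by a
  convolution over integer ranks (equivalent to enumerating all
  C(n+m, n) group labelings, resp. all 2**n sign assignments).  Exact
  mode requires tie-free ranks; with ties it falls back to the normal
  approximation with a warning.
* ``normal_approx`` -- large-sample normal approximation with optional
  continuity correction (0.5 toward the null mean) and optional tie
  correction of the variance.

Two-sided p-values are ``2 * min(lower tail, upper tail)`` capped at 1,
with both tails inclusive of the observed statistic in exact mode.

Also provides :func:`summarize`: median and quartiles by linear
interpolation of order statistics (type-7, the numpy default), the
summary used in the per-species comparison tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.stats import norm, rankdata

logger = logging.getLogger(__name__)

Method = Literal["auto", "exact", "normal_approx"]

__all__ = [
    "SummaryStats",
    "TestResult",
    "summarize",
    "rank_sum_test",
    "signed_rank_test",
]


@dataclass(frozen=True)
class SummaryStats:
    """Median and quartiles of one sample, in the input's units."""

    n: int
    median: float
    lower_quartile: float
    upper_quartile: float

    def __post_init__(self) -> None:
        if not (self.lower_quartile <= self.median <= self.upper_quartile):
            raise ValueError("quartiles out of order")


@dataclass(frozen=True)
class TestResult:
    """Outcome of a Wilcoxon test.

    ``statistic`` is W (rank sum of the first sample) for the rank-sum
    test, or W+ (sum of positive-difference ranks) for the signed-rank
    test.  ``n`` is the first-sample size (rank-sum) or the number of
    nonzero pairs (signed-rank); ``m`` is the second-sample size or
    None.
    """

    test: Literal["rank_sum", "signed_rank"]
    method: Literal["exact", "normal_approx"]
    statistic: float
    n: int
    p_two_sided: float
    m: int | None = None
    continuity_correction: bool = False
    tie_correction: bool = False
    n_zeros_dropped: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_two_sided <= 1.0):
            raise ValueError(f"p-value {self.p_two_sided} outside (0, 1]")

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "method": self.method,
            "statistic": self.statistic,
            "n": self.n,
            "m": self.m,
            "continuity_correction": self.continuity_correction,
            "tie_correction": self.tie_correction,
            "n_zeros_dropped": self.n_zeros_dropped,
            "p_two_sided": self.p_two_sided,
        }


def summarize(values: Sequence[float]) -> SummaryStats:
    """Median / lower / upper quartile by type-7 interpolation."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty sample")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values in sample")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
    return SummaryStats(
        n=int(arr.size),
        median=float(med),
        lower_quartile=float(q1),
        upper_quartile=float(q3),
    )


def _two_sided_from_tails(lower: float, upper: float) -> float:
    return float(min(1.0, 2.0 * min(lower, upper)))


def _exact_rank_sum_distribution(n: int, total: int) -> np.ndarray:
    """Counts of subsets of size n of ranks 1..total, indexed by rank sum.

    Equivalent to enumerating all C(total, n) labelings; computed by the
    standard dynamic program over ranks.
    """
    max_sum = n * (2 * total - n + 1) // 2
    # counts[k, s] = number of k-subsets of processed ranks with sum s
    counts = np.zeros((n + 1, max_sum + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in range(1, total + 1):
        for k in range(min(r, n), 0, -1):  # descending k: rank r used once
            counts[k, r:] += counts[k - 1, :-r]
    return counts[n]


def _exact_signed_rank_distribution(n: int) -> np.ndarray:
    """Counts of W+ over all 2**n sign assignments of ranks 1..n."""
    max_sum = n * (n + 1) // 2
    counts = np.zeros(max_sum + 1, dtype=float)
    counts[0] = 1.0
    for r in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r]
        counts = counts + shifted
    return counts


def _has_ties(values: np.ndarray) -> bool:
    return np.unique(values).size < values.size


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    method: Method = "auto",
    continuity_correction: bool = True,
    tie_correction: bool = True,
    exact_limit: int = 25,
) -> TestResult:
    """Two-sided Wilcoxon rank-sum test of two independent samples.

    The statistic is W, the sum of the (mid)ranks of ``x`` in the pooled
    ranking.  ``method="auto"`` chooses exact when the pooled sample is
    tie-free and no larger than ``exact_limit``, the normal
    approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    if n < 1 or m < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if not np.all(np.isfinite(pooled)):
        raise ValueError("non-finite values in input samples")
    ties = _has_ties(pooled)
    ranks = rankdata(pooled)
    w = float(ranks[:n].sum())
    total = n + m

    if method == "auto":
        method = "exact" if (not ties and total <= exact_limit) else "normal_approx"
    if method == "exact" and ties:
        warnings.warn(
            "ties present: exact rank-sum distribution unavailable, "
            "falling back to normal approximation",
            stacklevel=2,
        )
        method = "normal_approx"

    if method == "exact":
        counts = _exact_rank_sum_distribution(n, total)
        total_count = counts.sum()
        w_int = int(round(w))
        lower = counts[: w_int + 1].sum() / total_count
        upper = counts[w_int:].sum() / total_count
        return TestResult(
            test="rank_sum",
            method="exact",
            statistic=w,
            n=n,
            m=m,
            p_two_sided=_two_sided_from_tails(lower, upper),
        )

    mean = n * (total + 1) / 2.0
    var = n * m * (total + 1) / 12.0
    if tie_correction and ties:
        _, t = np.unique(pooled, return_counts=True)
        var -= n * m * float(np.sum(t**3 - t)) / (12.0 * total * (total - 1))
    if var <= 0:
        # all pooled values identical: no evidence either way
        return TestResult(
            test="rank_sum",
            method="normal_approx",
            statistic=w,
            n=n,
            m=m,
            continuity_correction=continuity_correction,
            tie_correction=tie_correction,
            p_two_sided=1.0,
        )
    sd = np.sqrt(var)
    cc = 0.5 if continuity_correction else 0.0
    # continuity correction shrinks |W - mean| toward the mean
    z_lower = (w - mean + cc) / sd
    z_upper = (w - mean - cc) / sd
    p = _two_sided_from_tails(norm.cdf(z_lower), norm.sf(z_upper))
    return TestResult(
        test="rank_sum",
        method="normal_approx",
        statistic=w,
        n=n,
        m=m,
        continuity_correction=continuity_correction,
        tie_correction=tie_correction,
        p_two_sided=max(p, np.nextafter(0.0, 1.0)),
    )


def signed_rank_test(
    pairs: Sequence[tuple[float, float]],
    method: Method = "auto",
    continuity_correction: bool = True,
    tie_correction: bool = True,
    exact_limit: int = 25,
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test of paired samples.

    Differences ``d = a - b``; zero differences are dropped (Wilcoxon's
    original treatment) with the count recorded in the result.  The
    statistic is W+, the sum of (mid)ranks of |d| over positive d.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (a, b) tuples")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values in input pairs")
    d = arr[:, 0] - arr[:, 1]
    n_zeros = int(np.sum(d == 0))
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("no nonzero pairs: all differences are zero")
    if n_zeros:
        logger.info("signed_rank_test: dropped %d zero differences", n_zeros)

    absd = np.abs(d)
    ties = _has_ties(absd)
    ranks = rankdata(absd)
    w_plus = float(ranks[d > 0].sum())

    if method == "auto":
        method = "exact" if (not ties and n <= exact_limit) else "normal_approx"
    if method == "exact" and ties:
        warnings.warn(
            "tied |differences|: exact signed-rank distribution unavailable, "
            "falling back to normal approximation",
            stacklevel=2,
        )
        method = "normal_approx"

    if method == "exact":
        counts = _exact_signed_rank_distribution(n)
        total_count = counts.sum()
        w_int = int(round(w_plus))
        lower = counts[: w_int + 1].sum() / total_count
        upper = counts[w_int:].sum() / total_count
        return TestResult(
            test="signed_rank",
            method="exact",
            statistic=w_plus,
            n=n,
            n_zeros_dropped=n_zeros,
            p_two_sided=_two_sided_from_tails(lower, upper),
        )

    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    if tie_correction and ties:
        _, t = np.unique(absd, return_counts=True)
        var -= float(np.sum(t**3 - t)) / 48.0
    if var <= 0:
        return TestResult(
            test="signed_rank",
            method="normal_approx",
            statistic=w_plus,
            n=n,
            continuity_correction=continuity_correction,
            tie_correction=tie_correction,
            n_zeros_dropped=n_zeros,
            p_two_sided=1.0,
        )
    sd = np.sqrt(var)
    cc = 0.5 if continuity_correction else 0.0
    z_lower = (w_plus - mean + cc) / sd
    z_upper = (w_plus - mean - cc) / sd
    p = _two_sided_from_tails(norm.cdf(z_lower), norm.sf(z_upper))
    return TestResult(
        test="signed_rank",
        method="normal_approx",
        statistic=w_plus,
        n=n,
        continuity_correction=continuity_correction,
        tie_correction=tie_correction,
        n_zeros_dropped=n_zeros,
        p_two_sided=max(p, np.nextafter(0.0, 1.0)),
    )
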