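"""Self-contained implementations of the statistical tests the pipeline uses.

All tests are two-sided. Exact small-sample branches are implemented by
enumeration / dynamic programming; large samples fall back on the usual
normal approximations with tie corrections and continuity corrections. The
branch actually taken is recorded in ``TestResult.method``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import lgamma, sqrt

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]


def _log_comb(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 contingency table.

    The two-sided p-value sums the hypergeometric probabilities of every
    table with the observed margins whose probability does not exceed the
    observed table's (with a 1+1e-7 relative slack against floating-point
    ties), computed in log space.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("all cells must be non-negative")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, c1, n = a + b, a + c, a + b + c + d
    if n == 0:
        return TestResult(statistic=float("nan"), p_value=1.0, method="exact", n=(0,))

    denom = _log_comb(n, r1)

    def log_p(aa: int) -> float:
        return _log_comb(c1, aa) + _log_comb(n - c1, r1 - aa) - denom

    lo = max(0, r1 - (n - c1))
    hi = min(r1, c1)
    lp_obs = log_p(a)
    cutoff = lp_obs + np.log1p(1e-7)
    p = 0.0
    for aa in range(lo, hi + 1):
        lp = log_p(aa)
        if lp <= cutoff:
            p += np.exp(lp)
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    return TestResult(statistic=odds, p_value=min(p, 1.0), method="exact", n=(r1, n - r1))


@lru_cache(maxsize=32)
def _ranksum_null_counts(nx: int, n: int) -> tuple[np.ndarray, int]:
    """Counts of subsets of size nx of ranks 1..n by rank sum.

    Returns (counts, min_sum) where counts[s - min_sum] is the number of
    nx-subsets summing to s.
    """
    min_sum = nx * (nx + 1) // 2
    max_sum = nx * (2 * n - nx + 1) // 2
    width = max_sum - min_sum + 1
    # dp[k][s]: subsets of size k with sum offset s (offset against k-minimum)
    dp = np.zeros((nx + 1, max_sum + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in range(1, n + 1):
        for k in range(min(r, nx), 0, -1):
            dp[k, r:] += dp[k - 1, : max_sum + 1 - r]
    return dp[nx, min_sum : max_sum + 1].copy(), min_sum


def wilcoxon_rank_sum(x, y, exact_limit: int = 20) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null by enumeration of rank assignments when the combined sample
    size is <= ``exact_limit`` and there are no ties; otherwise a normal
    approximation with midranks, tie-corrected variance and a 0.5 continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    n = nx + ny
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks
    w = float(ranks[:nx].sum())
    has_ties = len(np.unique(pooled)) < n
    mean_w = nx * (n + 1) / 2.0

    if n <= exact_limit and not has_ties:
        counts, min_sum = _ranksum_null_counts(nx, n)
        total = counts.sum()
        sums = np.arange(min_sum, min_sum + counts.size)
        dev = abs(w - mean_w)
        p = counts[np.abs(sums - mean_w) >= dev - 1e-9].sum() / total
        return TestResult(statistic=w, p_value=float(min(p, 1.0)), method="exact", n=(nx, ny))

    # tie-corrected variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts)).sum())
    var_w = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w <= 0:
        return TestResult(statistic=w, p_value=1.0, method="approximate", n=(nx, ny))
    dev = abs(w - mean_w)
    z = max(dev - 0.5, 0.0) / sqrt(var_w)
    p = 2.0 * sps.norm.sf(z)
    return TestResult(statistic=w, p_value=float(min(p, 1.0)), method="approximate", n=(nx, ny))


def two_sample_t(x, y, welch: bool = False) -> TestResult:
    """Two-tailed two-sample t test (Student pooled-variance by default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs >= 2 observations")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if welch:
        se2 = vx / nx + vy / ny
        if se2 == 0:
            return TestResult(0.0, 1.0, "welch", (nx, ny))
        t = (mx - my) / sqrt(se2)
        df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
        method = "welch"
    else:
        df = nx + ny - 2
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / df
        if sp2 == 0:
            return TestResult(0.0, 1.0, "student", (nx, ny))
        t = (mx - my) / sqrt(sp2 * (1.0 / nx + 1.0 / ny))
        method = "student"
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(statistic=float(t), p_value=float(min(p, 1.0)), method=method, n=(nx, ny))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR correction, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d array of p-values")
    if ((p < 0) | (p > 1)).any() or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def wilcoxon_signed_rank(deltas, exact_limit: int = 25) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped. Exact null by enumeration of the 2^n sign
    assignments (via subset-sum convolution) for n <= ``exact_limit``; above
    that, normal approximation with tie correction and continuity correction.
    """
    d = np.asarray(deltas, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(statistic=0.0, p_value=1.0, method="degenerate", n=(0,))
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mean_w = n * (n + 1) / 4.0

    if n <= exact_limit:
        # work in doubled-rank integers so midranks stay exact
        r2 = np.rint(ranks * 2).astype(int)
        max_sum = int(r2.sum())
        counts = np.zeros(max_sum + 1)
        counts[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[: max_sum + 1 - r]
            counts = counts + shifted
        sums = np.arange(max_sum + 1) / 2.0
        dev = abs(w_plus - mean_w)
        p = counts[np.abs(sums - mean_w) >= dev - 1e-9].sum() / counts.sum()
        return TestResult(statistic=w_plus, p_value=float(min(p, 1.0)), method="exact", n=(n,))

    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - float((tie_counts ** 3 - tie_counts).sum()) / 48.0
    if var_w <= 0:
        return TestResult(statistic=w_plus, p_value=1.0, method="degenerate", n=(n,))
    z = max(abs(w_plus - mean_w) - 0.5, 0.0) / sqrt(var_w)
    p = 2.0 * sps.norm.sf(z)
    return TestResult(statistic=w_plus, p_value=float(min(p, 1.0)), method="approximate", n=(n,))
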