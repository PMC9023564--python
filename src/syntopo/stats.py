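"""Statistical kernels shared across the pipeline.

Two tests recur everywhere in this analysis: the two-sided Wilcoxon
rank-sum (Mann-Whitney) test comparing block-level statistics between
synteny classes, and Fisher's exact test on 2x2 category tables.

``rank_sum_test`` computes the exact tie-aware permutation p-value via a
subset-sum dynamic program when both samples are small, and otherwise uses
the normal approximation with continuity and tie correction (scipy's
asymptotic Mann-Whitney path). Fisher's exact test delegates to scipy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

# exact path when total sample size is at most this
_EXACT_MAX_TOTAL = 40


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    method: str


def rank_sum_test(x, y, method: str = "auto") -> TestResult:
    """Two-sided Wilcoxon rank-sum test.

    Parameters
    ----------
    x, y
        The two samples.
    method
        ``"exact"`` (tie-aware permutation distribution), ``"asymptotic"``
        (normal approximation with continuity and tie correction), or
        ``"auto"`` (exact when ``len(x)+len(y) <= 40``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    if method == "auto":
        method = "exact" if n1 + n2 <= _EXACT_MAX_TOTAL else "asymptotic"
    if method == "exact":
        return _rank_sum_exact(x, y)
    if method == "asymptotic":
        res = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        return TestResult(float(res.statistic), float(res.pvalue), "asymptotic")
    raise ValueError(f"unknown method {method!r}")


def _rank_sum_exact(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Exact permutation distribution of the rank sum, ties included.

    Mid-ranks are doubled to integers; a DP over (subset size, rank sum)
    counts, for every achievable sum, the number of size-``n1`` subsets of
    the pooled ranks attaining it. Two-sided p = min(1, 2*min(P(T<=t),
    P(T>=t))) under the uniform distribution over subsets.
    """
    n1 = len(x)
    pooled = np.concatenate([x, y])
    ranks2 = np.rint(2 * sps.rankdata(pooled)).astype(np.int64)
    t_obs = int(ranks2[:n1].sum())

    max_sum = int(ranks2.sum())
    # dp[k, s] = number of k-subsets with doubled-rank sum s
    dp = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in ranks2:
        hi = min(n1, len(ranks2))
        for k in range(hi - 1, -1, -1):
            row = dp[k]
            nz = np.nonzero(row)[0]
            if nz.size:
                dp[k + 1, nz + r] += row[nz]
    dist = dp[n1]
    total = dist.sum()
    cdf = dist[: t_obs + 1].sum() / total
    sf = dist[t_obs:].sum() / total
    p = min(1.0, 2.0 * min(cdf, sf))
    u = t_obs / 2.0 - n1 * (n1 + 1) / 2.0
    return TestResult(float(u), float(p), "exact")


def fisher_exact_test(table) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table.

    Returns the conditional odds ratio as the statistic.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (table < 0).any():
        raise ValueError("table entries must be non-negative")
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return TestResult(float(odds), float(p), "fisher-exact")
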