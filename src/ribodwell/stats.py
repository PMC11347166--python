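"""Shared nonparametric statistics.

Rank tests use exact permutation distributions (computed by dynamic
programming over the rank multiset, so ties are handled exactly) up to a
combined sample size threshold, and a tie-corrected normal approximation
with continuity correction above it.  Two-sided exact p-values are defined
as ``P(|T - E[T]| >= |t - E[T]|)`` under the permutation null.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats as sps

DEFAULT_EXACT_MAX_N = 20


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(n)
    out[order] = q
    return out


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _perm_sum_distribution(scores2: np.ndarray, nx: int) -> dict[int, int]:
    """Number of size-``nx`` subsets of ``scores2`` (integers) per subset sum."""
    # dp[k] maps sum -> count over subsets of size k
    dp: list[dict[int, int]] = [dict() for _ in range(nx + 1)]
    dp[0][0] = 1
    for s in scores2:
        s = int(s)
        for k in range(min(nx, len(dp)) - 1, -1, -1):
            if not dp[k]:
                continue
            tgt = dp[k + 1]
            for total, cnt in dp[k].items():
                tgt[total + s] = tgt.get(total + s, 0) + cnt
    return dp[nx]


def _exact_two_sided_p(scores: np.ndarray, nx: int, observed: float) -> float:
    """Exact permutation two-sided p for the sum of ``nx`` scores."""
    scores2 = np.round(scores * 2).astype(np.int64)  # mid-ranks are half-integers
    dist = _perm_sum_distribution(scores2, nx)
    total = sum(dist.values())
    mean2 = scores2.sum() * nx / len(scores2)
    obs_dev = abs(observed * 2 - mean2)
    hits = sum(c for s, c in dist.items() if abs(s - mean2) >= obs_dev - 1e-9)
    return hits / total


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    exact_max_n: int = DEFAULT_EXACT_MAX_N,
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum / Mann-Whitney test.

    Returns ``(U, p)`` where U is the Mann-Whitney statistic for ``x``.
    Exact permutation null (mid-ranks, ties exact) when the combined size
    is at most ``exact_max_n``; otherwise normal approximation with tie
    correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("rank_sum_test requires two non-empty groups")
    combined = np.concatenate([x, y])
    ranks = _midranks(combined)
    w = float(ranks[:nx].sum())
    u = w - nx * (nx + 1) / 2.0
    n = nx + ny
    if n <= exact_max_n:
        p = _exact_two_sided_p(ranks, nx, w)
        return u, min(p, 1.0)
    mean_w = nx * (n + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n) * (n - 1))
    var_w = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return u, 1.0
    z = (abs(w - mean_w) - 0.5) / np.sqrt(var_w)
    z = max(z, 0.0)
    return u, float(min(2 * sps.norm.sf(z), 1.0))


def _ab_scores(ranks: np.ndarray, n: int) -> np.ndarray:
    return np.minimum(ranks, n + 1 - ranks)


def ansari_bradley_test(
    x: Sequence[float],
    y: Sequence[float],
    exact_max_n: int = DEFAULT_EXACT_MAX_N,
) -> tuple[float, float]:
    """Two-sided Ansari-Bradley test of equal dispersion (scale).

    Returns ``(AB, p)`` with AB the sum of Ansari scores of ``x``.  Exact
    permutation null for combined size at most ``exact_max_n``; otherwise a
    normal approximation using the exact permutation mean and variance of
    the score sum (correct under ties).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("ansari_bradley_test requires two non-empty groups")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        raise ValueError("scale test undefined: all observations identical")
    if np.all(x == x[0]) and np.all(y == y[0]):
        raise ValueError("scale test undefined: both groups constant-valued")
    n = nx + ny
    ranks = _midranks(combined)
    scores = _ab_scores(ranks, n)
    ab = float(scores[:nx].sum())
    if n <= exact_max_n:
        p = _exact_two_sided_p(scores, nx, ab)
        return ab, min(p, 1.0)
    mean = nx * scores.mean()
    var = nx * ny / (n * (n - 1)) * ((scores - scores.mean()) ** 2).sum()
    if var <= 0:
        return ab, 1.0
    z = abs(ab - mean) / np.sqrt(var)
    return ab, float(min(2 * sps.norm.sf(z), 1.0))


def binomial_enrichment(k: int, n: int, background_p: float) -> tuple[float, float]:
    """Fold enrichment and exact upper-tail binomial p for ``X >= k``."""
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    if not (0 < background_p < 1):
        raise ValueError("background_p must be in (0, 1)")
    fold = (k / n) / background_p if n > 0 else np.nan
    p = float(sps.binomtest(k, n, background_p, alternative="greater").pvalue)
    return fold, p
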