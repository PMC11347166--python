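"""Independent brute-force oracles used by the test suite.

Deliberately written with plain Python loops and a different code path from
the package (no shared helpers), so agreement is evidence of correctness
rather than tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import minimize


# ---------------------------------------------------------------------------
# dwell-time estimation by direct position enumeration
# ---------------------------------------------------------------------------

def brute_dwell(
    counts_by_tx: dict[str, list[int]],
    cds_by_tx: dict[str, str],
    min_tx_coverage: float = 0.5,
    trim_start: int = 20,
    trim_end: int = 10,
    condition: tuple[str, int] | None = None,
    min_positions: int = 3,
) -> dict[str, float]:
    """Codon -> dwell via explicit loops; returns only non-missing codons,
    renormalized to mean 1."""
    from Bio.Seq import Seq

    sums: dict[str, float] = {}
    npos: dict[str, int] = {}
    for tx_id, cds in cds_by_tx.items():
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        protein = str(Seq(cds[:-3]).translate())
        counts = counts_by_tx.get(tx_id, [0] * len(codons))
        lo, hi = trim_start, len(codons) - 1 - trim_end
        window = list(range(lo, hi))
        if not window:
            continue
        mean = sum(counts[i] for i in window) / len(window)
        if mean < min_tx_coverage or mean <= 0:
            continue
        for i in window:
            if codons[i] in ("TAA", "TAG", "TGA"):
                continue
            if condition is not None:
                aa, d = condition
                j = i - d
                if j < 0 or protein[j] != aa:
                    continue
            c = codons[i]
            sums[c] = sums.get(c, 0.0) + counts[i] / mean
            npos[c] = npos.get(c, 0) + 1
    vals = {c: sums[c] / npos[c] for c in sums if npos[c] >= min_positions}
    if not vals:
        return {}
    m = sum(vals.values()) / len(vals)
    return {c: v / m for c, v in vals.items()}


def brute_effect_positions(
    cds: str, aa: str, offset: int, codons: set[str]
) -> list[int]:
    """Codon indices where a planted (aa, offset, codons) effect applies."""
    from Bio.Seq import Seq

    cods = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    protein = str(Seq(cds[:-3]).translate())
    out = []
    for i in range(len(cods)):
        j = i - offset
        if j < 0 or j >= len(protein):
            continue
        if protein[j] == aa and cods[i] in codons:
            out.append(i)
    return out


# ---------------------------------------------------------------------------
# exact permutation rank tests by exhaustive enumeration
# ---------------------------------------------------------------------------

def _midranks_plain(values: list[float]) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def enum_rank_sum_p(x: list[float], y: list[float]) -> float:
    """Two-sided exact permutation p for the rank sum of x:
    P(|W - E[W]| >= |w - E[W]|) by enumerating all group assignments."""
    nx = len(x)
    combined = list(x) + list(y)
    ranks = _midranks_plain(combined)
    w_obs = sum(ranks[:nx])
    mean_w = nx * sum(ranks) / len(ranks)
    obs_dev = abs(w_obs - mean_w)
    hits = total = 0
    for idx in itertools.combinations(range(len(combined)), nx):
        w = sum(ranks[i] for i in idx)
        total += 1
        if abs(w - mean_w) >= obs_dev - 1e-9:
            hits += 1
    return hits / total


def enum_ansari_p(x: list[float], y: list[float]) -> float:
    """Two-sided exact permutation p for the Ansari-Bradley score sum."""
    nx = len(x)
    combined = list(x) + list(y)
    n = len(combined)
    ranks = _midranks_plain(combined)
    scores = [min(r, n + 1 - r) for r in ranks]
    obs = sum(scores[:nx])
    mean = nx * sum(scores) / n
    obs_dev = abs(obs - mean)
    hits = total = 0
    for idx in itertools.combinations(range(n), nx):
        s = sum(scores[i] for i in idx)
        total += 1
        if abs(s - mean) >= obs_dev - 1e-9:
            hits += 1
    return hits / total


def textbook_bh(pvalues: list[float]) -> list[float]:
    """BH step-up, straight from the definition."""
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    adjusted = [0.0] * n
    prev = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        q = min(prev, pvalues[i] * n / rank_from_top)
        adjusted[i] = q
        prev = q
    return adjusted


# ---------------------------------------------------------------------------
# NB GLM by numeric optimization (no IRLS)
# ---------------------------------------------------------------------------

def _nb_logpmf(y: float, mu: float, alpha: float) -> float:
    inv = 1.0 / alpha
    return (
        math.lgamma(y + inv)
        - math.lgamma(inv)
        - math.lgamma(y + 1)
        + inv * math.log(inv / (inv + mu))
        + y * math.log(mu / (inv + mu))
    )


def numeric_nb_fit(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray, n_alpha_grid: int = 241
) -> tuple[np.ndarray, float, float, float]:
    """Maximize the Cox-Reid adjusted NB profile likelihood over a dense
    alpha grid with numeric (BFGS) inner optimization, then compute the
    interaction Wald statistic from the expected-information covariance.

    Returns (beta_hat, alpha_hat, wald_stat, se_log2).
    """

    def negll(beta: np.ndarray, alpha: float) -> float:
        mu = np.exp(X @ beta + offset)
        return -sum(_nb_logpmf(float(yi), float(mi), alpha) for yi, mi in zip(y, mu))

    def cr_adjusted(alpha: float) -> tuple[float, np.ndarray]:
        beta0 = np.linalg.lstsq(X, np.log(y + 0.5) - offset, rcond=None)[0]
        res = minimize(negll, beta0, args=(alpha,), method="BFGS",
                       options={"gtol": 1e-10, "maxiter": 500})
        mu = np.exp(X @ res.x + offset)
        W = mu / (1.0 + alpha * mu)
        _, logdet = np.linalg.slogdet((X.T * W) @ X)
        return -res.fun - 0.5 * logdet, res.x

    grid = np.logspace(-8, 2, n_alpha_grid)
    best = (-np.inf, None, None)
    for a in grid:
        apl, beta = cr_adjusted(a)
        if apl > best[0]:
            best = (apl, a, beta)
    # iterative grid zoom around the optimum
    spacing = 10 / (n_alpha_grid - 1)
    for _ in range(3):
        _, alpha_hat, _ = best
        lo = np.log10(alpha_hat) - spacing
        hi = np.log10(alpha_hat) + spacing
        for a in np.logspace(lo, hi, 41):
            apl, beta = cr_adjusted(a)
            if apl > best[0]:
                best = (apl, a, beta)
        spacing /= 20
    _, alpha_hat, beta_hat = best
    mu = np.exp(X @ beta_hat + offset)
    W = mu / (1.0 + alpha_hat * mu)
    cov = np.linalg.inv((X.T * W) @ X)
    se = math.sqrt(cov[3, 3])
    return beta_hat, alpha_hat, beta_hat[3] / se, se / math.log(2)
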