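"""Positional enrichment of protein domain intervals.

Each protein's domain annotation (0-based half-open residue intervals) is
converted to a per-bin coverage-fraction vector over its relative sequence
position; target and non-target sets are then compared bin by bin.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .stats import binomial_enrichment, rank_sum_test

DEFAULT_N_BINS = 100


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals; drops empty ones."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def positional_fraction(
    intervals: Sequence[tuple[int, int]],
    length: int,
    n_bins: int = DEFAULT_N_BINS,
) -> np.ndarray:
    """Fraction of residues covered by intervals, per relative-position bin.

    Residue r maps to bin ``floor(n_bins * r / length)``, clamped to the
    last bin; a bin's fraction is covered residues over total residues in
    that bin.  Empty bins (possible when ``length < n_bins``) are 0.
    """
    if length <= 0:
        raise ValueError("protein length must be positive")
    merged = merge_intervals(intervals)
    for s, e in merged:
        if s < 0 or e > length:
            raise ValueError(f"interval [{s}, {e}) outside [0, {length})")
    bins = np.minimum((n_bins * np.arange(length)) // length, n_bins - 1)
    per_bin_total = np.bincount(bins, minlength=n_bins).astype(float)
    covered = np.zeros(length, dtype=bool)
    for s, e in merged:
        covered[s:e] = True
    per_bin_covered = np.bincount(bins[covered], minlength=n_bins).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(per_bin_total > 0, per_bin_covered / per_bin_total, 0.0)
    return frac


def fraction_matrix(
    domain_table: pd.DataFrame, n_bins: int = DEFAULT_N_BINS
) -> pd.DataFrame:
    """Per-protein bin-fraction vectors from an interval table with columns
    ``protein_id  start  end  length``."""
    rows = {}
    for pid, sub in domain_table.groupby("protein_id", sort=False):
        length = int(sub["length"].iloc[0])
        ivs = [(int(s), int(e)) for s, e in zip(sub["start"], sub["end"])]
        rows[pid] = positional_fraction(ivs, length, n_bins)
    return pd.DataFrame.from_dict(rows, orient="index", columns=range(n_bins))


def binned_mannwhitney(
    target: np.ndarray | pd.DataFrame,
    nontarget: np.ndarray | pd.DataFrame,
) -> pd.DataFrame:
    """Per-bin two-sided Mann-Whitney U of target vs non-target fractions.

    Inputs are proteins x bins matrices.  Returns columns ``bin, U,
    pvalue`` — one test per bin, displayed uncorrected.
    """
    t = np.asarray(target, dtype=float)
    nt = np.asarray(nontarget, dtype=float)
    if t.ndim != 2 or nt.ndim != 2 or t.shape[1] != nt.shape[1]:
        raise ValueError("target and nontarget must be proteins x bins with equal bins")
    if t.shape[0] == 0 or nt.shape[0] == 0:
        raise ValueError("both groups must be non-empty")
    rows = []
    for j in range(t.shape[1]):
        u, p = rank_sum_test(t[:, j], nt[:, j])
        rows.append((j, u, p))
    return pd.DataFrame(rows, columns=["bin", "U", "pvalue"])


def cterm_half_test(
    target: np.ndarray | pd.DataFrame,
    nontarget: np.ndarray | pd.DataFrame,
) -> tuple[float, float]:
    """Single Mann-Whitney test of per-protein mean fractions over the
    C-terminal half of the bins (bins >= n_bins/2)."""
    t = np.asarray(target, dtype=float)
    nt = np.asarray(nontarget, dtype=float)
    half = t.shape[1] // 2
    return rank_sum_test(t[:, half:].mean(axis=1), nt[:, half:].mean(axis=1))


def proportion_enrichment(
    k: int, n: int, background_p: float
) -> tuple[float, float]:
    """Fold enrichment of k/n over a background proportion with the exact
    upper-tail binomial p-value for ``X >= k``."""
    return binomial_enrichment(k, n, background_p)
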