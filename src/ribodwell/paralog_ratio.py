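"""Core-RP selection and paralog-to-core expression-ratio statistics.

A small set of "core" ribosomal proteins — rRNA-embedded, early-assembling,
conserved across taxa, paralog-free and not tissue-specific — serves as a
within-sample normalization reference; a focal paralog's expression is
summarized as the log2 ratio of its RPK to the median core-RP RPK.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import ansari_bradley_test, bh_adjust, rank_sum_test

CORE_CRITERIA = (
    "rrna_embedded",
    "early_assembly",
    "cross_taxa",
    "strong_paralog",
    "tissue_specific",
)


def select_core_rps(meta: pd.DataFrame) -> list[str]:
    """Genes passing all five stringency criteria.

    ``meta`` is indexed by gene with boolean columns ``rrna_embedded``,
    ``early_assembly``, ``cross_taxa``, ``strong_paralog`` (DIOPT-like),
    and ``tissue_specific``.  A core RP must satisfy the first three and
    fail the last two.
    """
    missing = [c for c in CORE_CRITERIA if c not in meta.columns]
    if missing:
        raise KeyError(f"metadata missing criterion columns: {missing}")
    passed = (
        meta["rrna_embedded"].astype(bool)
        & meta["early_assembly"].astype(bool)
        & meta["cross_taxa"].astype(bool)
        & ~meta["strong_paralog"].astype(bool)
        & ~meta["tissue_specific"].astype(bool)
    )
    core = list(meta.index[passed])
    if not core:
        raise ValueError(
            "no gene passes all five core-RP criteria; relax a criterion or "
            "check the metadata flags"
        )
    return core


def weighted_gene_length(
    transcript_lengths: Sequence[float], transcript_tpms: Sequence[float]
) -> float:
    """TPM-weighted average transcript length; falls back to the unweighted
    mean (with a warning) when every TPM is zero."""
    lengths = np.asarray(transcript_lengths, dtype=float)
    tpms = np.asarray(transcript_tpms, dtype=float)
    if lengths.shape != tpms.shape or lengths.size == 0:
        raise ValueError("lengths and TPMs must be non-empty and aligned")
    if (tpms < 0).any():
        raise ValueError("TPM values must be non-negative")
    total = tpms.sum()
    if total == 0:
        warnings.warn(
            "all transcript TPMs are zero; using the unweighted mean length",
            stacklevel=2,
        )
        return float(lengths.mean())
    return float((lengths * tpms).sum() / total)


def rpk(raw_count: float, gene_length_nt: float, pseudocount: float = 1.0) -> float:
    """Reads per kilobase: ``(count + pseudocount) / (length_nt / 1000)``."""
    if gene_length_nt <= 0:
        raise ValueError("gene length must be positive")
    return (raw_count + pseudocount) / (gene_length_nt / 1000.0)


def ratio_to_core(
    sample_rpks: Mapping[str, float], focal_gene: str, core_set: Sequence[str]
) -> float:
    """log2 of the focal gene's RPK over the median core-RP RPK."""
    if focal_gene not in sample_rpks:
        raise KeyError(f"no RPK value for focal gene {focal_gene}")
    missing = [g for g in core_set if g not in sample_rpks]
    if missing:
        raise KeyError(f"no RPK value for core genes: {missing}")
    core_median = float(np.median([sample_rpks[g] for g in core_set]))
    if core_median <= 0:
        raise ValueError("median core RPK is not positive")
    return float(np.log2(sample_rpks[focal_gene] / core_median))


def ratio_table(
    counts: pd.DataFrame,
    gene_lengths: Mapping[str, float],
    focal_gene: str,
    core_set: Sequence[str],
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-sample log2 focal-to-core ratios from a genes x samples count
    table."""
    out = {}
    for sample in counts.columns:
        rpks = {
            g: rpk(counts.at[g, sample], gene_lengths[g], pseudocount)
            for g in [focal_gene, *core_set]
        }
        out[sample] = ratio_to_core(rpks, focal_gene, core_set)
    return pd.Series(out, name=f"{focal_gene}_to_core_log2")


def group_ratio_tests(
    ratios_by_group: Mapping[str, Sequence[float]],
    reference_group: str,
) -> pd.DataFrame:
    """Each group's ratios vs the pooled reference by two-sided rank-sum.

    Returns a table with columns ``group, n, median_diff, direction, U,
    pvalue, padj``; empty groups are excluded with a warning, BH is applied
    across the tested groups.
    """
    if reference_group not in ratios_by_group:
        raise KeyError(f"reference group {reference_group!r} not present")
    reference = np.asarray(ratios_by_group[reference_group], dtype=float)
    if reference.size == 0:
        raise ValueError("reference group is empty")
    rows = []
    for group, values in ratios_by_group.items():
        if group == reference_group:
            continue
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            warnings.warn(f"group {group!r} is empty; excluded from testing", stacklevel=2)
            continue
        u, p = rank_sum_test(values, reference)
        diff = float(np.median(values) - np.median(reference))
        direction = "up" if diff > 0 else ("down" if diff < 0 else "none")
        rows.append((group, len(values), diff, direction, u, p))
    out = pd.DataFrame(
        rows, columns=["group", "n", "median_diff", "direction", "U", "pvalue"]
    )
    out["padj"] = bh_adjust(out["pvalue"].to_numpy()) if len(out) else []
    return out


def dispersion_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Ansari-Bradley two-sample scale test; ``(statistic, p)``."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size and np.all(a == a[0]):
        raise ValueError("group_a is constant-valued; scale test undefined")
    if b.size and np.all(b == b[0]):
        raise ValueError("group_b is constant-valued; scale test undefined")
    return ansari_bradley_test(a, b)


def coexpression_fraction(
    cell_counts: pd.DataFrame, gene_a: str, gene_b: str
) -> float:
    """Proportion of ``gene_a``-positive cells that also express ``gene_b``.

    ``cell_counts`` is genes x cells.  NaN when no cell expresses
    ``gene_a``.
    """
    for g in (gene_a, gene_b):
        if g not in cell_counts.index:
            raise KeyError(f"gene {g} not in count table")
    a_pos = cell_counts.loc[gene_a] > 0
    n_a = int(a_pos.sum())
    if n_a == 0:
        return float("nan")
    both = int(((cell_counts.loc[gene_b] > 0) & a_pos).sum())
    return both / n_a
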