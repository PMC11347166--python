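"""Conditional codon dwell times and the cross-clone consistency grid.

The dwell time of a codon is estimated as the mean, over qualifying codon
positions carrying that codon, of the per-transcript mean-normalized
footprint density.  A condition ``(aa, offset)`` restricts qualifying
positions to those where the nascent-chain residue ``offset`` codons
upstream of the P site (protein position ``i - offset``) equals ``aa``;
positions with ``i - offset < 0`` are excluded.  Offset 0 is the P-site
codon's own residue.

For the grid scan, each KO clone's conditioned dwell change relative to the
pooled WT mean is summarized per (amino acid, offset) cell by the average
cosine similarity over all clone pairs; consistent changes across
independent clones light up a single cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import CodonCoverage
from .io import provenance_line
from .synthio import DesignTable
from .transcripts import AA_INDEX, AMINO_ACIDS, SENSE_CODONS, TranscriptSet

N_CODONS = len(SENSE_CODONS)  # 61
N_AA = len(AMINO_ACIDS)  # 20

DEFAULT_TRIM_START = 20
DEFAULT_TRIM_END = 10
DEFAULT_MIN_TX_COVERAGE = 0.5
DEFAULT_MIN_POSITIONS = 3
DEFAULT_OFFSETS = range(20, 46)


@dataclass
class DwellTimeVector:
    """Relative dwell per sense codon, mean 1 over non-missing codons.

    ``values[k]`` is NaN (missing, not zero) when fewer than the
    position-count floor of qualifying positions carried codon k.
    """

    values: np.ndarray  # (61,) float, NaN = missing
    n_positions: np.ndarray  # (61,) int
    condition: tuple[str, int] | None = None
    sample_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.n_positions = np.asarray(self.n_positions, dtype=np.int64)
        if self.values.shape != (N_CODONS,) or self.n_positions.shape != (N_CODONS,):
            raise ValueError("dwell vectors are indexed by the 61 sense codons")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(SENSE_CODONS))

    def __getitem__(self, codon: str) -> float:
        return float(self.values[SENSE_CODONS.index(codon)])


# ---------------------------------------------------------------------------
# positional index over a transcript set (built once, reused across samples)
# ---------------------------------------------------------------------------

class _PositionIndex:
    """Flattened qualifying codon positions of a transcript set.

    Per position: transcript row, codon index i, sense-codon code, and the
    global index of residue i in the concatenated protein sequence.  The
    analysis window per transcript is ``[trim_start, n_codons - 1 -
    trim_end)`` — the stop codon is always excluded.
    """

    def __init__(self, tx: TranscriptSet, trim_start: int, trim_end: int) -> None:
        self.tx_ids: list[str] = []
        tx_idx, i_idx, codon, prot = [], [], [], []
        prot_ids = []
        prot_start = 0
        self.windows: list[tuple[int, int]] = []
        for row, t in enumerate(tx):
            lo, hi = trim_start, t.n_codons - 1 - trim_end
            self.tx_ids.append(t.transcript_id)
            self.windows.append((lo, hi))
            rid = t.residue_ids()
            prot_ids.append(rid)
            if hi > lo:
                cid = t.codon_ids()[lo:hi]
                n = hi - lo
                tx_idx.append(np.full(n, row))
                i_idx.append(np.arange(lo, hi))
                codon.append(cid)
                prot.append(prot_start + np.arange(lo, hi))
            prot_start += len(rid)
        if not tx_idx:
            raise ValueError("no transcript has a non-empty analysis window")
        self.tx_idx = np.concatenate(tx_idx)
        self.i_idx = np.concatenate(i_idx)
        self.codon = np.concatenate(codon)
        self.prot_pos = np.concatenate(prot)
        self.prot_ids = np.concatenate(prot_ids)
        self.window_len = np.array([hi - lo for lo, hi in self.windows], dtype=float)

    def sample_density(
        self, coverage: CodonCoverage, min_tx_coverage: float
    ) -> tuple[np.ndarray, np.ndarray]:
        """(normalized density, validity mask) per flattened position."""
        counts = np.zeros(len(self.tx_idx), dtype=float)
        pos = 0
        means = np.zeros(len(self.tx_ids))
        for row, (tx_id, (lo, hi)) in enumerate(zip(self.tx_ids, self.windows)):
            n = max(hi - lo, 0)
            if n == 0:
                continue
            if tx_id in coverage:
                seg = coverage[tx_id][lo:hi]
                counts[pos : pos + n] = seg
                means[row] = seg.mean()
            pos += n
        keep = (means >= min_tx_coverage) & (means > 0)
        mean_per_pos = means[self.tx_idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            norm = np.where(mean_per_pos > 0, counts / mean_per_pos, 0.0)
        return norm, keep[self.tx_idx]

    def conditioned_sums(
        self, norm: np.ndarray, valid: np.ndarray, offset: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per (residue-at-offset, codon): sum of normalized density and
        position counts, shape (20, 61) each."""
        mask = valid & (self.i_idx >= offset)
        res = self.prot_ids[self.prot_pos[mask] - offset]
        key = res * N_CODONS + self.codon[mask]
        sums = np.bincount(key, weights=norm[mask], minlength=N_AA * N_CODONS)
        cnts = np.bincount(key, minlength=N_AA * N_CODONS)
        return sums.reshape(N_AA, N_CODONS), cnts.reshape(N_AA, N_CODONS)

    def unconditioned_sums(
        self, norm: np.ndarray, valid: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        sums = np.bincount(self.codon[valid], weights=norm[valid], minlength=N_CODONS)
        cnts = np.bincount(self.codon[valid], minlength=N_CODONS)
        return sums, cnts


def _nanmean_stack(vectors: Sequence[np.ndarray]) -> np.ndarray:
    """Column-wise nanmean; all-NaN columns stay NaN without warnings."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(np.stack(vectors), axis=0)


def _finalize_vector(
    sums: np.ndarray, cnts: np.ndarray, min_positions: int
) -> tuple[np.ndarray, np.ndarray]:
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(cnts >= max(min_positions, 1), sums / cnts, np.nan)
    m = np.nanmean(vals) if np.isfinite(vals).any() else np.nan
    if np.isfinite(m) and m > 0:
        vals = vals / m
    return vals, cnts.astype(np.int64)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def dwell_times(
    coverage: CodonCoverage,
    tx: TranscriptSet,
    min_tx_coverage: float = DEFAULT_MIN_TX_COVERAGE,
    trim_start: int = DEFAULT_TRIM_START,
    trim_end: int = DEFAULT_TRIM_END,
    condition: tuple[str, int] | None = None,
    min_positions: int = DEFAULT_MIN_POSITIONS,
) -> DwellTimeVector:
    """Per-codon relative dwell times for one sample.

    Transcripts whose mean count over the analysis window is below
    ``min_tx_coverage`` are excluded; the first ``trim_start`` and last
    ``trim_end`` codons (plus the stop codon) never contribute.  The
    returned vector has mean 1 over non-missing codons.
    """
    index = _PositionIndex(tx, trim_start, trim_end)
    norm, valid = index.sample_density(coverage, min_tx_coverage)
    if condition is None:
        sums, cnts = index.unconditioned_sums(norm, valid)
    else:
        aa, offset = condition
        if aa not in AA_INDEX:
            raise ValueError(f"unknown amino acid {aa!r}")
        if offset < 0:
            raise ValueError("condition offset must be >= 0")
        s2, c2 = index.conditioned_sums(norm, valid, offset)
        sums, cnts = s2[AA_INDEX[aa]], c2[AA_INDEX[aa]]
    vals, cnts = _finalize_vector(sums, cnts, min_positions)
    if not np.isfinite(vals).any():
        cond = "unconditioned" if condition is None else f"condition {condition}"
        raise ValueError(
            f"no codon has enough qualifying positions ({cond}); "
            "relax the trims, coverage floor, or position floor"
        )
    return DwellTimeVector(vals, cnts, condition=condition, sample_id=coverage.sample_id)


def dwell_change(
    clone_samples: Sequence[DwellTimeVector],
    wt_samples: Sequence[DwellTimeVector],
) -> np.ndarray:
    """Per-codon log2 change: replicate-mean clone dwell over replicate-mean
    WT dwell.  Missing (NaN) wherever either group mean is missing."""
    if not clone_samples or not wt_samples:
        raise ValueError("both groups need at least one dwell vector")
    clone = _nanmean_stack([v.values for v in clone_samples])
    wt = _nanmean_stack([v.values for v in wt_samples])
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.log2(clone) - np.log2(wt)
    delta[~np.isfinite(delta)] = np.nan
    return delta


def cosine(u: np.ndarray, v: np.ndarray) -> float | None:
    """Cosine similarity over the intersection of non-missing codons; None
    when fewer than 2 codons are shared or either restricted vector has
    zero norm."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    common = np.isfinite(u) & np.isfinite(v)
    if common.sum() < 2:
        return None
    uu, vv = u[common], v[common]
    nu, nv = np.linalg.norm(uu), np.linalg.norm(vv)
    if nu == 0 or nv == 0:
        return None
    return float(np.dot(uu, vv) / (nu * nv))


@dataclass
class DwellChangeGrid:
    """Amino acid x offset matrix of mean pairwise clone cosine similarity."""

    aa: list[str]
    offsets: list[int]
    values: np.ndarray  # (n_aa, n_offsets), NaN = missing
    pair_cosines: pd.DataFrame | None = None  # long format: aa, offset, clone_a, clone_b, cosine
    clone_deltas: dict | None = None  # (aa, offset) -> {clone: delta vector}

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.aa, columns=self.offsets)

    def to_tsv(self, path: str | Path, params: Mapping | None = None) -> None:
        with open(path, "w") as fh:
            fh.write(provenance_line("dwell-grid", params) + "\n")
            self.as_frame().rename_axis("aa").to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DwellChangeGrid":
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        return cls(
            aa=[str(a) for a in df.index],
            offsets=[int(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
        )


def consistency_grid(
    coverages: Mapping[str, CodonCoverage],
    design: DesignTable,
    tx: TranscriptSet,
    offsets: Sequence[int] = DEFAULT_OFFSETS,
    aa_set: Sequence[str] = tuple(AMINO_ACIDS),
    min_tx_coverage: float = DEFAULT_MIN_TX_COVERAGE,
    trim_start: int = DEFAULT_TRIM_START,
    trim_end: int = DEFAULT_TRIM_END,
    min_positions: int = DEFAULT_MIN_POSITIONS,
    keep_details: bool = False,
) -> DwellChangeGrid:
    """Scan all (amino acid, offset) conditions for cross-clone consistency.

    Per cell: each KO clone's conditioned dwell vectors (replicates
    averaged) are compared to the pooled WT mean as a log2 change vector;
    the cell holds the arithmetic mean cosine similarity over all
    ``C(n_clones, 2)`` clone pairs.  Cells where any clone's change vector
    has fewer than 2 non-missing codons, or a pairwise cosine is undefined,
    are missing.
    """
    rpf = design.subset(assay="RPF")
    clones = rpf.clones("KO")
    if len(clones) < 2:
        raise ValueError(
            f"consistency requires >= 2 KO clones, found {len(clones)}"
        )
    wt_ids = [s.sample_id for s in rpf if s.genotype == "WT"]
    if not wt_ids:
        raise ValueError("no WT RPF samples in design")
    clone_ids = {
        c: [s.sample_id for s in rpf if s.genotype == "KO" and s.clone_id == c]
        for c in clones
    }
    missing = [
        sid
        for sid in wt_ids + [s for ids in clone_ids.values() for s in ids]
        if sid not in coverages
    ]
    if missing:
        raise KeyError(f"no coverage for samples: {missing[:5]}")

    offsets = [int(d) for d in offsets]
    aa_rows = [AA_INDEX[a] for a in aa_set]
    index = _PositionIndex(tx, trim_start, trim_end)

    # per sample, per offset: (20, 61) sum and count matrices
    per_sample: dict[str, dict[int, tuple[np.ndarray, np.ndarray]]] = {}
    all_ids = wt_ids + [s for ids in clone_ids.values() for s in ids]
    for sid in all_ids:
        norm, valid = index.sample_density(coverages[sid], min_tx_coverage)
        per_sample[sid] = {
            d: index.conditioned_sums(norm, valid, d) for d in offsets
        }

    def vector(sid: str, d: int, aa_row: int) -> np.ndarray:
        sums, cnts = per_sample[sid][d]
        vals, _ = _finalize_vector(sums[aa_row], cnts[aa_row], min_positions)
        return vals

    values = np.full((len(aa_set), len(offsets)), np.nan)
    pair_rows = []
    deltas_store: dict = {}
    for col, d in enumerate(offsets):
        for row, (aa, aa_row) in enumerate(zip(aa_set, aa_rows)):
            wt_vecs = [vector(sid, d, aa_row) for sid in wt_ids]
            wt_mean = _nanmean_stack(wt_vecs)
            deltas = {}
            ok = True
            for c in clones:
                cl_vecs = [vector(sid, d, aa_row) for sid in clone_ids[c]]
                cl_mean = _nanmean_stack(cl_vecs)
                with np.errstate(divide="ignore", invalid="ignore"):
                    delta = np.log2(cl_mean) - np.log2(wt_mean)
                delta[~np.isfinite(delta)] = np.nan
                if np.isfinite(delta).sum() < 2:
                    ok = False
                    break
                deltas[c] = delta
            if not ok:
                continue
            cosines = []
            for i in range(len(clones)):
                for j in range(i + 1, len(clones)):
                    cs = cosine(deltas[clones[i]], deltas[clones[j]])
                    if cs is None:
                        ok = False
                        break
                    cosines.append((clones[i], clones[j], cs))
                if not ok:
                    break
            if not ok:
                continue
            values[row, col] = float(np.mean([c for *_, c in cosines]))
            if keep_details:
                deltas_store[(aa, d)] = deltas
                for a, b, cs in cosines:
                    pair_rows.append((aa, d, a, b, cs))

    pair_df = (
        pd.DataFrame(pair_rows, columns=["aa", "offset", "clone_a", "clone_b", "cosine"])
        if keep_details
        else None
    )
    return DwellChangeGrid(
        aa=list(aa_set),
        offsets=offsets,
        values=values,
        pair_cosines=pair_df,
        clone_deltas=deltas_store if keep_details else None,
    )


def argmax_grid(grid: DwellChangeGrid) -> tuple[str, int, float]:
    """Cell with the highest consistency score; ties resolve to the
    lexicographically smallest (amino acid, offset)."""
    best: tuple[str, int, float] | None = None
    order = np.argsort(np.array(grid.aa, dtype=object), kind="stable")
    col_order = np.argsort(np.array(grid.offsets), kind="stable")
    for row in order:
        for col in col_order:
            d = grid.offsets[col]
            v = grid.values[row, col]
            if np.isnan(v):
                continue
            if best is None or v > best[2]:
                best = (grid.aa[row], d, float(v))
    if best is None:
        raise ValueError("all grid cells are missing")
    return best
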