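"""From raw footprint reads to codon-resolved, P-site-anchored coverage.

The P-site offset of a read length is the distance in nt from the read's
5' end to the first nucleotide of the codon occupying the P site.  Offsets
are inferred per read length from the start-codon metagene: under a
correct offset, no 5' end can fall further upstream of the annotated ATG
than the offset itself, so the 5'-most sustained peak of the windowed 5'
end histogram sits exactly at ``-offset``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from .coverage import CodonCoverage
from .io import provenance_line
from .transcripts import TranscriptSet

DEFAULT_ADAPTER = "AAAAAAAAAA"


# ---------------------------------------------------------------------------
# FASTQ trimming and filtering
# ---------------------------------------------------------------------------

@dataclass
class TrimFilterStats:
    n_input: int = 0
    n_kept: int = 0
    dropped_short: int = 0
    dropped_quality: int = 0
    dropped_ambiguous: int = 0

    @property
    def n_dropped(self) -> int:
        return self.dropped_short + self.dropped_quality + self.dropped_ambiguous


def _clip_adapter(seq: str, adapter: str) -> str:
    """Remove a 3' adapter: either a full internal occurrence (clip from the
    first match) or the longest read suffix that is a prefix of the adapter."""
    idx = seq.find(adapter)
    if idx != -1:
        return seq[:idx]
    for k in range(min(len(adapter), len(seq)) - 1, 0, -1):
        if seq.endswith(adapter[:k]):
            return seq[: len(seq) - k]
    return seq


def _quality_trim_3p(quals: Sequence[int], min_quality: int) -> int:
    """Length to keep after trimming low-quality bases from the 3' end."""
    n = len(quals)
    while n > 0 and quals[n - 1] < min_quality:
        n -= 1
    return n


def trim_filter_reads(
    reads: Iterable[SeqRecord],
    min_length: int = 20,
    min_quality: int = 20,
    min_quality_fraction: float = 0.90,
    adapter: str = DEFAULT_ADAPTER,
    drop_ambiguous: bool = True,
) -> tuple[list[SeqRecord], TrimFilterStats]:
    """Adapter clip, 3' quality trim, then length / quality-fraction filters.

    A read survives when, after trimming, it is at least ``min_length`` nt,
    contains no N (if ``drop_ambiguous``), and at least
    ``min_quality_fraction`` of its bases have phred quality >=
    ``min_quality``.  Reads lacking per-base qualities raise when quality
    filtering is requested.
    """
    stats = TrimFilterStats()
    kept: list[SeqRecord] = []
    for rec in reads:
        stats.n_input += 1
        quals = rec.letter_annotations.get("phred_quality")
        if quals is None and (min_quality > 0 or min_quality_fraction > 0):
            raise ValueError(
                f"read {rec.id} has no per-base qualities but quality filtering "
                "is enabled; disable it or supply FASTQ input"
            )
        seq = str(rec.seq)
        clipped = _clip_adapter(seq, adapter) if adapter else seq
        q = list(quals[: len(clipped)]) if quals is not None else None
        if q is not None:
            keep_n = _quality_trim_3p(q, min_quality)
            clipped, q = clipped[:keep_n], q[:keep_n]
        if len(clipped) < min_length:
            stats.dropped_short += 1
            continue
        if drop_ambiguous and "N" in clipped.upper():
            stats.dropped_ambiguous += 1
            continue
        if q is not None:
            frac = float(np.mean(np.asarray(q) >= min_quality)) if q else 0.0
            if frac < min_quality_fraction:
                stats.dropped_quality += 1
                continue
        out = SeqRecord(rec.seq[: len(clipped)], id=rec.id, description="")
        if q is not None:
            out.letter_annotations["phred_quality"] = q
        kept.append(out)
        stats.n_kept += 1
    return kept, stats


def read_fastq(path: str | Path) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fastq"))


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


# ---------------------------------------------------------------------------
# P-site offset inference
# ---------------------------------------------------------------------------

@dataclass
class PSiteOffsets:
    """Per-read-length P-site offsets with support counts.

    ``offsets`` maps read length (nt) to the 5'-end-to-P-site distance (nt);
    ``support`` counts reads per length; lengths in ``discarded`` failed the
    support minimum and carry no offset.
    """

    offsets: dict[int, int] = field(default_factory=dict)
    support: dict[int, int] = field(default_factory=dict)
    discarded: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        for L, off in self.offsets.items():
            if not (0 <= off <= L - 3):
                raise ValueError(f"offset {off} outside [0, {L - 3}] for length {L}")

    def to_json(self, path: str | Path, params: Mapping | None = None) -> None:
        payload = {
            "_provenance": provenance_line("psite", params),
            "offsets": {str(k): v for k, v in sorted(self.offsets.items())},
            "support": {str(k): v for k, v in sorted(self.support.items())},
            "discarded": sorted(self.discarded),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PSiteOffsets":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            offsets={int(k): int(v) for k, v in payload["offsets"].items()},
            support={int(k): int(v) for k, v in payload["support"].items()},
            discarded=set(payload.get("discarded", [])),
        )


def infer_psite_offsets(
    footprints: pd.DataFrame,
    tx: TranscriptSet,
    lengths: Sequence[int] | None = None,
    min_reads: int = 200,
    window: tuple[int, int] = (-20, 10),
    peak_frac: float = 0.30,
) -> PSiteOffsets:
    """Per-length P-site offsets from the start-codon metagene.

    For each read length, 5' ends falling in ``window`` nt around the
    annotated start codon (position 0 of these CDS-anchored transcripts)
    are histogrammed; the offset is the distance from the start codon to
    the 5'-most bin holding at least ``peak_frac`` of the modal windowed
    bin count.  Elongating ribosomes tile every codon, so bins repeat every
    3 nt downstream of ``-offset`` — but no read can start upstream of it,
    which pins the boundary.  Lengths with fewer than ``min_reads`` reads
    are flagged discarded.
    """
    if footprints.empty:
        raise ValueError("no footprint reads supplied")
    unknown = set(footprints["transcript_id"].unique()) - set(tx.ids)
    if unknown:
        raise KeyError(f"unknown transcript ids in footprints: {sorted(unknown)[:5]}")
    if lengths is None:
        lengths = sorted(footprints["length"].unique())

    result = PSiteOffsets()
    for L in lengths:
        sub = footprints[footprints["length"] == L]
        n = int(sub["count"].sum())
        result.support[int(L)] = n
        if n < min_reads:
            result.discarded.add(int(L))
            continue
        in_win = sub[(sub["pos5p"] >= window[0]) & (sub["pos5p"] <= min(window[1], 0))]
        if in_win.empty:
            result.discarded.add(int(L))
            continue
        hist = in_win.groupby("pos5p")["count"].sum()
        threshold = peak_frac * hist.max()
        candidates = hist[hist >= threshold]
        p_star = int(candidates.index.min())
        offset = -p_star
        if not (0 <= offset <= L - 3):
            result.discarded.add(int(L))
            continue
        result.offsets[int(L)] = offset
    if not result.offsets:
        raise ValueError(
            "no read length passed the support minimum "
            f"({min_reads}); lower min_reads or provide more reads"
        )
    return result


# ---------------------------------------------------------------------------
# codon coverage
# ---------------------------------------------------------------------------

@dataclass
class CoverageStats:
    n_input: int = 0
    n_assigned: int = 0
    dropped_length: int = 0
    dropped_outside_cds: int = 0

    @property
    def n_dropped(self) -> int:
        return self.dropped_length + self.dropped_outside_cds


def codon_coverage(
    footprints: pd.DataFrame,
    offsets: PSiteOffsets,
    tx: TranscriptSet,
    sample_id: str = "sample",
) -> tuple[CodonCoverage, CoverageStats]:
    """Assign each read's count to the codon containing its P-site.

    P-site nt position = ``pos5p + offset[length]``; the receiving codon is
    ``floor(position / 3)`` (off-frame P-sites go to the containing codon).
    Reads of discarded lengths or with P-sites outside the CDS are dropped
    and tallied.
    """
    unknown = set(footprints["transcript_id"].unique()) - set(tx.ids)
    if unknown:
        raise KeyError(f"unknown transcript ids in footprints: {sorted(unknown)[:5]}")
    stats = CoverageStats(n_input=int(footprints["count"].sum()))
    counts = {t.transcript_id: np.zeros(t.n_codons, dtype=np.int64) for t in tx}

    for L, sub in footprints.groupby("length"):
        L = int(L)
        c = int(sub["count"].sum())
        if L not in offsets.offsets:
            stats.dropped_length += c
            continue
        off = offsets.offsets[L]
        psite = sub["pos5p"].to_numpy() + off
        codon = np.floor_divide(psite, 3)
        for tx_id, tx_rows in sub.assign(codon=codon, psite=psite).groupby(
            "transcript_id", sort=False
        ):
            vec = counts[str(tx_id)]
            inside = (tx_rows["psite"] >= 0) & (tx_rows["psite"] < 3 * len(vec))
            stats.dropped_outside_cds += int(tx_rows.loc[~inside, "count"].sum())
            good = tx_rows[inside]
            np.add.at(vec, good["codon"].to_numpy(dtype=np.int64), good["count"].to_numpy())
            stats.n_assigned += int(good["count"].sum())
    cov = CodonCoverage(sample_id, {k: v for k, v in counts.items() if v.sum() > 0})
    return cov, stats


# ---------------------------------------------------------------------------
# periodicity diagnostics
# ---------------------------------------------------------------------------

@dataclass
class PeriodicityStats:
    frame_fractions: tuple[float, float, float]
    autocorrelation: dict[int, float]
    dominant_period: int
    stable: bool


def psite_positions(footprints: pd.DataFrame, offsets: PSiteOffsets) -> pd.DataFrame:
    """Nucleotide-resolution P-site positions (reads of discarded lengths
    are skipped); columns ``transcript_id  psite  count``."""
    keep = footprints[footprints["length"].isin(offsets.offsets)]
    off = keep["length"].map(offsets.offsets)
    return pd.DataFrame(
        {
            "transcript_id": keep["transcript_id"].to_numpy(),
            "psite": keep["pos5p"].to_numpy() + off.to_numpy(),
            "count": keep["count"].to_numpy(),
        }
    )


def periodicity_stats(
    psites: pd.DataFrame,
    lags: Sequence[int] = (2, 3, 4, 5, 6),
    min_frame_fraction: float = 0.4,
    min_autocorr: float = 0.05,
) -> PeriodicityStats:
    """Frame occupancy and the dominant period of the metagene profile.

    The metagene profile sums P-site counts per nt position across
    transcripts (positions < 0 discarded).  The dominant period is the
    smallest lag whose autocorrelation reaches 95% of the maximum over
    ``lags`` — a signal of period 3 also peaks at lag 6, so the smallest
    strong lag is the fundamental.  The call is flagged unstable when the
    modal frame holds less than ``min_frame_fraction`` of P-sites or the
    peak autocorrelation is below ``min_autocorr``.
    """
    inside = psites[psites["psite"] >= 0]
    if inside.empty:
        raise ValueError("no P-sites at non-negative positions")
    pos = inside["psite"].to_numpy(dtype=np.int64)
    cnt = inside["count"].to_numpy(dtype=np.int64)

    frames = np.zeros(3, dtype=float)
    np.add.at(frames, pos % 3, cnt)
    frames = frames / frames.sum()

    profile = np.bincount(pos, weights=cnt).astype(float)
    prof = profile - profile.mean()
    denom = float(np.dot(prof, prof))
    ac: dict[int, float] = {}
    for lag in lags:
        if lag >= len(prof) or denom == 0:
            ac[lag] = 0.0
        else:
            ac[lag] = float(np.dot(prof[:-lag], prof[lag:]) / denom)
    max_ac = max(ac.values())
    if max_ac > 0:
        dominant = min(l for l, v in ac.items() if v >= 0.95 * max_ac)
    else:
        dominant = min(ac, key=lambda l: -ac[l])
    stable = frames.max() >= min_frame_fraction and max_ac >= min_autocorr
    return PeriodicityStats(
        frame_fractions=tuple(frames.round(12)),
        autocorrelation=ac,
        dominant_period=int(dominant),
        stable=bool(stable),
    )
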