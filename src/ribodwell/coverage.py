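"""Codon-resolved coverage containers and their sparse TSV serialization."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .io import provenance_line
from .transcripts import TranscriptSet


@dataclass
class CodonCoverage:
    """Per-sample map transcript -> integer count vector over codon positions.

    Vector length equals the transcript's codon count (stop codon included).
    """

    sample_id: str
    counts: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tx_id, vec in self.counts.items():
            arr = np.asarray(vec, dtype=np.int64)
            if (arr < 0).any():
                raise ValueError(f"negative counts for {tx_id}")
            self.counts[tx_id] = arr

    def __getitem__(self, tx_id: str) -> np.ndarray:
        return self.counts[tx_id]

    def __contains__(self, tx_id: str) -> bool:
        return tx_id in self.counts

    def __iter__(self) -> Iterator[str]:
        return iter(self.counts)

    @property
    def total_assigned(self) -> int:
        return int(sum(v.sum() for v in self.counts.values()))

    def validate_against(self, tx: TranscriptSet) -> None:
        for tx_id, vec in self.counts.items():
            if tx_id not in tx:
                raise KeyError(f"coverage references unknown transcript {tx_id}")
            if len(vec) != tx[tx_id].n_codons:
                raise ValueError(
                    f"{tx_id}: coverage length {len(vec)} != {tx[tx_id].n_codons} codons"
                )


def write_coverage_tsv(
    coverages: Mapping[str, CodonCoverage],
    path: str | Path,
    params: Mapping | None = None,
) -> None:
    """Write one or more samples as sparse long-format TSV
    ``sample  transcript_id  codon_index  count`` (zero entries omitted)."""
    rows = []
    for sample_id, cov in coverages.items():
        for tx_id, vec in cov.counts.items():
            nz = np.nonzero(vec)[0]
            for i in nz:
                rows.append((sample_id, tx_id, int(i), int(vec[i])))
    df = pd.DataFrame(rows, columns=["sample", "transcript_id", "codon_index", "count"])
    with open(path, "w") as fh:
        fh.write(provenance_line("coverage", params) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_coverage_tsv(path: str | Path, tx: TranscriptSet) -> dict[str, CodonCoverage]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out: dict[str, CodonCoverage] = {}
    for sample_id, sub in df.groupby("sample", sort=False):
        counts: dict[str, np.ndarray] = {}
        for tx_id, rows in sub.groupby("transcript_id", sort=False):
            if tx_id not in tx:
                raise KeyError(f"coverage references unknown transcript {tx_id}")
            vec = np.zeros(tx[str(tx_id)].n_codons, dtype=np.int64)
            vec[rows["codon_index"].to_numpy()] = rows["count"].to_numpy()
            counts[str(tx_id)] = vec
        out[str(sample_id)] = CodonCoverage(str(sample_id), counts)
    return out
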