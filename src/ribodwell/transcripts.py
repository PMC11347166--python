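"""Coding-sequence transcript sets with codon and amino-acid projections.

Transcripts are CDS-only: position 0 is the first nucleotide of the start
codon, coordinates are 0-based half-open, and frame is defined relative to
the annotated ATG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STOP_CODONS = ("TAA", "TAG", "TGA")

#: the 61 sense codons in lexicographic order
SENSE_CODONS: tuple[str, ...] = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

#: the 20 standard amino acids, alphabetical one-letter codes
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: codon -> amino acid for sense codons
CODON_TO_AA: dict[str, str] = {c: str(Seq(c).translate()) for c in SENSE_CODONS}

#: amino acid -> frozenset of its codons
AA_CODONS: dict[str, frozenset[str]] = {
    aa: frozenset(c for c, a in CODON_TO_AA.items() if a == aa) for aa in AMINO_ACIDS
}


@dataclass(frozen=True)
class Transcript:
    """A single CDS with derived protein sequence.

    Invariants: starts with ATG, ends with a stop codon, length divisible
    by 3, no internal stop.  Protein length equals ``n_codons - 1`` (the
    stop codon does not encode a residue).
    """

    transcript_id: str
    cds_seq: str

    def __post_init__(self) -> None:
        seq = self.cds_seq.upper()
        object.__setattr__(self, "cds_seq", seq)
        if len(seq) % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {len(seq)} not divisible by 3"
            )
        if not seq.startswith("ATG"):
            raise ValueError(f"{self.transcript_id}: CDS does not start with ATG")
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if codons[-1] not in STOP_CODONS:
            raise ValueError(f"{self.transcript_id}: CDS does not end with a stop codon")
        if any(c in STOP_CODONS for c in codons[:-1]):
            raise ValueError(f"{self.transcript_id}: internal stop codon")

    @property
    def n_codons(self) -> int:
        return len(self.cds_seq) // 3

    @property
    def codons(self) -> list[str]:
        return [self.cds_seq[i : i + 3] for i in range(0, len(self.cds_seq), 3)]

    @property
    def protein_seq(self) -> str:
        return str(Seq(self.cds_seq[:-3]).translate())

    def codon_ids(self) -> np.ndarray:
        """Integer codes into :data:`SENSE_CODONS` per codon; stop codon is -1."""
        return np.array(
            [CODON_INDEX.get(c, -1) for c in self.codons], dtype=np.int64
        )

    def residue_ids(self) -> np.ndarray:
        """Integer codes into :data:`AMINO_ACIDS` per protein residue."""
        return np.array([AA_INDEX[a] for a in self.protein_seq], dtype=np.int64)


@dataclass
class TranscriptSet:
    """Ordered collection of :class:`Transcript` keyed by transcript id."""

    records: dict[str, Transcript] = field(default_factory=dict)

    @classmethod
    def from_transcripts(cls, transcripts: Iterable[Transcript]) -> "TranscriptSet":
        out: dict[str, Transcript] = {}
        for t in transcripts:
            if t.transcript_id in out:
                raise ValueError(f"duplicate transcript id: {t.transcript_id}")
            out[t.transcript_id] = t
        return cls(out)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Transcript]:
        return iter(self.records.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.records

    def __getitem__(self, transcript_id: str) -> Transcript:
        return self.records[transcript_id]

    @property
    def ids(self) -> list[str]:
        return list(self.records)

    def to_fasta(self, path: str | Path) -> None:
        recs = [
            SeqRecord(Seq(t.cds_seq), id=t.transcript_id, description="")
            for t in self
        ]
        with open(path, "w") as fh:
            SeqIO.write(recs, fh, "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "TranscriptSet":
        return cls.from_transcripts(
            Transcript(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
        )
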