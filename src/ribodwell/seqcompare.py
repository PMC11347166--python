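"""Position-wise comparison of equal-length protein paralogs.

Bundles the canonical mouse RPL39 and RPL39L protein sequences (UniProt
canonical entries; both 51 residues) so paralog divergence and residue
composition can be computed without network access.
"""

from __future__ import annotations

from dataclasses import dataclass

MOUSE_RPL39 = "MSSHKTFRIKRFLAKKQKQNRPIPQWIRMKTGNKIRYNSKRRHWRRTKLGL"
MOUSE_RPL39L = "MASHKTFRIKRFLAKKQKQNRPIPQWIQMKTGNKIMYNSKRRHWRRTKLGL"


@dataclass(frozen=True)
class Substitution:
    position: int  # 1-based
    ref: str
    alt: str

    def __str__(self) -> str:
        return f"{self.ref}{self.position}{self.alt}"


def substitutions(ref: str, alt: str) -> list[Substitution]:
    """Position-wise differences between two equal-length sequences."""
    if len(ref) != len(alt):
        raise ValueError(
            f"sequences must be equal length for position-wise comparison "
            f"({len(ref)} vs {len(alt)})"
        )
    return [
        Substitution(i + 1, a, b)
        for i, (a, b) in enumerate(zip(ref.upper(), alt.upper()))
        if a != b
    ]


def count_differences(ref: str, alt: str) -> int:
    """Hamming distance between two equal-length sequences."""
    return len(substitutions(ref, alt))


def residue_content_percent(seq: str, residues: str = "KR") -> float:
    """Percentage of positions holding any of ``residues``."""
    if not seq:
        raise ValueError("empty sequence")
    wanted = set(residues.upper())
    n = sum(1 for a in seq.upper() if a in wanted)
    return 100.0 * n / len(seq)
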