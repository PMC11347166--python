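"""Synthetic inputs with plantable effects for every downstream stage.

All generators are deterministic given their parameters and an integer
seed.  Where one call drives several samples, per-sample child generators
are derived from ``numpy.random.SeedSequence(seed).spawn(...)`` in the
fixed order the samples appear in the design table, so adding parameters
elsewhere never perturbs an existing stream.

Counts are negative binomial parameterized by (mean mu, dispersion alpha)
with variance mu + alpha * mu**2, drawn as a gamma-Poisson mixture;
alpha = 0 degenerates to Poisson.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import CodonCoverage
from .io import provenance_line
from .transcripts import (
    AA_CODONS,
    AA_INDEX,
    CODON_INDEX,
    SENSE_CODONS,
    STOP_CODONS,
    Transcript,
    TranscriptSet,
)

MIN_EFFECT_OFFSET = 20
MAX_EFFECT_OFFSET = 45

# offsets up to MAX_EFFECT_OFFSET plus the default dwell-estimation trims
# (20 codons at the start, 10 at the end) must fit inside every transcript
MIN_CODONS = 60


# ---------------------------------------------------------------------------
# design table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Sample:
    sample_id: str
    genotype: str  # "WT" | "KO"
    clone_id: str
    replicate: int
    assay: str  # "RPF" | "RNA"

    def __post_init__(self) -> None:
        if self.genotype not in ("WT", "KO"):
            raise ValueError(f"genotype must be WT or KO, got {self.genotype!r}")
        if self.assay not in ("RPF", "RNA"):
            raise ValueError(f"assay must be RPF or RNA, got {self.assay!r}")
        if self.genotype == "KO" and not self.clone_id:
            raise ValueError("KO samples require a non-empty clone_id")


@dataclass
class DesignTable:
    """Sample -> (genotype, clone, replicate, assay) mapping."""

    samples: list[Sample] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in design")

    def __iter__(self):
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    def subset(self, assay: str | None = None, genotype: str | None = None) -> "DesignTable":
        keep = [
            s
            for s in self.samples
            if (assay is None or s.assay == assay)
            and (genotype is None or s.genotype == genotype)
        ]
        return DesignTable(keep)

    def clones(self, genotype: str = "KO") -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.genotype == genotype and s.clone_id not in seen:
                seen.append(s.clone_id)
        return seen

    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (s.sample_id, s.genotype, s.clone_id, s.replicate, s.assay)
                for s in self.samples
            ],
            columns=["sample_id", "genotype", "clone_id", "replicate", "assay"],
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(provenance_line("design") + "\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DesignTable":
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"clone_id": str})
        return cls(
            [
                Sample(
                    str(r.sample_id),
                    str(r.genotype),
                    "" if pd.isna(r.clone_id) else str(r.clone_id),
                    int(r.replicate),
                    str(r.assay),
                )
                for r in df.itertuples()
            ]
        )


def standard_design(
    n_wt_reps: int = 3,
    ko_clones: Sequence[str] = ("ko1", "ko2", "ko3", "ko4"),
    n_ko_reps: int = 3,
    assays: Sequence[str] = ("RPF", "RNA"),
) -> DesignTable:
    """WT plus several KO clones, replicated, for the requested assays."""
    samples: list[Sample] = []
    for assay in assays:
        for rep in range(1, n_wt_reps + 1):
            samples.append(Sample(f"wt_r{rep}_{assay}", "WT", "wt", rep, assay))
        for clone in ko_clones:
            for rep in range(1, n_ko_reps + 1):
                samples.append(Sample(f"{clone}_r{rep}_{assay}", "KO", clone, rep, assay))
    return DesignTable(samples)


# ---------------------------------------------------------------------------
# dwell model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DwellModel:
    """Codon dwell-time model with an optional conditional planted effect.

    ``base_dwell`` maps the 61 sense codons to positive relative dwell
    values with mean 1.  The effect multiplies the footprint mean by
    ``effect_factor`` at codon positions i where the nascent-chain residue
    ``effect_offset`` codons upstream of the P site (protein position
    ``i - effect_offset``) equals ``effect_aa`` and the P-site codon is in
    ``effect_codons``.
    """

    base_dwell: Mapping[str, float]
    effect_aa: str | None = None
    effect_offset: int | None = None
    effect_codons: frozenset[str] = frozenset()
    effect_factor: float = 1.0
    dispersion: float = 0.1
    depth: float = 1e6

    def __post_init__(self) -> None:
        if set(self.base_dwell) != set(SENSE_CODONS):
            raise ValueError("base_dwell must cover exactly the 61 sense codons")
        vals = np.array([self.base_dwell[c] for c in SENSE_CODONS])
        if (vals <= 0).any():
            raise ValueError("base_dwell values must be positive")
        if not np.isclose(vals.mean(), 1.0, atol=1e-9):
            raise ValueError("base_dwell must have mean 1 over the 61 sense codons")
        if self.effect_offset is not None and not (
            MIN_EFFECT_OFFSET <= self.effect_offset <= MAX_EFFECT_OFFSET
        ):
            raise ValueError(
                f"effect_offset must lie in [{MIN_EFFECT_OFFSET}, {MAX_EFFECT_OFFSET}], "
                f"got {self.effect_offset}"
            )
        if self.effect_factor <= 0:
            raise ValueError("effect_factor must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")

    @property
    def has_effect(self) -> bool:
        return (
            self.effect_aa is not None
            and self.effect_offset is not None
            and len(self.effect_codons) > 0
            and self.effect_factor != 1.0
        )

    def dwell_array(self) -> np.ndarray:
        return np.array([self.base_dwell[c] for c in SENSE_CODONS], dtype=float)

    @classmethod
    def uniform(cls, **kwargs) -> "DwellModel":
        return cls({c: 1.0 for c in SENSE_CODONS}, **kwargs)

    @classmethod
    def random(cls, seed: int, sd: float = 0.4, **kwargs) -> "DwellModel":
        """Log-normal codon dwell values, renormalized to mean 1."""
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD3E11]))
        vals = rng.lognormal(mean=0.0, sigma=sd, size=len(SENSE_CODONS))
        vals = vals / vals.mean()
        return cls(dict(zip(SENSE_CODONS, vals)), **kwargs)

    def with_effect(
        self, aa: str, offset: int, codons: Iterable[str] | None = None, factor: float = 1.5
    ) -> "DwellModel":
        if codons is None:
            codons = AA_CODONS[aa]
        return replace(
            self,
            effect_aa=aa,
            effect_offset=offset,
            effect_codons=frozenset(codons),
            effect_factor=factor,
        )


# ---------------------------------------------------------------------------
# transcriptome
# ---------------------------------------------------------------------------

def gen_transcriptome(n_tx: int, n_codons: int, seed: int) -> TranscriptSet:
    """Random CDS set: forced ATG start and stop end, internal codons drawn
    uniformly from the 61 sense codons.

    ``n_codons`` counts the start and stop codons; it must be at least
    :data:`MIN_CODONS` so the offset grid (conditioning offsets up to 45
    codons) plus the dwell-estimation trims fit in every transcript.
    """
    if n_codons < MIN_CODONS:
        raise ValueError(
            f"n_codons must be >= {MIN_CODONS} so transcripts span the "
            f"conditioning-offset grid (offsets up to {MAX_EFFECT_OFFSET} codons "
            f"plus trimming margins); got {n_codons}"
        )
    if n_tx < 1:
        raise ValueError("n_tx must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7C0DE]))
    sense = np.array(SENSE_CODONS)
    stops = np.array(STOP_CODONS)
    transcripts = []
    width = len(str(n_tx))
    for k in range(n_tx):
        internal = sense[rng.integers(0, len(sense), size=n_codons - 2)]
        stop = stops[rng.integers(0, len(stops))]
        seq = "ATG" + "".join(internal) + str(stop)
        transcripts.append(Transcript(f"tx{k + 1:0{width}d}", seq))
    return TranscriptSet.from_transcripts(transcripts)


# ---------------------------------------------------------------------------
# footprints
# ---------------------------------------------------------------------------

def draw_abundances(tx: TranscriptSet, seed: int) -> dict[str, float]:
    """Log-normal(mu=0, sigma=1) relative transcript abundances."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xAB0D]))
    vals = rng.lognormal(mean=0.0, sigma=1.0, size=len(tx))
    return dict(zip(tx.ids, vals))


def effect_mask(transcript: Transcript, model: DwellModel) -> np.ndarray:
    """Boolean vector over codon positions where the model's planted effect
    applies: residue at chain position ``i - effect_offset`` equals
    ``effect_aa`` and codon i is in ``effect_codons``.  Positions with
    ``i - effect_offset < 0`` never receive the effect."""
    n = transcript.n_codons
    mask = np.zeros(n, dtype=bool)
    if not model.has_effect:
        return mask
    d = model.effect_offset
    protein = transcript.protein_seq
    codons = transcript.codons
    for i in range(n):
        j = i - d
        if j < 0 or j >= len(protein):
            continue
        if protein[j] == model.effect_aa and codons[i] in model.effect_codons:
            mask[i] = True
    return mask


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Gamma-Poisson NB draw with variance mu + alpha*mu^2."""
    mu = np.asarray(mu, dtype=float)
    if alpha == 0:
        return rng.poisson(mu)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, alpha * mu)
    return rng.poisson(lam)


def simulate_footprints(
    tx: TranscriptSet,
    design: DesignTable,
    wt_model: DwellModel,
    ko_model: DwellModel,
    seed: int,
    abundances: Mapping[str, float] | None = None,
) -> dict[str, CodonCoverage]:
    """Codon-count matrices for every RPF sample in the design.

    The count at codon i of transcript t is negative binomial with mean
    ``depth * abundance_t * dwell(codon_i) * effect`` (normalized so the
    no-effect means sum to ``depth`` per sample; the planted effect then
    scales exactly by ``effect_factor`` at qualifying positions).  Stop
    codons take neutral dwell 1.
    """
    if not np.allclose(wt_model.dwell_array(), ko_model.dwell_array()):
        raise ValueError("wt_model and ko_model must share base_dwell")
    rpf = design.subset(assay="RPF")
    if len(rpf) == 0:
        raise ValueError("design contains no RPF samples")
    if abundances is None:
        abundances = draw_abundances(tx, seed)

    dwell = wt_model.dwell_array()
    # per transcript: base mean density over codons
    base: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    for t in tx:
        cid = t.codon_ids()
        d = np.where(cid >= 0, dwell[np.clip(cid, 0, None)], 1.0)
        base[t.transcript_id] = abundances[t.transcript_id] * d
        masks[t.transcript_id] = effect_mask(t, ko_model)
    total = sum(v.sum() for v in base.values())

    children = np.random.SeedSequence([seed, 0xF007]).spawn(len(rpf))
    out: dict[str, CodonCoverage] = {}
    for sample, ss in zip(rpf, children):
        model = ko_model if sample.genotype == "KO" else wt_model
        scale = model.depth / total
        rng = np.random.default_rng(ss)
        counts: dict[str, np.ndarray] = {}
        for t in tx:
            mu = base[t.transcript_id] * scale
            if sample.genotype == "KO" and ko_model.has_effect:
                mu = np.where(masks[t.transcript_id], mu * ko_model.effect_factor, mu)
            counts[t.transcript_id] = _nb_draw(rng, mu, model.dispersion)
        out[sample.sample_id] = CodonCoverage(sample.sample_id, counts)
    return out


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def simulate_reads(
    tx: TranscriptSet,
    coverage: CodonCoverage,
    offset_map: Mapping[int, int],
    lengths: Sequence[int] = (28, 29, 30, 31, 32),
    frame_noise: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Expand codon counts into a footprint table.

    Each codon-count unit becomes one read: a length is drawn uniformly
    from ``lengths`` and the 5' end placed at ``codon_start -
    offset_map[length]``.  With probability ``frame_noise`` the 5' end is
    jittered by a uniform draw from {0, +1, +2} nt (frame resampled
    uniformly, so a noisy read stays in frame with probability 1/3).

    Returns an aggregated table with columns
    ``transcript_id  pos5p  length  count`` (0-based 5' position on the
    transcript; may be negative for reads anchored upstream of the start).
    """
    lengths = list(lengths)
    for L in lengths:
        if L not in offset_map:
            raise ValueError(f"offset_map missing entry for length {L}")
        if not (0 <= offset_map[L] <= L - 3):
            raise ValueError(f"offset {offset_map[L]} outside [0, {L - 3}] for length {L}")
    if not (0.0 <= frame_noise <= 1.0):
        raise ValueError("frame_noise must be a probability")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EAD]))
    tx_col: list[np.ndarray] = []
    pos_col: list[np.ndarray] = []
    len_col: list[np.ndarray] = []
    offsets = np.array([offset_map[L] for L in lengths])
    larr = np.array(lengths)
    for tx_id in coverage:
        vec = coverage[tx_id]
        n = int(vec.sum())
        if n == 0:
            continue
        codon_idx = np.repeat(np.arange(len(vec)), vec)
        li = rng.integers(0, len(lengths), size=n)
        pos = 3 * codon_idx - offsets[li]
        if frame_noise > 0:
            noisy = rng.random(n) < frame_noise
            jitter = rng.integers(0, 3, size=n)
            pos = pos + np.where(noisy, jitter, 0)
        tx_col.append(np.full(n, tx_id, dtype=object))
        pos_col.append(pos)
        len_col.append(larr[li])
    if not tx_col:
        return pd.DataFrame(columns=["transcript_id", "pos5p", "length", "count"])
    df = pd.DataFrame(
        {
            "transcript_id": np.concatenate(tx_col),
            "pos5p": np.concatenate(pos_col),
            "length": np.concatenate(len_col),
        }
    )
    out = (
        df.groupby(["transcript_id", "pos5p", "length"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return out


def write_footprint_tsv(df: pd.DataFrame, path: str | Path, params: Mapping | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_line("footprints", params) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_footprint_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# RNA-seq / TE counts
# ---------------------------------------------------------------------------

def simulate_rnaseq(
    tx: TranscriptSet,
    design: DesignTable,
    abundances: Mapping[str, float] | None = None,
    te_log2fc: Mapping[str, float] | None = None,
    depth: float = 1e5,
    dispersion: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene-level NB count table (genes x samples) for every sample in the
    design, RNA and RPF assays alike.

    Expected RNA counts are identical across genotypes.  ``te_log2fc``
    shifts the RPF mean of KO samples only, so the planted value equals the
    genotype:assay interaction log2 fold change recovered by the
    differential-TE test.
    """
    if abundances is None:
        abundances = draw_abundances(tx, seed)
    if te_log2fc is None:
        te_log2fc = {}
    bad = [g for g, a in abundances.items() if a < 0]
    if bad:
        raise ValueError(f"negative abundance for {bad[:5]}")
    if depth < 0:
        raise ValueError("depth must be non-negative")

    genes = tx.ids
    base = np.array([abundances[g] * tx[g].n_codons for g in genes], dtype=float)
    if base.sum() > 0:
        base = base / base.sum()
    lfc = np.array([te_log2fc.get(g, 0.0) for g in genes])

    children = np.random.SeedSequence([seed, 0x2A5E]).spawn(len(design))
    cols: dict[str, np.ndarray] = {}
    for sample, ss in zip(design, children):
        mu = base * depth
        if sample.assay == "RPF" and sample.genotype == "KO":
            mu = mu * np.exp2(lfc)
        rng = np.random.default_rng(ss)
        cols[sample.sample_id] = _nb_draw(rng, mu, dispersion)
    return pd.DataFrame(cols, index=pd.Index(genes, name="gene"))


# ---------------------------------------------------------------------------
# polysome trace
# ---------------------------------------------------------------------------

def simulate_polysome_trace(
    peak_positions: Sequence[float],
    peak_heights: Sequence[float],
    peak_widths: Sequence[float],
    baseline: float = 0.0,
    n_points: int = 2000,
    noise_sd: float = 0.0,
    x_range: tuple[float, float] | None = None,
    seed: int = 0,
):
    """Absorbance-like trace: baseline + sum of Gaussians + optional white
    noise.  The analytic AUC of each peak is ``height * width * sqrt(2*pi)``.
    """
    from .polysome import PolysomeTrace

    pos = np.asarray(peak_positions, dtype=float)
    hts = np.asarray(peak_heights, dtype=float)
    wds = np.asarray(peak_widths, dtype=float)
    if not (len(pos) == len(hts) == len(wds)):
        raise ValueError("peak parameter vectors must have equal length")
    if (wds <= 0).any():
        raise ValueError("peak widths must be positive")
    if x_range is None:
        pad = 5.0 * wds.max()
        x_range = (float(pos.min() - pad), float(pos.max() + pad))
    x = np.linspace(x_range[0], x_range[1], n_points)
    y = np.full_like(x, baseline)
    for p, h, w in zip(pos, hts, wds):
        y = y + h * np.exp(-0.5 * ((x - p) / w) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7ACE]))
        y = y + rng.normal(0.0, noise_sd, size=len(x))
    return PolysomeTrace(position=x, absorbance=y)


# ---------------------------------------------------------------------------
# domain interval sets
# ---------------------------------------------------------------------------

def gen_domain_sets(
    n_target: int,
    n_other: int,
    cterm_bias: float,
    seed: int,
    length_range: tuple[int, int] = (200, 800),
    interval_frac: float = 0.08,
    p_has_domain: float = 0.6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Protein interval annotations for the positional-enrichment stage.

    Target proteins place their intervals in the C-terminal half with
    probability ``(1 + cterm_bias) / (2 + cterm_bias)`` (0.5 at bias 0,
    approaching 1 as bias grows); non-targets place uniformly.  Returns
    ``(targets, others)`` DataFrames with columns
    ``protein_id  start  end  length`` (0-based half-open residues).
    """
    if cterm_bias < 0:
        raise ValueError("cterm_bias must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD0AA]))
    p_cterm = (1.0 + cterm_bias) / (2.0 + cterm_bias)

    def one_group(n: int, prefix: str, biased: bool) -> pd.DataFrame:
        rows = []
        for k in range(n):
            pid = f"{prefix}{k + 1}"
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            rows_for_protein = []
            if rng.random() < p_has_domain:
                span = max(5, int(round(interval_frac * length)))
                if biased and rng.random() < p_cterm:
                    lo, hi = length // 2, length - span
                else:
                    lo, hi = 0, length - span
                hi = max(hi, lo + 1)
                start = int(rng.integers(lo, hi))
                rows_for_protein.append((pid, start, start + span, length))
            if not rows_for_protein:
                # empty half-open interval: protein present, no domain coverage
                rows_for_protein.append((pid, 0, 0, length))
            rows.extend(rows_for_protein)
        df = pd.DataFrame(rows, columns=["protein_id", "start", "end", "length"])
        return df

    targets = one_group(n_target, "target_", biased=True)
    others = one_group(n_other, "other_", biased=False)
    return targets, others


def write_domain_tsv(df: pd.DataFrame, path: str | Path, params: Mapping | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_line("domains", params) + "\n")
        df.to_csv(fh, sep="\t", index=False)
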