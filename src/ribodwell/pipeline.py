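"""End-to-end demo pipeline: simulate -> P-site -> coverage -> dwell grid ->
differential TE, driven by a strictly validated YAML configuration.

Per-stage seeds are derived from the master seed by
``SeedSequence(master).generate_state(...)`` in a fixed documented order
(transcriptome, footprints, reads, rnaseq), so outputs are byte-identical
across reruns of the same configuration.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import dwelltime, footprints, synthio, teglm
from .coverage import write_coverage_tsv
from .io import config_hash, write_json, write_tsv

log = logging.getLogger("ribodwell")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 1,
    "outdir": "ribodwell_out",
    "transcriptome": {"n_tx": 200, "n_codons": 150},
    "design": {
        "n_wt_reps": 3,
        "ko_clones": ["ko1", "ko2", "ko3", "ko4"],
        "n_ko_reps": 3,
    },
    "dwell": {
        "base_sd": 0.4,
        "dispersion": 0.1,
        "depth": 500000.0,
        "effect": {"aa": "L", "offset": 31, "factor": 1.5, "codons": None},
    },
    "reads": {
        "lengths": [28, 29, 30, 31, 32],
        "offsets": {28: 12, 29: 12, 30: 13, 31: 13, 32: 13},
        "frame_noise": 0.1,
    },
    "psite": {"min_reads": 200},
    "grid": {
        "offset_min": 20,
        "offset_max": 45,
        "trim_start": 20,
        "trim_end": 10,
        "min_tx_coverage": 0.5,
        "min_positions": 3,
    },
    "te": {
        "depth": 100000.0,
        "dispersion": 0.1,
        "te_log2fc": {},
        "alpha": 0.01,
    },
}


class ConfigError(ValueError):
    pass


def _merge_validate(defaults: Mapping[str, Any], user: Mapping[str, Any], path: str = "") -> dict:
    out = copy.deepcopy(dict(defaults))
    for key, value in user.items():
        if key not in defaults:
            raise ConfigError(f"unknown configuration key: {path}{key}")
        if isinstance(defaults[key], dict) and key not in ("offsets", "te_log2fc", "effect"):
            if not isinstance(value, Mapping):
                raise ConfigError(f"{path}{key} must be a mapping")
            out[key] = _merge_validate(defaults[key], value, path=f"{path}{key}.")
        else:
            out[key] = copy.deepcopy(value)
    return out


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    raw: dict[str, Any] = field(default_factory=lambda: copy.deepcopy(DEFAULT_CONFIG))

    @classmethod
    def from_dict(cls, user: Mapping[str, Any]) -> "PipelineConfig":
        return cls(_merge_validate(DEFAULT_CONFIG, user))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, Mapping):
            raise ConfigError("configuration must be a YAML mapping")
        return cls.from_dict(user)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.raw, fh, sort_keys=True)

    def __getitem__(self, key: str) -> Any:
        return self.raw[key]

    @property
    def hash(self) -> str:
        # outdir is excluded: the same analysis written elsewhere is the
        # same analysis (and reruns must be byte-identical)
        return config_hash({k: v for k, v in self.raw.items() if k != "outdir"})


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages; writes provenance-stamped outputs under
    ``config['outdir']`` and returns the in-memory result bundle."""
    cfg = config.raw
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"seed": cfg["seed"], "config": config.hash}
    seeds = [int(s) for s in np.random.SeedSequence(cfg["seed"]).generate_state(4)]
    seed_tx, seed_fp, seed_reads, seed_rna = seeds

    def stage(name: str):
        log.info("stage %s", name)

    # --- simulate ---------------------------------------------------------
    stage("transcriptome")
    tcfg = cfg["transcriptome"]
    tx = synthio.gen_transcriptome(tcfg["n_tx"], tcfg["n_codons"], seed_tx)
    tx.to_fasta(outdir / "transcripts.fasta")

    dcfg = cfg["design"]
    design = synthio.standard_design(
        n_wt_reps=dcfg["n_wt_reps"],
        ko_clones=dcfg["ko_clones"],
        n_ko_reps=dcfg["n_ko_reps"],
    )
    design.to_tsv(outdir / "design.tsv")

    stage("footprints")
    wcfg = cfg["dwell"]
    wt_model = synthio.DwellModel.random(
        seed=seed_fp, sd=wcfg["base_sd"], dispersion=wcfg["dispersion"], depth=wcfg["depth"]
    )
    eff = wcfg["effect"] or {}
    if eff and eff.get("aa"):
        ko_model = wt_model.with_effect(
            eff["aa"], int(eff["offset"]), eff.get("codons"), float(eff.get("factor", 1.5))
        )
    else:
        ko_model = wt_model
    true_cov = synthio.simulate_footprints(tx, design, wt_model, ko_model, seed_fp)
    write_coverage_tsv(true_cov, outdir / "true_coverage.tsv", stamp)
    log.info("footprints: %d samples, %d reads total", len(true_cov),
             sum(c.total_assigned for c in true_cov.values()))

    stage("reads")
    rcfg = cfg["reads"]
    offset_map = {int(k): int(v) for k, v in rcfg["offsets"].items()}
    read_seeds = [int(s) for s in np.random.SeedSequence(seed_reads).generate_state(len(true_cov))]
    read_tables = []
    for (sid, cov), s in zip(true_cov.items(), read_seeds):
        df = synthio.simulate_reads(
            tx, cov, offset_map, rcfg["lengths"], rcfg["frame_noise"], seed=s
        )
        read_tables.append(df.assign(sample=sid))
    reads = pd.concat(read_tables, ignore_index=True)
    write_tsv(reads, outdir / "reads.tsv", "reads", stamp)

    # --- P-site & coverage ------------------------------------------------
    stage("psite")
    pooled = reads.groupby(["transcript_id", "pos5p", "length"], as_index=False)["count"].sum()
    offsets = footprints.infer_psite_offsets(
        pooled, tx, lengths=rcfg["lengths"], min_reads=cfg["psite"]["min_reads"]
    )
    offsets.to_json(outdir / "psite_offsets.json", stamp)
    periodicity = footprints.periodicity_stats(footprints.psite_positions(pooled, offsets))
    write_json(
        {
            "frame_fractions": list(periodicity.frame_fractions),
            "autocorrelation": {str(k): v for k, v in periodicity.autocorrelation.items()},
            "dominant_period": periodicity.dominant_period,
            "stable": periodicity.stable,
        },
        outdir / "periodicity.json",
        "periodicity",
        stamp,
    )

    stage("coverage")
    observed = {}
    for sid, sub in reads.groupby("sample", sort=False):
        cov, stats = footprints.codon_coverage(
            sub[["transcript_id", "pos5p", "length", "count"]], offsets, tx, sample_id=str(sid)
        )
        observed[str(sid)] = cov
        log.info("coverage %s: %d assigned, %d dropped", sid, stats.n_assigned, stats.n_dropped)
    write_coverage_tsv(observed, outdir / "coverage.tsv", stamp)

    # --- dwell grid -------------------------------------------------------
    stage("dwell-scan")
    gcfg = cfg["grid"]
    grid = dwelltime.consistency_grid(
        observed,
        design,
        tx,
        offsets=range(gcfg["offset_min"], gcfg["offset_max"] + 1),
        trim_start=gcfg["trim_start"],
        trim_end=gcfg["trim_end"],
        min_tx_coverage=gcfg["min_tx_coverage"],
        min_positions=gcfg["min_positions"],
    )
    grid.to_tsv(outdir / "dwell_grid.tsv", stamp)
    top_aa, top_offset, top_score = dwelltime.argmax_grid(grid)
    write_json(
        {"aa": top_aa, "offset": top_offset, "score": top_score},
        outdir / "dwell_argmax.json",
        "dwell-argmax",
        stamp,
    )

    # --- differential TE --------------------------------------------------
    stage("te-test")
    tecfg = cfg["te"]
    gene_counts = synthio.simulate_rnaseq(
        tx,
        design,
        te_log2fc=dict(tecfg["te_log2fc"] or {}),
        depth=tecfg["depth"],
        dispersion=tecfg["dispersion"],
        seed=seed_rna,
    )
    rna_ids = [s.sample_id for s in design if s.assay == "RNA"]
    rpf_ids = [s.sample_id for s in design if s.assay == "RPF"]
    rna_counts = gene_counts[rna_ids]
    rpf_counts = gene_counts[rpf_ids]
    write_tsv(rna_counts.rename_axis("gene"), outdir / "rna_counts.tsv", "rna-counts", stamp, index=True)
    write_tsv(rpf_counts.rename_axis("gene"), outdir / "rpf_counts.tsv", "rpf-counts", stamp, index=True)
    te_table = teglm.delta_te_test(rna_counts, rpf_counts, design, alpha=tecfg["alpha"])
    write_tsv(te_table, outdir / "te_results.tsv", "te-test", stamp)

    return {
        "transcripts": tx,
        "design": design,
        "true_coverage": true_cov,
        "observed_coverage": observed,
        "psite_offsets": offsets,
        "periodicity": periodicity,
        "grid": grid,
        "argmax": (top_aa, top_offset, top_score),
        "te_table": te_table,
        "outdir": outdir,
    }
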