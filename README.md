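# ribodwell

Codon-resolved ribosome profiling analysis with a fully synthetic test
bench. The package covers five analysis stages and the generators needed to
exercise them end to end without any external data:

- **synthio** — synthetic transcriptomes (CDS-only FASTA), multi-clone
  WT/KO ribo-seq codon counts driven by a codon dwell-time model with a
  plantable effect conditioned on the nascent-chain residue at a chosen
  offset from the P site, 28–32 nt footprint reads with 3-nt frame bias,
  matched RNA-seq counts with plantable translation-efficiency changes,
  Gaussian-mixture polysome traces, and domain-interval sets with a
  C-terminal positional bias.
- **footprints** — FASTQ trimming/filtering (adapter clip, 3′ quality trim,
  length and quality-fraction filters), per-read-length P-site offset
  inference from the start-codon metagene, codon-resolved coverage, and
  3-nt periodicity diagnostics.
- **dwelltime** — per-codon relative dwell times (per-transcript
  mean-normalized density), optionally conditioned on (amino acid, offset)
  of the nascent chain; KO-vs-WT log2 change vectors per clone; and the
  cross-clone cosine-consistency grid over 20 amino acids × offsets 20–45
  with its argmax report.
- **teglm** — median-of-ratios size factors, per-condition translation
  efficiency, and the differential-TE test: per-gene negative binomial GLM
  with a genotype × assay interaction, Cox–Reid adjusted profile-likelihood
  dispersion, Wald (or LRT) inference, and BH adjustment.
- **paralog_ratio** — core-RP selection by five stringency criteria,
  TPM-weighted gene lengths, RPK with pseudocount, log2 focal-to-core
  ratios, per-group Wilcoxon rank-sum tests (exact permutation null at
  small n), an Ansari–Bradley dispersion test, and single-cell
  co-expression fractions.
- **domainpos** — per-protein domain-coverage fractions over 100
  relative-position bins, per-bin Mann–Whitney profiles, a C-terminal-half
  summary test, and binomial proportion enrichment.
- **polysome** — trapezoidal polysome/monosome AUC ratios with three
  baseline modes and a one-sided Welch t comparison of clone ratios to WT.

## Command line

All stages are subcommands of a single entry point:

```sh
ribodwell simulate --n-tx 200 --n-codons 150 --effect-aa L --outdir out/
ribodwell psite --reads out/reads.tsv --transcripts out/transcripts.fasta --out offsets.json
ribodwell dwell-scan --coverage out/coverage.tsv --design out/design.tsv \
    --transcripts out/transcripts.fasta --out grid.tsv
ribodwell te-test --rna out/rna_counts.tsv --rpf out/rpf_counts.tsv \
    --design out/design.tsv --out te.tsv
ribodwell rp-ratio --counts counts.tsv --meta rp_meta.tsv --lengths lengths.tsv \
    --groups groups.tsv --focal-gene RPL39L --reference-group normal --out ratios.tsv
ribodwell domain-enrich --targets targets.tsv --others others.tsv --out bins.tsv
ribodwell polysome-ratio --trace trace.tsv --mono 0.5 3.5 --poly 4.5 7.5
ribodwell run --config config.yaml     # full demo pipeline
```

`ribodwell run` executes simulate → P-site inference → coverage →
dwell-scan → TE test from a strictly validated YAML configuration (unknown
keys are rejected before any stage runs); outputs carry provenance headers
with the package version, configuration hash and seed, and reruns of the
same configuration are byte-identical.

## File formats

Everything is plain text: FASTA transcripts; footprint tables
(`transcript_id  pos5p  length  count`, 0-based 5′ positions); sparse codon
coverage (`sample  transcript_id  codon_index  count`); design tables
(`sample_id  genotype  clone_id  replicate  assay`); genes × samples count
matrices; two-column traces (`position  absorbance`); domain intervals
(`protein_id  start  end  length`, 0-based half-open); P-site offsets as
JSON. Tabular writers prepend one `#` provenance line; readers skip it.

## Conventions

- Transcripts are CDS-only; coordinates are 0-based half-open and frame is
  relative to the annotated ATG. Off-frame P-sites are assigned to the
  containing codon (floor division).
- A conditioning offset *d* refers to the residue synthesized *d* codons
  before the P-site codon (offset 0 is the P-site codon's own residue).
- Counts are negative binomial with variance μ + αμ²; α = 0.1 by default.
- One master seed per run; per-stage child seeds are derived by
  fixed-order `SeedSequence` splitting.
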