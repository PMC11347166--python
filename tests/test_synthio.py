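import numpy as np
import pytest

from oracles import brute_effect_positions
from ribodwell import synthio
from ribodwell.synthio import DesignTable, DwellModel, Sample, standard_design
from ribodwell.transcripts import AA_CODONS, SENSE_CODONS, STOP_CODONS


# ---------------------------------------------------------------------------
# design table
# ---------------------------------------------------------------------------

class TestDesign:
    def test_standard_design_structure(self):
        design = standard_design()
        assert len(design) == (3 + 4 * 3) * 2
        assert design.clones("KO") == ["ko1", "ko2", "ko3", "ko4"]

    def test_ko_requires_clone(self):
        with pytest.raises(ValueError, match="clone_id"):
            Sample("s1", "KO", "", 1, "RPF")

    def test_tsv_roundtrip(self, tmp_path):
        design = standard_design(ko_clones=("a", "b"))
        path = tmp_path / "design.tsv"
        design.to_tsv(path)
        back = DesignTable.from_tsv(path)
        assert back.to_frame().equals(design.to_frame())


# ---------------------------------------------------------------------------
# transcriptome generation
# ---------------------------------------------------------------------------

class TestGenTranscriptome:
    def test_forced_start_and_stop(self):
        tx = synthio.gen_transcriptome(1, 100, seed=7)
        t = next(iter(tx))
        assert t.codons[0] == "ATG"
        assert t.codons[-1] in STOP_CODONS
        assert t.n_codons == 100

    def test_seeded_determinism_byte_identical(self, tmp_path):
        p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        synthio.gen_transcriptome(200, 300, seed=1).to_fasta(p1)
        synthio.gen_transcriptome(200, 300, seed=1).to_fasta(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seed_differs(self):
        a = synthio.gen_transcriptome(3, 70, seed=1)
        b = synthio.gen_transcriptome(3, 70, seed=2)
        assert any(a[i].cds_seq != b[i].cds_seq for i in a.ids)

    def test_uniform_codon_usage(self):
        # internal codons are iid uniform over 61 codons: the count of each
        # codon is Binomial(n, 1/61); check all within 3 SD
        tx = synthio.gen_transcriptome(200, 300, seed=1)
        counts = {c: 0 for c in SENSE_CODONS}
        n = 0
        for t in tx:
            for c in t.codons[1:-1]:
                counts[c] += 1
                n += 1
        p = 1 / 61
        sd = np.sqrt(n * p * (1 - p))
        lo, hi = n * p - 3.3 * sd, n * p + 3.3 * sd
        outliers = [c for c, k in counts.items() if not (lo <= k <= hi)]
        # with 61 codons at 3.3 SD expect <<1 false positive on average
        assert len(outliers) <= 1, outliers

    def test_too_short_rejected_names_offset_grid(self):
        with pytest.raises(ValueError, match="offset"):
            synthio.gen_transcriptome(5, 59, seed=1)


# ---------------------------------------------------------------------------
# dwell model & footprints
# ---------------------------------------------------------------------------

class TestDwellModel:
    def test_base_dwell_mean_one_enforced(self):
        with pytest.raises(ValueError, match="mean 1"):
            DwellModel({c: 2.0 for c in SENSE_CODONS})

    def test_random_model_normalized(self):
        m = DwellModel.random(seed=3)
        assert np.isclose(m.dwell_array().mean(), 1.0)

    @pytest.mark.parametrize("offset", [19, 46, 0])
    def test_effect_offset_bounds(self, offset):
        with pytest.raises(ValueError, match=r"\[20, 45\]"):
            DwellModel.uniform().with_effect("L", offset)


class TestSimulateFootprints:
    def test_null_effect_identical_distributions(self, mid_tx, rpf_design):
        model = DwellModel.random(seed=4, depth=2e5)
        cov = synthio.simulate_footprints(mid_tx, rpf_design, model, model, seed=8)
        wt = np.concatenate([cov["wt_r1_RPF"][t] for t in mid_tx.ids])
        ko = np.concatenate([cov["ko1_r1_RPF"][t] for t in mid_tx.ids])
        # same expectations: totals within a few SD of each other
        assert abs(wt.sum() - ko.sum()) / wt.sum() < 0.02

    def test_nb_mean_matches_specification(self, mid_tx):
        # Monte-Carlo invariant: empirical mean of >=1e5 NB draws within 2%
        # of the stated mean structure
        design = DesignTable([Sample("s1", "WT", "wt", 1, "RPF")])
        model = DwellModel.uniform(depth=1e6, dispersion=0.1)
        ab = {t: 1.0 for t in mid_tx.ids}
        cov = synthio.simulate_footprints(
            mid_tx, design, model, model, seed=5, abundances=ab
        )
        counts = np.concatenate([cov["s1"][t] for t in mid_tx.ids])
        n_pos = len(counts)
        assert n_pos >= 1e4
        expected = 1e6 / n_pos  # uniform dwell, equal abundance
        assert abs(counts.mean() - expected) / expected < 0.02

    def test_planted_ratio_monte_carlo(self, mid_tx, rpf_design):
        # oracle: mean KO/WT count ratio at qualifying positions -> factor
        wt = DwellModel.uniform(depth=3e5)
        ko = wt.with_effect("L", 31, factor=1.5)
        masks = {t.transcript_id: synthio.effect_mask(t, ko) for t in mid_tx}
        ko_sum = wt_sum = 0.0
        for seed in range(20):
            cov = synthio.simulate_footprints(mid_tx, rpf_design, wt, ko, seed=seed)
            for t in mid_tx.ids:
                m = masks[t]
                wt_sum += cov["wt_r1_RPF"][t][m].sum()
                ko_sum += cov["ko1_r1_RPF"][t][m].sum()
        ratio = ko_sum / wt_sum
        assert ratio == pytest.approx(1.5, rel=0.03)

    def test_effect_mask_agrees_with_brute_force_scan(self, mid_tx):
        ko = DwellModel.uniform().with_effect("K", 25, factor=2.0)
        for t in mid_tx:
            expected = brute_effect_positions(
                t.cds_seq, "K", 25, set(AA_CODONS["K"])
            )
            got = list(np.nonzero(synthio.effect_mask(t, ko))[0])
            assert got == expected

    def test_short_transcript_never_gets_effect(self):
        tx = synthio.gen_transcriptome(3, 60, seed=2)
        # offset 45 leaves qualifying positions only at i >= 45
        ko = DwellModel.uniform().with_effect("L", 45, factor=2.0)
        for t in tx:
            mask = synthio.effect_mask(t, ko)
            assert not mask[:45].any()

    def test_mismatched_base_dwell_rejected(self, mid_tx, rpf_design):
        a = DwellModel.uniform()
        b = DwellModel.random(seed=9)
        with pytest.raises(ValueError, match="share base_dwell"):
            synthio.simulate_footprints(mid_tx, rpf_design, a, b, seed=1)

    def test_bit_reproducible(self, mid_tx, rpf_design):
        m = DwellModel.random(seed=4, depth=1e5)
        c1 = synthio.simulate_footprints(mid_tx, rpf_design, m, m, seed=3)
        c2 = synthio.simulate_footprints(mid_tx, rpf_design, m, m, seed=3)
        for s in c1:
            for t in mid_tx.ids:
                assert np.array_equal(c1[s][t], c2[s][t])


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

class TestSimulateReads:
    def test_noiseless_single_length(self, toy_tx, uniform_model):
        design = DesignTable([Sample("s1", "WT", "wt", 1, "RPF")])
        cov = synthio.simulate_footprints(
            toy_tx, design, uniform_model, uniform_model, seed=1
        )
        reads = synthio.simulate_reads(
            toy_tx, cov["s1"], {29: 12}, lengths=[29], frame_noise=0.0, seed=2
        )
        assert (reads["length"] == 29).all()
        assert ((reads["pos5p"] + 12) % 3 == 0).all()
        assert reads["count"].sum() == cov["s1"].total_assigned

    def test_frame_zero_fraction_closed_form(self, mid_tx, uniform_model):
        # enumeration: P(frame 0) = (1-p)*1 + p*(1/3) for jitter uniform
        # over the three frames; at p = 1/3 that is 7/9
        p = 1 / 3
        expected = (1 - p) + p / 3
        design = DesignTable([Sample("s1", "WT", "wt", 1, "RPF")])
        cov = synthio.simulate_footprints(
            mid_tx, design, uniform_model, uniform_model, seed=1
        )
        reads = synthio.simulate_reads(
            mid_tx, cov["s1"], {30: 12}, lengths=[30], frame_noise=p, seed=4
        )
        frame0 = reads.loc[(reads["pos5p"] + 12) % 3 == 0, "count"].sum()
        frac = frame0 / reads["count"].sum()
        assert frac == pytest.approx(expected, abs=0.01)

    def test_missing_offset_rejected(self, toy_tx, uniform_model):
        design = DesignTable([Sample("s1", "WT", "wt", 1, "RPF")])
        cov = synthio.simulate_footprints(
            toy_tx, design, uniform_model, uniform_model, seed=1
        )
        with pytest.raises(ValueError, match="offset_map"):
            synthio.simulate_reads(toy_tx, cov["s1"], {29: 12}, lengths=[29, 30])


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------

class TestSimulateRnaseq:
    def test_rna_means_equal_across_genotypes(self, mid_tx, full_design):
        lfc = {g: 2.0 for g in mid_tx.ids}  # RPF-only effect
        counts = synthio.simulate_rnaseq(
            mid_tx, full_design, te_log2fc=lfc, depth=2e5, seed=3
        )
        rna_wt = counts[[s.sample_id for s in full_design if s.assay == "RNA" and s.genotype == "WT"]]
        rna_ko = counts[[s.sample_id for s in full_design if s.assay == "RNA" and s.genotype == "KO"]]
        assert rna_ko.to_numpy().sum() == pytest.approx(rna_wt.to_numpy().sum(), rel=0.02)

    def test_rpf_shift_applied_to_ko_only(self, mid_tx, full_design):
        g = mid_tx.ids[0]
        counts = synthio.simulate_rnaseq(
            mid_tx, full_design, te_log2fc={g: 1.0}, depth=5e5, seed=3
        )
        rpf_wt = counts.loc[g, [s.sample_id for s in full_design if s.assay == "RPF" and s.genotype == "WT"]]
        rpf_ko = counts.loc[g, [s.sample_id for s in full_design if s.assay == "RPF" and s.genotype == "KO"]]
        assert rpf_ko.mean() / rpf_wt.mean() == pytest.approx(2.0, rel=0.25)

    def test_negative_abundance_rejected(self, mid_tx, full_design):
        ab = {g: 1.0 for g in mid_tx.ids}
        ab[mid_tx.ids[0]] = -1.0
        with pytest.raises(ValueError, match="negative abundance"):
            synthio.simulate_rnaseq(mid_tx, full_design, abundances=ab)

    def test_zero_depth_gives_all_zero(self, mid_tx, full_design):
        counts = synthio.simulate_rnaseq(mid_tx, full_design, depth=0, seed=1)
        assert (counts.to_numpy() == 0).all()


# ---------------------------------------------------------------------------
# domain interval sets
# ---------------------------------------------------------------------------

class TestGenDomainSets:
    def test_columns_and_bounds(self):
        targets, others = synthio.gen_domain_sets(10, 10, cterm_bias=0.0, seed=1)
        for df in (targets, others):
            assert list(df.columns) == ["protein_id", "start", "end", "length"]
            assert (df["start"] >= 0).all()
            assert (df["end"] <= df["length"]).all()

    def test_determinism(self):
        a = synthio.gen_domain_sets(5, 5, 1.0, seed=42)
        b = synthio.gen_domain_sets(5, 5, 1.0, seed=42)
        assert a[0].equals(b[0]) and a[1].equals(b[1])

    def test_negative_bias_rejected(self):
        with pytest.raises(ValueError, match="cterm_bias"):
            synthio.gen_domain_sets(5, 5, -0.5, seed=1)
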