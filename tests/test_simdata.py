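"""Synthetic genome, haplotype and read-simulator behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonevar import simdata
from clonevar.simdata import (
    ChimeraSpec,
    HaplotypeSpec,
    ReadSimParams,
    SizingError,
    TEInsertionSpec,
    apply_te_excision,
    apply_te_insertion,
    make_reference,
    revcomp,
)


class TestMakeReference:
    def test_constructs_requested_genes(self):
        g = make_reference(100_000, 5, seed=7)
        assert len(g.sequence) == 100_000
        assert len(g.genes) == 5
        assert set(g.sequence) <= set("ACGT")

    def test_gene_models_are_valid(self):
        g = make_reference(30_000, 3, seed=3)
        for gene in g.genes:
            assert len(gene.exons) >= 2
            # exons ordered and non-overlapping
            for (s1, e1), (s2, e2) in zip(gene.exons, gene.exons[1:]):
                assert s1 < e1 <= s2 < e2
            coding = gene.coding_sequence(g.sequence)
            assert len(coding) % 3 == 0
            assert coding.startswith("ATG")
            assert coding[-3:] in simdata.STOP_CODONS
            internal = [coding[i: i + 3] for i in range(3, len(coding) - 3, 3)]
            assert not any(c in simdata.STOP_CODONS for c in internal)
        # genes do not overlap each other
        spans = sorted(gene.span for gene in g.genes)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_seed_determinism(self):
        a = make_reference(12_000, 2, seed=42)
        b = make_reference(12_000, 2, seed=42)
        assert a.sequence == b.sequence
        assert a.genes[0].exons == b.genes[0].exons

    def test_too_small_genome_raises(self):
        with pytest.raises(SizingError):
            make_reference(100, 5, seed=7)


@pytest.fixture(scope="module")
def te_setup():
    rng = np.random.default_rng(5)
    seq = simdata.random_dna(rng, 10_000)
    te = TEInsertionSpec(simdata.random_dna(rng, 800), insertion_site=4321)
    return seq, te


class TestTEInsertion:
    def test_output_length_is_input_plus_element_plus_tsd(self, te_setup):
        seq, te = te_setup
        out, _ = apply_te_insertion(seq, te)
        assert len(out) == len(seq) + 800 + te.tsd_len

    def test_structure_prefix_tsd_element_tsd_suffix(self, te_setup):
        seq, te = te_setup
        out, _ = apply_te_insertion(seq, te)
        s, t = te.insertion_site, te.tsd_len
        tsd = seq[s: s + t]
        assert out[: s + t] == seq[: s + t]
        assert out[s + t: s + t + 800] == te.element_sequence
        assert out[s + t + 800: s + t + 800 + t] == tsd
        assert out[s + t + 800 + t:] == seq[s + t:]

    def test_zero_tsd_length(self, te_setup):
        seq, _ = te_setup
        te = TEInsertionSpec("ACGT" * 200, 4321, tsd_len=0, scar_len=1,
                             footprint="G")
        out, _ = apply_te_insertion(seq, te)
        assert len(out) == len(seq) + 800

    def test_coordinate_map_roundtrip(self, te_setup):
        seq, te = te_setup
        out, cmap = apply_te_insertion(seq, te)
        for i in range(len(out)):
            r = cmap.to_ref(i)
            if r >= 0:
                assert out[i] == seq[r]

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            TEInsertionSpec("A" * 800, 100, tsd_len=4, scar_len=7)
        with pytest.raises(ValueError):
            TEInsertionSpec("ACGT", 100)  # element too short


class TestTEExcision:
    def test_scar_is_insertion_relative_to_intact(self, te_setup):
        seq, te = te_setup
        te_hap, _ = apply_te_insertion(seq, te)
        scar_hap, _ = apply_te_excision(te_hap, te)
        # sequence-diff oracle: exactly one insertion of scar_len at site
        cut = te.insertion_site + te.tsd_len
        assert scar_hap[:cut] == seq[:cut]
        assert scar_hap[cut + te.scar_len:] == seq[cut:]
        assert len(scar_hap) == len(seq) + te.scar_len
        assert scar_hap[cut: cut + te.scar_len] == te.scar_footprint(seq)

    def test_full_tsd_footprint_gives_tandem_duplication(self, te_setup):
        seq, _ = te_setup
        te = TEInsertionSpec(simdata.random_dna(
            np.random.default_rng(0), 800), 4321, tsd_len=8, scar_len=8)
        te_hap, _ = apply_te_insertion(seq, te)
        scar_hap, _ = apply_te_excision(te_hap, te)
        tsd = te.tsd(seq)
        s = te.insertion_site
        assert scar_hap[s: s + 16] == tsd + tsd

    def test_input_without_element_raises(self, te_setup):
        seq, te = te_setup
        with pytest.raises(ValueError, match="does not carry"):
            apply_te_excision(seq, te)

    def test_composed_maps_equal_direct_scar_map(self, te_setup):
        """Insertion-then-excision composes to a plain scar insertion."""
        seq, te = te_setup
        te_hap, ins_map = apply_te_insertion(seq, te)
        scar_hap, exc_map = apply_te_excision(te_hap, te)
        composed = exc_map.compose(ins_map)
        # brute-force base-by-base oracle on the direct construction
        cut = te.insertion_site + te.tsd_len
        direct = np.concatenate([
            np.arange(cut), np.full(te.scar_len, -1),
            np.arange(cut, len(seq)),
        ])
        assert np.array_equal(composed.ref_of, direct)


class TestHaplotypes:
    def test_copy_counts_must_sum_to_ploidy(self, genome):
        with pytest.raises(ValueError, match="sum to"):
            simdata.expand_copies(
                genome, [HaplotypeSpec("INTACT", [], 3)])

    def test_small_variant_validation(self, genome):
        pos = 500
        wrong = "A" if genome.sequence[pos] != "A" else "C"
        spec = HaplotypeSpec("INTACT", [(pos, wrong, "G")], 4)
        with pytest.raises(ValueError, match="reference is"):
            simdata.build_haplotype(genome, spec)

    def test_deletion_variant_shifts_insertion_site(self, genome):
        te = TEInsertionSpec(
            simdata.random_dna(np.random.default_rng(1), 800), 5000)
        dele = (400, genome.sequence[400:403], "")
        hap = simdata.build_haplotype(
            genome, HaplotypeSpec("TE", [dele], 1, te))
        # the TSD at the (shifted) junction matches the reference site
        assert te.element_sequence in hap.seq
        idx = hap.seq.find(te.element_sequence)
        tsd = genome.sequence[5000:5008]
        assert hap.seq[idx - 8: idx] == tsd
        assert hap.seq[idx + 800: idx + 808] == tsd


class TestChimeraSpecValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ChimeraSpec((0.5, 0.2, 0.2))

    def test_unknown_layer_rejected(self):
        with pytest.raises(ValueError):
            ChimeraSpec(mutant_layers=frozenset({"L4"}))

    def test_params_validation(self):
        with pytest.raises(ValueError):
            ReadSimParams(coverage=0)
        with pytest.raises(ValueError):
            ReadSimParams(fragment_mean=100, read_len=150)


class TestChimeraReadSimulation:
    def test_truth_sam_reproduces_read_bases(self):
        """Error positions aside, M-aligned bases match the reference."""
        sc = simdata.default_scenario(seed=17, genotype="simplex_scar",
                                      n_het_snps=0)
        sim = simdata.simulate_chimera_reads(
            sc.genome, sc.haplotypes, sc.chimera, sc.params)
        ref = sc.genome.sequence
        mismatches = total = 0
        for aln in sim.truth_alignments():
            if aln.is_unmapped:
                continue
            for q, r, _ in aln.aligned_pairs():
                total += 1
                if aln.seq[q] != ref[r]:
                    mismatches += 1
        # substitutions occur at the error rate; allow 3x headroom
        assert total > 100_000
        assert mismatches / total < 3 * 0.001

    def test_mean_depth_matches_coverage(self, simplex_sim,
                                         simplex_scenario):
        ref_len = len(simplex_scenario.genome)
        depth = np.zeros(ref_len)
        for aln in simplex_sim.truth_alignments():
            if aln.is_unmapped:
                continue
            r = aln.start
            for op, n in aln.cigar:
                if op in "M=X":
                    depth[r: r + n] += 1
                    r += n
                elif op in "DN":
                    r += n
        mean = depth[200:-200].mean()
        cov = simplex_scenario.params.coverage
        assert abs(mean - cov) / cov < 0.10

    def test_scar_truth_fraction_near_quarter(self, simplex_sim):
        recs = simplex_sim.truth_records()
        frac = sum(t.allele_class == "SCAR" for t in recs) / len(recs)
        se = np.sqrt(0.25 * 0.75 / len(recs))
        assert abs(frac - 0.25) < 3 * se + 0.01

    def test_layer_fractions_recovered(self):
        sc = simdata.default_scenario(
            seed=22, genotype="txns", mutant_layers=("L2", "L3"),
            coverage=200)
        sim = simdata.simulate_chimera_reads(
            sc.genome, sc.haplotypes, sc.chimera, sc.params)
        # one independent layer draw per fragment (mates share it)
        frag_layer = {t.read_id: t.layer for t in sim.truth_records()}
        n = len(frag_layer)
        assert n >= 6_000
        for layer, f in zip(simdata.LAYERS, sc.chimera.layer_fractions):
            obs = sum(v == layer for v in frag_layer.values()) / n
            se = np.sqrt(f * (1 - f) / n)
            assert abs(obs - f) < 3 * se

    def test_no_mutant_layers_means_no_scar_reads(self, rn_scenario):
        sc = rn_scenario
        sim = simdata.simulate_chimera_reads(
            sc.genome, sc.haplotypes, sc.chimera, sc.params)
        assert all(t.allele_class != "SCAR" for t in sim.truth_records())

    def test_seed_determinism_byte_identical(self, tmp_path):
        sc = simdata.default_scenario(seed=31, genotype="txns",
                                      mutant_layers=("L2", "L3"))
        outs = []
        for sub in ("a", "b"):
            sim = simdata.simulate_chimera_reads(
                sc.genome, sc.haplotypes, sc.chimera, sc.params)
            paths = sim.write(tmp_path / sub)
            outs.append(paths)
        for key in ("r1", "r2", "sam", "truth"):
            assert outs[0][key].read_bytes() == outs[1][key].read_bytes()

    def test_reads_inside_element_are_unmapped(self, simplex_sim):
        unmapped = [a for a in simplex_sim.truth_alignments()
                    if a.is_unmapped]
        assert unmapped, "expected some element-interior reads"
        assert all(a.cigar == [] for a in unmapped)


class TestRnaSimulation:
    def test_equal_weights_give_half_intact_informative(self, rn_scenario):
        sc = rn_scenario
        sim = simdata.simulate_rna_reads(
            sc.genome, sc.haplotypes, [1, 1, 1, 1],
            ReadSimParams(coverage=300, seed=3, fragment_mean=300,
                          fragment_sd=30))
        # per-copy read density is proportional to weight: reads covering
        # a single exonic position split evenly between allele classes
        site = sc.te.insertion_site
        ex2 = sc.gene.exons[1]
        pos = max(ex2[0] + 20, site - 100)
        recs = [t for t in sim.truth_records()
                if ex2[0] <= t.ref_start <= pos and pos < t.ref_end <= ex2[1]]
        frac = sum(t.allele_class == "INTACT" for t in recs) / len(recs)
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / len(recs)) + 0.02

    def test_single_expressed_haplotype(self, rn_scenario):
        sc = rn_scenario
        sim = simdata.simulate_rna_reads(
            sc.genome, sc.haplotypes, [1, 0, 0, 0],
            ReadSimParams(coverage=50, seed=5, fragment_mean=300,
                          fragment_sd=30))
        assert {t.haplotype_index for t in sim.truth_records()} == {0}

    def test_all_zero_weights_rejected(self, rn_scenario):
        sc = rn_scenario
        with pytest.raises(ValueError, match="weights"):
            simdata.simulate_rna_reads(
                sc.genome, sc.haplotypes, [0, 0, 0, 0],
                ReadSimParams(seed=1, fragment_mean=300))

    def test_spliced_truth_alignments_skip_introns(self, rn_scenario):
        sc = rn_scenario
        sim = simdata.simulate_rna_reads(
            sc.genome, sc.haplotypes, [1, 1, 1, 1],
            ReadSimParams(coverage=100, seed=9, fragment_mean=300,
                          fragment_sd=30))
        n_ops = [op for a in sim.truth_alignments()
                 for op, _ in a.cigar if op == "N"]
        assert n_ops, "expected exon-junction reads with intron skips"


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_revcomp_involution(seed):
    seq = simdata.random_dna(np.random.default_rng(seed), 60)
    assert revcomp(revcomp(seq)) == seq
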