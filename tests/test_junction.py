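"""Read classification, VAF estimation and element reconstruction."""

import numpy as np
import pytest
from scipy import stats

from clonevar import simdata
from clonevar.alnio import AlignedRead, FLAG_MATE_UNMAPPED
from clonevar.junction import (
    AMBIGUOUS,
    INTACT,
    SCAR,
    TE_JUNCTION,
    ClassifyParams,
    LocusAlleleModel,
    SearchParams,
    classify_read,
    classify_reads,
    estimate_locus_vaf,
    estimate_vaf,
    extract_flank_segments,
    locate_element,
    locus_model_from_scenario,
    wilson_interval,
    _consensus,
)


@pytest.fixture(scope="module")
def model():
    return LocusAlleleModel(
        locus=(0, 10_000), insertion_site=5000, tsd_len=8,
        scar_seq="ACGTACG",
        te_terminal_5p="GATTACAGATTACAGATTACAGATTACAGA",
        te_terminal_3p="CTCGAGCTCGAGCTCGAGCTCGAGCTCGAG",
    )


def read(start, cigar, seq, qname="r", flags=0):
    return AlignedRead(qname=qname, rname="ref", start=start,
                       cigar=cigar, seq=seq, flags=flags)


def mseq(n):
    return "A" * n


class TestClassifyRead:
    def test_scar_insertion_called(self, model):
        # spans the site with anchors, carrying the 7-bp scar insertion
        r = read(4958, [("M", 50), ("I", 7), ("M", 93)],
                 mseq(50) + model.scar_seq + mseq(93))
        assert classify_read(r, model).assigned_class == SCAR

    def test_scar_with_one_error_still_called(self, model):
        scar = "ACGTACT"  # edit distance 1 from the model scar
        r = read(4958, [("M", 50), ("I", 7), ("M", 93)],
                 mseq(50) + scar + mseq(93))
        assert classify_read(r, model).assigned_class == SCAR

    def test_te_junction_right_clip(self, model):
        clip = model.te_terminal_5p + mseq(20)
        r = read(5008 - 100, [("M", 100), ("S", 50)], mseq(100) + clip)
        call = classify_read(r, model)
        assert call.assigned_class == TE_JUNCTION
        assert call.evidence["clip_side"] == "right"

    def test_te_junction_left_clip(self, model):
        clip = mseq(20) + model.te_terminal_3p
        r = read(5000, [("S", 50), ("M", 100)], clip + mseq(100))
        call = classify_read(r, model)
        assert call.assigned_class == TE_JUNCTION
        assert call.evidence["clip_side"] == "left"

    def test_clip_not_matching_terminal_is_ambiguous(self, model):
        r = read(4908, [("M", 100), ("S", 50)], mseq(150))
        assert classify_read(r, model).assigned_class == AMBIGUOUS

    def test_mate_in_element_is_te_evidence(self, model):
        r = read(4700, [("M", 150)], mseq(150), flags=FLAG_MATE_UNMAPPED)
        call = classify_read(r, model)
        assert call.assigned_class == TE_JUNCTION
        assert call.evidence == {"mate_unmapped": True}

    def test_reference_like_span_is_intact(self, model):
        r = read(4930, [("M", 150)], mseq(150))
        assert classify_read(r, model).assigned_class == INTACT

    def test_anchor_boundary_is_ambiguous(self, model):
        # ends 2 bp past the insertion point: right anchor unmet
        r = read(5010 - 150, [("M", 150)], mseq(150))
        assert classify_read(r, model).assigned_class == AMBIGUOUS

    def test_short_clip_at_junction_not_intact(self, model):
        # 6-bp clip at the junction: too short for TE, not clean INTACT
        r = read(4864, [("M", 144), ("S", 6)], mseq(150))
        assert classify_read(r, model).assigned_class == AMBIGUOUS

    def test_read_outside_locus_raises(self, model):
        r = read(20_000, [("M", 150)], mseq(150))
        with pytest.raises(ValueError, match="locus"):
            classify_read(r, model)


class TestClassifyOnSimulation:
    def test_error_free_reads_match_truth_everywhere(self):
        """With no sequencing errors, classification never contradicts
        the truth labels; with default errors agreement stays >= 99%."""
        for err, min_agree in ((0.0, 1.0), (0.001, 0.99)):
            sc = simdata.default_scenario(
                seed=41, genotype="simplex_scar", sub_error_rate=err)
            sim = simdata.simulate_chimera_reads(
                sc.genome, sc.haplotypes, sc.chimera, sc.params)
            model = locus_model_from_scenario(sc)
            truth = {(t.read_id, t.mate): t.allele_class
                     for t in sim.truth_records()}
            checked = agree = 0
            for aln in sim.truth_alignments():
                if aln.is_unmapped or not aln.overlaps(*model.locus):
                    continue
                call = classify_read(aln, model)
                if call.assigned_class == AMBIGUOUS:
                    continue
                mate = 1 if aln.flags & 0x40 else 2
                expected = truth[(aln.qname, mate)]
                if expected == "TE":
                    expected = TE_JUNCTION
                checked += 1
                agree += call.assigned_class == expected
            assert checked > 50
            assert agree / checked >= min_agree

    def test_class_conservation(self, simplex_sim, simplex_model):
        reads = [a for a in simplex_sim.truth_alignments()
                 if not a.is_unmapped
                 and a.overlaps(*simplex_model.locus)]
        calls = classify_reads(reads, simplex_model)
        assert len(calls) == len(reads)
        classes = [c.assigned_class for c in calls]
        total = sum(classes.count(c)
                    for c in (INTACT, TE_JUNCTION, SCAR, AMBIGUOUS))
        assert total == len(reads)


class TestEstimateVaf:
    def test_point_estimate(self):
        calls = ([type("C", (), {"assigned_class": SCAR})()] * 5
                 + [type("C", (), {"assigned_class": INTACT})()] * 15)
        est = estimate_vaf(calls, SCAR)
        assert est.vaf == pytest.approx(0.25)
        assert est.k == 5 and est.n == 20

    def test_zero_count_interval_starts_at_zero(self):
        calls = [type("C", (), {"assigned_class": INTACT})()] * 10
        est = estimate_vaf(calls, SCAR)
        assert est.vaf == 0.0
        assert est.ci_low == 0.0

    def test_no_informative_reads(self):
        calls = [type("C", (), {"assigned_class": AMBIGUOUS})()] * 5
        assert estimate_vaf(calls, SCAR) is None

    def test_wilson_vs_clopper_pearson(self):
        """The exact binomial interval contains the Wilson interval's
        midpoint and overlaps it substantially (k=12, n=60)."""
        k, n = 12, 60
        lo, hi = wilson_interval(k, n)
        cp_lo = stats.beta.ppf(0.025, k, n - k + 1)
        cp_hi = stats.beta.ppf(0.975, k + 1, n - k)
        assert cp_lo < (lo + hi) / 2 < cp_hi
        # Wilson is narrower but nested within +/- 2% of Clopper-Pearson
        assert lo > cp_lo - 0.02 and hi < cp_hi + 0.02
        assert lo <= k / n <= hi

    def test_wilson_coverage_at_n_100(self):
        """Empirical 95% interval coverage >= 93% over 1,000 replicates."""
        rng = np.random.default_rng(7)
        p = 0.25
        n = 100
        hits = 0
        for _ in range(1000):
            k = rng.binomial(n, p)
            lo, hi = wilson_interval(k, n)
            hits += lo <= p <= hi
        assert hits / 1000 >= 0.93


class TestLocusVaf:
    def test_simplex_scar_vaf_near_quarter(self, simplex_sim,
                                           simplex_model):
        calls = classify_reads(simplex_sim.truth_alignments(),
                               simplex_model)
        est = estimate_locus_vaf(calls, simplex_model)
        se = np.sqrt(0.25 * 0.75 / est.n)
        assert abs(est.vaf - 0.25) < 3 * se + 0.01


class TestConsensus:
    def test_majority_vote_fixes_planted_errors(self):
        rng = np.random.default_rng(3)
        true = simdata.random_dna(rng, 60)
        clips = []
        for i in range(10):
            ln = 30 + 3 * i
            clip = list(true[:ln])
            if i == 9:  # plant one error in the longest clip at 10%
                clip[5] = "A" if clip[5] != "A" else "C"
            clips.append("".join(clip))
        cons = _consensus(clips, anchor_end=False)
        assert cons == true[:len(cons)]
        assert len(cons) == max(len(c) for c in clips)

    def test_single_clip_returned_verbatim(self):
        assert _consensus(["ACGTACGTACGT"], anchor_end=False) == \
            "ACGTACGTACGT"
        assert _consensus([], anchor_end=True) == ""


@pytest.fixture(scope="module")
def planted():
    sc = simdata.default_scenario(
        seed=6, genotype="rn", genome_length=100_000, n_genes=3,
        plant_element_copy=True)
    sim = simdata.simulate_chimera_reads(
        sc.genome, sc.haplotypes, sc.chimera, sc.params)
    model = locus_model_from_scenario(sc)
    calls = classify_reads(sim.truth_alignments(), model)
    te_calls = [c for c in calls if c.assigned_class == TE_JUNCTION]
    return sc, extract_flank_segments(te_calls)


class TestElementReconstruction:
    def test_flank_segments_match_element_termini(self, planted):
        sc, seg = planted
        elem = sc.te.element_sequence
        assert seg.left == elem[: len(seg.left)]
        assert seg.right == elem[len(elem) - len(seg.right):]
        assert min(len(seg.left), len(seg.right)) >= 30

    def test_planted_copy_found_with_exact_length(self, planted):
        sc, seg = planted
        hits = locate_element(sc.genome, seg.left, seg.right)
        assert len(hits) == 1
        assert hits[0].element_length == len(sc.te.element_sequence)
        assert hits[0].strand == "+"

    def test_two_planted_copies_found(self):
        rng = np.random.default_rng(12)
        seq = simdata.random_dna(rng, 50_000)
        elem = simdata.random_dna(rng, 800)
        seq = seq[:10_000] + elem + seq[10_800:30_000] + elem + seq[30_800:]
        genome = simdata.GenomeModel(seq, [], seed=12)
        hits = locate_element(genome, elem[:60], elem[-60:])
        assert len(hits) == 2
        assert all(h.element_length == 800 for h in hits)
        assert sorted(h.element_start for h in hits) == [10_000, 30_000]

    def test_reverse_strand_copy_found(self):
        rng = np.random.default_rng(13)
        seq = simdata.random_dna(rng, 40_000)
        elem = simdata.random_dna(rng, 800)
        seq = seq[:20_000] + simdata.revcomp(elem) + seq[20_800:]
        genome = simdata.GenomeModel(seq, [], seed=13)
        hits = locate_element(genome, elem[:60], elem[-60:])
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert hits[0].element_length == 800

    def test_random_segments_find_nothing(self):
        rng = np.random.default_rng(14)
        genome = simdata.GenomeModel(
            simdata.random_dna(rng, 30_000), [], seed=14)
        left = simdata.random_dna(rng, 60)
        right = simdata.random_dna(rng, 60)
        assert locate_element(genome, left, right) == []

    def test_short_segments_rejected(self):
        genome = simdata.GenomeModel("ACGT" * 1000, [], seed=0)
        with pytest.raises(ValueError, match="seed"):
            locate_element(genome, "ACGT", "ACGTACGTACGTACGTACGT")
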