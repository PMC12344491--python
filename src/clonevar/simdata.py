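"""Synthetic tetraploid chimera locus and read simulator.

Generates random reference genomes with gene models, tetraploid haplotypes
carrying transposable-element (TE) insertion / excision-scar alleles,
periclinal-chimera cell populations with configurable layer fractions, and
paired-end DNA / RNA reads with per-read truth labels and truth alignments.
Every downstream analysis stage is testable against these truth sets
without an external aligner or real data.

Model of the structural alleles
-------------------------------
A cut-and-paste DNA transposon inserts at a target site and duplicates the
``tsd_len`` bases at the site (target-site duplication, TSD), so the
insertion haplotype reads ``prefix · TSD · element · TSD · suffix``.
Excision removes the element and leaves a small footprint derived from the
TSD — by default its first ``scar_len`` bases — so the excision haplotype
differs from the never-inserted one by exactly a ``scar_len``-bp insertion
at the site.  With the defaults (8-bp TSD, 7-bp scar) this reproduces a
7-bp excision scar that is part of a direct repeat.

All internal coordinates are 0-based half-open.  A single integer seed
drives one :class:`numpy.random.Generator`; identical seeds and parameters
give byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import alnio
from .alnio import (
    AlignedRead,
    FLAG_MATE_REVERSE,
    FLAG_MATE_UNMAPPED,
    FLAG_PAIRED,
    FLAG_READ1,
    FLAG_READ2,
    FLAG_REVERSE,
    FLAG_UNMAPPED,
)

# allele class labels
INTACT = "INTACT"
TE = "TE"
SCAR = "SCAR"

LAYERS = ("L1", "L2", "L3")

#: Leaf cell fractions (f_L1, f_L2, f_L3).  Chosen so that a simplex
#: mutation confined to L1 has expected VAF 0.06 and one confined to
#: L2+L3 has expected VAF 0.19: the epidermis is a modest fraction of
#: leaf cells, the mesophyll the largest.
DEFAULT_LAYER_FRACTIONS = (0.24, 0.56, 0.20)

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")

STOP_CODONS = ("TAA", "TAG", "TGA")


class SizingError(ValueError):
    """Requested genome too small for the gene models."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """One gene: exon and CDS intervals in genomic coordinates."""

    gene_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def cds_positions(self) -> list[int]:
        """Genomic CDS positions in translation order (5'→3' of the mRNA)."""
        pos = [p for s, e in self.cds for p in range(s, e)]
        return pos if self.strand == "+" else pos[::-1]

    def coding_sequence(self, genome_seq: str) -> str:
        if self.strand == "+":
            return "".join(genome_seq[p] for p in self.cds_positions())
        return "".join(genome_seq[p].translate(_COMP)
                       for p in self.cds_positions())


@dataclass
class GenomeModel:
    """A synthetic reference: one contig plus gene models."""

    sequence: str
    genes: list[GeneModel]
    seed: int
    name: str = "ref"

    def __post_init__(self) -> None:
        if set(self.sequence) - set("ACGT"):
            raise ValueError("genome alphabet must be A/C/G/T")

    def __len__(self) -> int:
        return len(self.sequence)


_MIN_GENE_SLOT = 2400  # bp of territory needed per gene, incl. spacing


def make_reference(length: int, n_genes: int, seed: int,
                   name: str = "ref") -> GenomeModel:
    """Random reference of ``length`` bp with ``n_genes`` gene models.

    Each gene has >=2 exons and a valid CDS: ATG start, length divisible
    by three, a single terminal stop codon and no internal stops (so
    translate-and-compare impact analysis is well defined on it).
    """
    if length < 10_000:
        raise SizingError(f"genome length {length} < 10000")
    if n_genes > 0 and length < n_genes * _MIN_GENE_SLOT + 1000:
        raise SizingError(
            f"length {length} too small for {n_genes} genes "
            f"(need >= {n_genes * _MIN_GENE_SLOT + 1000})"
        )
    rng = np.random.default_rng(seed)
    seq = np.array(list(random_dna(rng, length)))

    genes: list[GeneModel] = []
    slot = (length - 1000) // n_genes if n_genes else 0
    for g in range(n_genes):
        slot_start = 500 + g * slot
        n_ex = int(rng.integers(2, 4))
        exon_lens = rng.integers(350, 650, n_ex)
        intron_lens = rng.integers(150, 350, n_ex - 1)
        gene_len = int(exon_lens.sum() + intron_lens.sum())
        offset = int(rng.integers(0, max(1, slot - gene_len - 200)))
        pos = slot_start + offset
        exons: list[tuple[int, int]] = []
        for i in range(n_ex):
            exons.append((pos, pos + int(exon_lens[i])))
            pos += int(exon_lens[i])
            if i < n_ex - 1:
                pos += int(intron_lens[i])
        strand = "+" if rng.random() < 0.5 else "-"

        # CDS from inside the first exon to inside the last, trimmed to a
        # multiple of three
        cds_start = exons[0][0] + int(rng.integers(40, 120))
        cds_end = exons[-1][1] - int(rng.integers(40, 120))
        cds = _clip_intervals(exons, cds_start, cds_end)
        cds_len = sum(e - s for s, e in cds)
        cds = _clip_intervals(exons, cds_start, cds_end - cds_len % 3)
        cds_len = sum(e - s for s, e in cds)

        gene = GeneModel(f"gene{g + 1}", strand, exons, cds)
        _write_coding_sequence(seq, gene, cds_len, rng)
        genes.append(gene)

    return GenomeModel("".join(seq), genes, seed, name)


def _clip_intervals(intervals: Sequence[tuple[int, int]],
                    start: int, end: int) -> list[tuple[int, int]]:
    out = []
    for s, e in intervals:
        s2, e2 = max(s, start), min(e, end)
        if s2 < e2:
            out.append((s2, e2))
    return out


_NON_STOP = [a + b + c
             for a in "ACGT" for b in "ACGT" for c in "ACGT"
             if a + b + c not in STOP_CODONS]


def _write_coding_sequence(seq: np.ndarray, gene: GeneModel,
                           cds_len: int, rng: np.random.Generator) -> None:
    n_codons = cds_len // 3
    codons = ["ATG"]
    idx = rng.integers(0, len(_NON_STOP), n_codons - 2)
    codons.extend(_NON_STOP[i] for i in idx)
    codons.append(STOP_CODONS[int(rng.integers(0, 3))])
    coding = "".join(codons)
    positions = gene.cds_positions()
    if gene.strand == "+":
        for p, b in zip(positions, coding):
            seq[p] = b
    else:
        for p, b in zip(positions, coding):
            seq[p] = b.translate(_COMP)


# ---------------------------------------------------------------------------
# coordinate maps and structural edits
# ---------------------------------------------------------------------------

@dataclass
class CoordinateMap:
    """Maps every position of a derived sequence to its source coordinate.

    ``ref_of[i]`` is the source position of derived base ``i``, or -1 for
    bases with no source correspondence (element interior, scar footprint,
    inserted alleles).
    """

    ref_of: np.ndarray

    def __len__(self) -> int:
        return len(self.ref_of)

    def to_ref(self, i: int) -> int:
        return int(self.ref_of[i])

    def compose(self, inner: "CoordinateMap") -> "CoordinateMap":
        """Map through ``self`` (derived→mid) then ``inner`` (mid→source)."""
        out = np.full(len(self.ref_of), -1, dtype=np.int64)
        ok = self.ref_of >= 0
        out[ok] = inner.ref_of[self.ref_of[ok]]
        return CoordinateMap(out)

    @staticmethod
    def identity(n: int) -> "CoordinateMap":
        return CoordinateMap(np.arange(n, dtype=np.int64))


@dataclass
class TEInsertionSpec:
    """A cut-and-paste TE insertion with target-site duplication.

    ``scar_len`` bases of footprint remain after excision; by default the
    footprint is the first ``scar_len`` bases of the TSD (set ``footprint``
    to override, e.g. to model footprints with novel bases).
    """

    element_sequence: str
    insertion_site: int
    tsd_len: int = 8
    scar_len: int = 7
    footprint: str | None = None
    min_clip_match: int = 12

    def __post_init__(self) -> None:
        if not 0 < self.scar_len <= self.tsd_len + 2:
            raise ValueError("need 0 < scar_len <= tsd_len + 2")
        if len(self.element_sequence) < 2 * self.min_clip_match:
            raise ValueError("element shorter than 2 x min_clip_match")
        if self.footprint is None and self.scar_len > self.tsd_len:
            raise ValueError(
                "default TSD-derived footprint requires scar_len <= tsd_len"
            )
        if self.footprint is not None and len(self.footprint) != self.scar_len:
            raise ValueError("footprint length must equal scar_len")

    def tsd(self, source_seq: str) -> str:
        s = self.insertion_site
        return source_seq[s: s + self.tsd_len]

    def scar_footprint(self, source_seq: str) -> str:
        if self.footprint is not None:
            return self.footprint
        return self.tsd(source_seq)[: self.scar_len]


def apply_te_insertion(
    haplotype_seq: str, te: TEInsertionSpec
) -> tuple[str, CoordinateMap]:
    """Insert the element with TSD duplication.

    Output is ``prefix · TSD · element · TSD · suffix``; its length is the
    input length plus element length plus ``tsd_len``.  The second TSD copy
    maps back to the original target-site bases (an aligner places it
    there), while element bases map to -1.
    """
    site = te.insertion_site
    if not 0 < site < len(haplotype_seq) - te.tsd_len:
        raise ValueError("insertion_site outside sequence")
    tsd = te.tsd(haplotype_seq)
    cut = site + te.tsd_len
    seq = haplotype_seq[:cut] + te.element_sequence + tsd + haplotype_seq[cut:]
    n_in = len(haplotype_seq)
    ref_of = np.concatenate([
        np.arange(cut, dtype=np.int64),
        np.full(len(te.element_sequence), -1, dtype=np.int64),
        np.arange(site, site + te.tsd_len, dtype=np.int64),
        np.arange(cut, n_in, dtype=np.int64),
    ])
    return seq, CoordinateMap(ref_of)


def apply_te_excision(
    te_haplotype_seq: str, te: TEInsertionSpec
) -> tuple[str, CoordinateMap]:
    """Excise the element, leaving the scar footprint.

    The input must carry the TE allele produced by
    :func:`apply_te_insertion`.  The output differs from the never-inserted
    sequence by exactly a ``scar_len`` insertion at the site.  Footprint
    bases map to -1 (novel relative to the pre-insertion state), so
    composing the insertion map with this map reproduces the map of a
    direct scar insertion.
    """
    idx = te_haplotype_seq.find(te.element_sequence)
    if idx < 0:
        raise ValueError("input sequence does not carry the TE element")
    elem_end = idx + len(te.element_sequence)
    tsd1 = te_haplotype_seq[idx - te.tsd_len: idx]
    tsd2 = te_haplotype_seq[elem_end: elem_end + te.tsd_len]
    if te.tsd_len and tsd1 != tsd2:
        raise ValueError("element not flanked by matching TSD copies")
    footprint = (te.footprint if te.footprint is not None
                 else tsd1[: te.scar_len])
    seq = te_haplotype_seq[:idx] + footprint + \
        te_haplotype_seq[elem_end + te.tsd_len:]
    n_in = len(te_haplotype_seq)
    ref_of = np.concatenate([
        np.arange(idx, dtype=np.int64),
        np.full(len(footprint), -1, dtype=np.int64),
        np.arange(elem_end + te.tsd_len, n_in, dtype=np.int64),
    ])
    return seq, CoordinateMap(ref_of)


# ---------------------------------------------------------------------------
# haplotypes
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeSpec:
    """One haplotype class of the tetraploid genotype.

    ``small_variants`` are ``(pos, ref_allele, alt_allele)`` in reference
    coordinates (substitutions or short indels, e.g. an in-frame 3-bp
    deletion).  ``copy_count`` copies of this haplotype are present; counts
    across all specs must sum to the ploidy (4).
    """

    allele_class_label: str
    small_variants: list[tuple[int, str, str]] = field(default_factory=list)
    copy_count: int = 1
    te: TEInsertionSpec | None = None

    def __post_init__(self) -> None:
        if self.allele_class_label not in (INTACT, TE, SCAR):
            raise ValueError(f"unknown class {self.allele_class_label}")
        if self.allele_class_label in (TE, SCAR) and self.te is None:
            raise ValueError(f"{self.allele_class_label} spec requires te")


@dataclass
class HaplotypeCopy:
    """A realised haplotype copy: sequence plus map to the reference."""

    label: str
    seq: str
    cmap: CoordinateMap
    spec: HaplotypeSpec


def build_haplotype(genome: GenomeModel, spec: HaplotypeSpec) -> HaplotypeCopy:
    """Realise one haplotype copy from the reference."""
    ref = genome.sequence
    seq = ref
    cmap = CoordinateMap.identity(len(ref))
    # small variants first (reference coordinates), right-to-left so that
    # earlier edits do not shift later ones
    for pos, ref_allele, alt in sorted(spec.small_variants, reverse=True):
        if ref[pos: pos + len(ref_allele)] != ref_allele:
            raise ValueError(
                f"variant at {pos}: reference is "
                f"{ref[pos: pos + len(ref_allele)]!r}, not {ref_allele!r}"
            )
        hits = np.flatnonzero(cmap.ref_of == pos)
        if len(hits) == 0:
            raise ValueError(f"variant position {pos} removed by prior edit")
        hap_pos = int(hits[0])
        seq = seq[:hap_pos] + alt + seq[hap_pos + len(ref_allele):]
        alt_map = (np.arange(pos, pos + len(alt), dtype=np.int64)
                   if len(alt) == len(ref_allele)
                   else np.full(len(alt), -1, dtype=np.int64))
        cmap = CoordinateMap(np.concatenate([
            cmap.ref_of[:hap_pos], alt_map,
            cmap.ref_of[hap_pos + len(ref_allele):],
        ]))
    if spec.allele_class_label == INTACT:
        return HaplotypeCopy(INTACT, seq, cmap, spec)

    te = spec.te
    assert te is not None
    # translate the insertion site through any upstream indels
    site_hits = np.flatnonzero(cmap.ref_of == te.insertion_site)
    if len(site_hits) == 0:
        raise ValueError("insertion site removed by small variant")
    shifted = TEInsertionSpec(
        te.element_sequence,
        int(site_hits[0]),
        te.tsd_len, te.scar_len, te.footprint, te.min_clip_match,
    )
    te_seq, te_map = apply_te_insertion(seq, shifted)
    if spec.allele_class_label == TE:
        return HaplotypeCopy(TE, te_seq, te_map.compose(cmap), spec)
    scar_seq, scar_map = apply_te_excision(te_seq, shifted)
    return HaplotypeCopy(
        SCAR, scar_seq, scar_map.compose(te_map).compose(cmap), spec
    )


def expand_copies(genome: GenomeModel,
                  haplotypes: Sequence[HaplotypeSpec],
                  ploidy: int = 4) -> list[HaplotypeCopy]:
    """Expand specs into the ``ploidy`` realised haplotype copies."""
    total = sum(h.copy_count for h in haplotypes)
    if total != ploidy:
        raise ValueError(f"copy counts sum to {total}, expected {ploidy}")
    copies = []
    for spec in haplotypes:
        built = build_haplotype(genome, spec)
        copies.extend([built] * spec.copy_count)
    return copies


# ---------------------------------------------------------------------------
# chimera and read-simulation parameters
# ---------------------------------------------------------------------------

@dataclass
class ChimeraSpec:
    """Periclinal chimera: leaf layer fractions and the somatic event.

    ``mutant_layers`` is the subset of {L1, L2, L3} whose cells carry the
    somatic change; ``mutant_event`` names the change, currently
    ``te_to_scar`` (TE excision on one TE haplotype copy, by default the
    first; set ``mutant_copy`` to override).
    """

    layer_fractions: tuple[float, float, float] = DEFAULT_LAYER_FRACTIONS
    mutant_layers: frozenset[str] = frozenset()
    mutant_event: str = "te_to_scar"
    mutant_copy: int | None = None

    def __post_init__(self) -> None:
        self.mutant_layers = frozenset(self.mutant_layers)
        if abs(sum(self.layer_fractions) - 1.0) > 1e-9:
            raise ValueError("layer fractions must sum to 1")
        if any(f < 0 for f in self.layer_fractions):
            raise ValueError("layer fractions must be >= 0")
        if not self.mutant_layers <= set(LAYERS):
            raise ValueError(f"mutant_layers must be within {LAYERS}")


@dataclass
class ReadSimParams:
    """Illumina-like paired-end simulation parameters.

    Defaults model a 40-fold whole-locus library of 2x150 bp reads with
    400±60 bp fragments and a 1e-3 per-base substitution error rate
    (no indel errors, so truth edits stay unambiguous).
    """

    coverage: float = 40.0
    read_len: int = 150
    fragment_mean: float = 400.0
    fragment_sd: float = 60.0
    sub_error_rate: float = 0.001
    seed: int = 0
    qual_char: str = "I"

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.fragment_mean <= self.read_len:
            raise ValueError("fragment_mean must exceed read_len")


@dataclass
class TruthRecord:
    """Truth labels for one simulated read."""

    read_id: str
    mate: int
    haplotype_index: int
    layer: str
    allele_class: str
    ref_start: int
    ref_end: int
    edit: str  # CIGAR string of the truth alignment, or '*' if unmapped

    def as_row(self) -> dict:
        return {
            "read_id": self.read_id, "mate": self.mate,
            "haplotype_index": self.haplotype_index, "layer": self.layer,
            "allele_class": self.allele_class,
            "ref_start": self.ref_start, "ref_end": self.ref_end,
            "edit": self.edit,
        }


TRUTH_COLUMNS = ("read_id", "mate", "haplotype_index", "layer",
                 "allele_class", "ref_start", "ref_end", "edit")


# ---------------------------------------------------------------------------
# read projection: haplotype interval -> reference alignment
# ---------------------------------------------------------------------------

def project_interval(
    cmap: CoordinateMap, start: int, length: int, gap_op_threshold: int = 0
) -> tuple[int, list[tuple[str, int]]]:
    """Project a haplotype interval to a reference alignment.

    Returns ``(ref_start, cigar)``; ``ref_start`` is -1 with an empty CIGAR
    when no base has a reference correspondence (read fully inside the
    element).  Unmapped bases at the ends become soft clips, interior
    unmapped runs become insertions, and jumps in the reference become
    deletions (or ``N`` skips when the jump is >= ``gap_op_threshold`` > 0,
    for spliced RNA alignments).
    """
    refs = cmap.ref_of[start: start + length]
    mapped = np.flatnonzero(refs >= 0)
    if len(mapped) == 0:
        return -1, []
    first, last = int(mapped[0]), int(mapped[-1])
    cigar: list[tuple[str, int]] = []
    if first > 0:
        cigar.append(("S", first))
    run_ins = 0
    prev_ref: int | None = None
    match_len = 0
    for i in range(first, last + 1):
        r = int(refs[i])
        if r < 0:
            run_ins += 1
            continue
        if prev_ref is None:
            match_len = 1
        else:
            if run_ins:
                cigar.append(("M", match_len))
                cigar.append(("I", run_ins))
                match_len = 0
                run_ins = 0
            gap = r - prev_ref - 1
            if gap == 0:
                match_len += 1
            elif gap > 0:
                if match_len:
                    cigar.append(("M", match_len))
                op = ("N" if gap_op_threshold and gap >= gap_op_threshold
                      else "D")
                cigar.append((op, gap))
                match_len = 1
            else:
                raise ValueError("non-monotonic coordinate map within read")
        prev_ref = r
    if match_len:
        cigar.append(("M", match_len))
    if last < len(refs) - 1:
        cigar.append(("S", len(refs) - 1 - last))
    return int(refs[first]), cigar


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass
class SimRead:
    qname: str
    r1_seq: str
    r2_seq: str
    aln1: AlignedRead
    aln2: AlignedRead
    truth1: TruthRecord
    truth2: TruthRecord


@dataclass
class SimResult:
    """Reads, truth alignments and truth labels from one simulation."""

    genome: GenomeModel
    params: ReadSimParams
    reads: list[SimRead]

    def fastq_records(self, mate: int) -> list[tuple[str, str, str]]:
        q = self.params.qual_char * self.params.read_len
        if mate == 1:
            return [(r.qname + "/1", r.r1_seq, q) for r in self.reads]
        return [(r.qname + "/2", r.r2_seq, q) for r in self.reads]

    def truth_alignments(self) -> list[AlignedRead]:
        """All truth alignments, coordinate-sorted, unmapped last."""
        alns = [a for r in self.reads for a in (r.aln1, r.aln2)]
        return sorted(
            alns, key=lambda a: (a.is_unmapped, a.start, a.qname)
        )

    def truth_records(self) -> list[TruthRecord]:
        return [t for r in self.reads for t in (r.truth1, r.truth2)]

    def write(self, outdir: str | Path, prefix: str = "sim") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "r1": outdir / f"{prefix}_R1.fastq",
            "r2": outdir / f"{prefix}_R2.fastq",
            "sam": outdir / f"{prefix}.truth.sam",
            "truth": outdir / f"{prefix}.truth.tsv",
            "fasta": outdir / f"{prefix}.ref.fasta",
            "gff": outdir / f"{prefix}.genes.gff3",
        }
        alnio.write_fastq(paths["r1"], self.fastq_records(1))
        alnio.write_fastq(paths["r2"], self.fastq_records(2))
        alnio.write_sam(
            paths["sam"],
            alnio.sam_header(self.genome.name, len(self.genome)),
            self.truth_alignments(),
        )
        alnio.write_tsv(paths["truth"],
                        (t.as_row() for t in self.truth_records()),
                        TRUTH_COLUMNS)
        alnio.write_fasta(paths["fasta"],
                          [(self.genome.name, self.genome.sequence)])
        alnio.write_gff3(paths["gff"], self.genome.name, self.genome.genes)
        return paths


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hit:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(0, 3))]
    return "".join(arr)


def _make_pair(
    qname: str,
    hap: HaplotypeCopy,
    frag_start: int,
    frag_len: int,
    layer: str,
    hap_index: int,
    params: ReadSimParams,
    rng: np.random.Generator,
    rname: str,
    gap_op_threshold: int = 0,
    cmap_override: CoordinateMap | None = None,
    seq_override: str | None = None,
) -> SimRead:
    rl = params.read_len
    seq = seq_override if seq_override is not None else hap.seq
    cmap = cmap_override if cmap_override is not None else hap.cmap
    r1 = _apply_errors(seq[frag_start: frag_start + rl],
                       params.sub_error_rate, rng)
    r2_start = frag_start + frag_len - rl
    r2_ref_oriented = _apply_errors(seq[r2_start: r2_start + rl],
                                    params.sub_error_rate, rng)

    s1, cig1 = project_interval(cmap, frag_start, rl, gap_op_threshold)
    s2, cig2 = project_interval(cmap, r2_start, rl, gap_op_threshold)

    f1 = FLAG_PAIRED | FLAG_READ1
    f2 = FLAG_PAIRED | FLAG_READ2 | FLAG_REVERSE
    f1 |= FLAG_MATE_REVERSE
    if s1 < 0:
        f1 |= FLAG_UNMAPPED
        f2 |= FLAG_MATE_UNMAPPED
    if s2 < 0:
        f2 |= FLAG_UNMAPPED
        f1 |= FLAG_MATE_UNMAPPED

    aln1 = AlignedRead(
        qname=qname, rname=rname if s1 >= 0 else None, start=s1,
        cigar=cig1, seq=r1, mapq=60, flags=f1,
        mate_rname=rname if s2 >= 0 else None, mate_start=s2,
    )
    aln2 = AlignedRead(
        qname=qname, rname=rname if s2 >= 0 else None, start=s2,
        cigar=cig2, seq=r2_ref_oriented, mapq=60, flags=f2,
        mate_rname=rname if s1 >= 0 else None, mate_start=s1,
    )

    def cigstr(cig: list[tuple[str, int]]) -> str:
        return "".join(f"{n}{op}" for op, n in cig) if cig else "*"

    t1 = TruthRecord(qname, 1, hap_index, layer, hap.label,
                     s1, aln1.end if s1 >= 0 else -1, cigstr(cig1))
    t2 = TruthRecord(qname, 2, hap_index, layer, hap.label,
                     s2, aln2.end if s2 >= 0 else -1, cigstr(cig2))
    return SimRead(qname, r1, revcomp(r2_ref_oriented), aln1, aln2, t1, t2)


def _layer_copy_sets(
    genome: GenomeModel,
    haplotypes: Sequence[HaplotypeSpec],
    chimera: ChimeraSpec,
) -> dict[str, list[HaplotypeCopy]]:
    """Per-layer haplotype copy lists, applying the somatic event."""
    base = expand_copies(genome, haplotypes)
    mutant_copies = base
    if chimera.mutant_layers and chimera.mutant_event == "te_to_scar":
        idx = chimera.mutant_copy
        if idx is None:
            te_indices = [i for i, c in enumerate(base) if c.label == TE]
            if not te_indices:
                raise ValueError("te_to_scar event but no TE haplotype copy")
            idx = te_indices[0]
        if base[idx].label != TE:
            raise ValueError(f"mutant copy {idx} is not a TE haplotype")
        spec = base[idx].spec
        scar_spec = HaplotypeSpec(SCAR, spec.small_variants, 1, spec.te)
        mutant_copies = list(base)
        mutant_copies[idx] = build_haplotype(genome, scar_spec)
    return {
        layer: (mutant_copies if layer in chimera.mutant_layers else base)
        for layer in LAYERS
    }


def simulate_chimera_reads(
    genome: GenomeModel,
    haplotypes: Sequence[HaplotypeSpec],
    chimera: ChimeraSpec,
    params: ReadSimParams,
    read_prefix: str = "sim",
) -> SimResult:
    """Simulate leaf DNA paired-end reads from a layered chimera.

    Each fragment samples a layer by the layer fractions, then one of the
    four haplotype copies uniformly (the somatic event applies in mutant
    layers), then a fragment position and length, then substitution
    errors.  Truth alignments are reference projections: reads crossing a
    TE junction carry soft clips, scar-spanning reads carry the scar
    insertion, and reads fully inside the element are recorded unmapped.
    """
    rng = np.random.default_rng(params.seed)
    layer_copies = _layer_copy_sets(genome, haplotypes, chimera)
    fracs = np.asarray(chimera.layer_fractions, dtype=float)
    # fragments per copy scale with the copy's number of valid fragment
    # placements (uniform shearing), so per-offset read-start density is
    # even across copies despite structural length differences
    copy_p = {
        layer: (lambda L: L / L.sum())(np.array(
            [max(1.0, len(c.seq) - params.fragment_mean + 1)
             for c in copies]))
        for layer, copies in layer_copies.items()
    }

    locus_len = len(genome)
    n_frags = int(round(params.coverage * locus_len / (2 * params.read_len)))
    reads: list[SimRead] = []
    for i in range(n_frags):
        layer = LAYERS[int(rng.choice(3, p=fracs))]
        hap_index = int(rng.choice(4, p=copy_p[layer]))
        hap = layer_copies[layer][hap_index]
        frag_len = max(params.read_len + 1,
                       int(round(rng.normal(params.fragment_mean,
                                            params.fragment_sd))))
        frag_len = min(frag_len, len(hap.seq))
        frag_start = int(rng.integers(0, len(hap.seq) - frag_len + 1))
        reads.append(_make_pair(
            f"{read_prefix}_{i:06d}", hap, frag_start, frag_len,
            layer, hap_index, params, rng, genome.name,
        ))
    return SimResult(genome, params, reads)


# ---------------------------------------------------------------------------
# RNA simulation
# ---------------------------------------------------------------------------

def transcript_of(hap: HaplotypeCopy, gene: GeneModel
                  ) -> tuple[str, CoordinateMap]:
    """Spliced transcript of ``gene`` on a haplotype copy.

    Exon intervals are projected through the haplotype's coordinate map;
    bases inserted inside an exon (TE element, scar) are part of the
    transcript.  Returned map sends transcript positions to reference
    positions (introns absent, so spliced reads project with ``N`` gaps).
    """
    parts: list[str] = []
    maps: list[np.ndarray] = []
    refs = hap.cmap.ref_of
    for (s, e) in gene.exons:
        inside = np.flatnonzero((refs >= s) & (refs < e))
        if len(inside) == 0:
            continue
        lo, hi = int(inside[0]), int(inside[-1]) + 1
        parts.append(hap.seq[lo:hi])
        maps.append(refs[lo:hi])
    seq = "".join(parts)
    return seq, CoordinateMap(np.concatenate(maps))


def simulate_rna_reads(
    genome: GenomeModel,
    haplotypes: Sequence[HaplotypeSpec],
    expression_weights: Sequence[float],
    params: ReadSimParams,
    gene: GeneModel | None = None,
    read_prefix: str = "rna",
) -> SimResult:
    """Simulate RNA paired-end reads with per-haplotype expression weights.

    Transcript molecules are sampled proportional to the weights and
    fragmented uniformly per base, so a copy's read count scales with
    weight × transcript length while its per-bp (and junction-window)
    read density scales with the weight alone.  Truth alignments are in
    genome coordinates with ``N`` ops across introns.
    """
    weights = np.asarray(expression_weights, dtype=float)
    if len(weights) != 4:
        raise ValueError("need one expression weight per haplotype copy (4)")
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("expression weights must be nonnegative, not all 0")
    rng = np.random.default_rng(params.seed)
    copies = expand_copies(genome, haplotypes)
    if gene is None:
        gene = _locus_gene(genome, haplotypes)
    transcripts = [transcript_of(c, gene) for c in copies]
    wl = weights * np.array(
        [max(1.0, len(t[0]) - params.fragment_mean + 1)
         for t in transcripts])
    p = wl / wl.sum()

    mean_tx = float(np.mean([len(t[0]) for t in transcripts]))
    n_frags = int(round(params.coverage * mean_tx / (2 * params.read_len)))
    reads: list[SimRead] = []
    for i in range(n_frags):
        hap_index = int(rng.choice(4, p=p))
        hap = copies[hap_index]
        tx_seq, tx_map = transcripts[hap_index]
        frag_len = max(params.read_len + 1,
                       int(round(rng.normal(params.fragment_mean,
                                            params.fragment_sd))))
        frag_len = min(frag_len, len(tx_seq))
        frag_start = int(rng.integers(0, len(tx_seq) - frag_len + 1))
        reads.append(_make_pair(
            f"{read_prefix}_{i:06d}", hap, frag_start, frag_len,
            "RNA", hap_index, params, rng, genome.name,
            gap_op_threshold=30, cmap_override=tx_map, seq_override=tx_seq,
        ))
    return SimResult(genome, params, reads)


def _locus_gene(genome: GenomeModel,
                haplotypes: Sequence[HaplotypeSpec]) -> GeneModel:
    """The gene containing the TE insertion site, else the first gene."""
    for h in haplotypes:
        if h.te is not None:
            for g in genome.genes:
                s, e = g.span
                if s <= h.te.insertion_site < e:
                    return g
    if not genome.genes:
        raise ValueError("genome has no genes")
    return genome.genes[0]


# ---------------------------------------------------------------------------
# canonical scenario
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    """A ready-to-simulate locus: genome, TE, genotype and chimera."""

    genome: GenomeModel
    te: TEInsertionSpec
    haplotypes: list[HaplotypeSpec]
    chimera: ChimeraSpec
    params: ReadSimParams
    gene: GeneModel

    def config(self) -> dict:
        return {
            "genome_length": len(self.genome),
            "seed": self.params.seed,
            "element_length": len(self.te.element_sequence),
            "insertion_site": self.te.insertion_site,
            "tsd_len": self.te.tsd_len,
            "scar_len": self.te.scar_len,
            "genotype": [h.allele_class_label for h in self.haplotypes
                         for _ in range(h.copy_count)],
            "layer_fractions": list(self.chimera.layer_fractions),
            "mutant_layers": sorted(self.chimera.mutant_layers),
            "coverage": self.params.coverage,
            "read_len": self.params.read_len,
        }

    def write_config(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.config(), indent=2) + "\n")


def default_scenario(
    seed: int,
    genotype: str = "txns",
    genome_length: int = 10_000,
    n_genes: int = 2,
    element_length: int = 800,
    mutant_layers: Iterable[str] = (),
    layer_fractions: tuple[float, float, float] = DEFAULT_LAYER_FRACTIONS,
    coverage: float = 40.0,
    plant_element_copy: bool = False,
    with_intact_deletion: bool = True,
    n_het_snps: int = 40,
    **param_overrides,
) -> Scenario:
    """Build the canonical locus scenario.

    Genotypes: ``rn`` = INTACT/INTACT/TE/TE (progenitor),
    ``txns`` = INTACT/INTACT/TE/TE with a somatic TE→scar excision in
    ``mutant_layers`` (the improved-clone situation), ``simplex_scar`` =
    INTACT/INTACT/TE/SCAR constitutively in all cells.  The TE sits in the
    second exon of a gene, inside its CDS, so the 7-bp scar is a
    frameshift; the two INTACT copies optionally carry an in-frame 3-bp
    CDS deletion.  ``plant_element_copy`` embeds one full-length copy of
    the element elsewhere in the reference, outside any gene.
    """
    rng = np.random.default_rng(seed + 104729)
    genome = make_reference(genome_length, n_genes, seed)
    gene = genome.genes[0]

    # insertion inside the CDS portion of the second exon
    ex2 = gene.exons[1]
    cds_in_ex2 = _clip_intervals(gene.cds, ex2[0], ex2[1])
    if not cds_in_ex2:
        raise ValueError("second exon has no CDS portion")
    s, e = cds_in_ex2[0]
    insertion_site = (s + e) // 2

    element = random_dna(rng, element_length)
    seq = genome.sequence
    if plant_element_copy:
        copy_pos = _free_interval(genome, element_length, rng)
        seq = (seq[:copy_pos] + element
               + seq[copy_pos + element_length:])
        genome = GenomeModel(seq, genome.genes, genome.seed, genome.name)

    te = TEInsertionSpec(element, insertion_site)

    small_variants: list[tuple[int, str, str]] = []
    if with_intact_deletion:
        cs, ce = gene.cds[0]
        dpos = cs + 3 * ((30) // 3)  # in-frame 3-bp deletion in the CDS
        small_variants = [(dpos, seq[dpos: dpos + 3], "")]

    # duplex heterozygous SNPs on the TE haplotype, intergenic, clear of
    # the junction: substrate for dosage calling and clonality checks
    te_snps: list[tuple[int, str, str]] = []
    if n_het_snps:
        spans = [g.span for g in genome.genes]
        if plant_element_copy:
            spans.append((copy_pos - 50, copy_pos + element_length + 50))
        used: set[int] = set()
        while len(te_snps) < n_het_snps:
            p = int(rng.integers(100, len(genome) - 100))
            if p in used or any(s - 5 <= p < e + 5 for s, e in spans):
                continue
            used.add(p)
            ref_b = seq[p]
            alt_b = "ACGT"[("ACGT".index(ref_b) + 1 + int(rng.integers(0, 3)))
                           % 4]
            te_snps.append((p, ref_b, alt_b))
        te_snps.sort()

    intact = HaplotypeSpec(INTACT, small_variants, 2)
    if genotype == "rn":
        haps = [intact, HaplotypeSpec(TE, te_snps, 2, te)]
        chim = ChimeraSpec(layer_fractions, frozenset())
    elif genotype == "txns":
        haps = [intact, HaplotypeSpec(TE, te_snps, 2, te)]
        chim = ChimeraSpec(layer_fractions, frozenset(mutant_layers))
    elif genotype == "simplex_scar":
        haps = [intact, HaplotypeSpec(TE, te_snps, 1, te),
                HaplotypeSpec(SCAR, te_snps, 1, te)]
        chim = ChimeraSpec(layer_fractions, frozenset())
    else:
        raise ValueError(f"unknown genotype {genotype!r}")

    params = ReadSimParams(coverage=coverage, seed=seed, **param_overrides)
    return Scenario(genome, te, haps, chim, params, gene)


def _free_interval(genome: GenomeModel, length: int,
                   rng: np.random.Generator) -> int:
    """A start position for ``length`` bp clear of all genes (+margin)."""
    spans = [(max(0, s - 200), e + 200)
             for s, e in (g.span for g in genome.genes)]
    for _ in range(1000):
        pos = int(rng.integers(200, len(genome) - length - 200))
        if all(pos + length <= s or pos >= e for s, e in spans):
            return pos
    raise ValueError("no gene-free interval available for element copy")
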