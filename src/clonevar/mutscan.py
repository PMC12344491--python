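"""Relaxed progenitor-vs-clone somatic mutation scan.

A deterministic threshold filter, not a probabilistic caller: a site is a
candidate when the clone shows at least ``min_alt_reads`` reads of a
non-reference allele, the progenitor shows at most
``max_control_alt_reads`` of the same allele, and both samples reach
minimum depth.  The permissive default of three supporting reads trades a
high false discovery rate for sensitivity to low-VAF somatic alleles in
layered chimeras; candidates found in every clone of an independent set
are the strongest leads.  Functional impact follows the common
variant-effect convention (HIGH = stop gain/loss, start loss, frameshift,
splice-site dinucleotide; MODERATE = missense, in-frame indel;
LOW = synonymous; NONCODING otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from Bio.Seq import Seq

from .alnio import PileupColumn
from .simdata import GeneModel, GenomeModel

HIGH = "HIGH"
MODERATE = "MODERATE"
LOW = "LOW"
NONCODING = "NONCODING"


@dataclass
class ScanParams:
    min_alt_reads: int = 3
    max_control_alt_reads: int = 0
    min_depth_case: int = 10
    min_depth_control: int = 10

    def __post_init__(self) -> None:
        if self.min_alt_reads < 1:
            raise ValueError("min_alt_reads must be >= 1")


@dataclass
class MutationCandidate:
    """One candidate somatic variant (SNV or short indel).

    ``pos``/``ref``/``alt`` use VCF-style alleles in 0-based coordinates
    (indels are anchored on the reference base left of the event).
    ``support`` maps sample name to ``(alt_count, depth)``.
    """

    pos: int
    ref: str
    alt: str
    support: dict[str, tuple[int, int]] = field(default_factory=dict)
    impact: str | None = None

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


def _column_alleles(col: PileupColumn, ref_seq: str
                    ) -> dict[tuple[int, str, str], int]:
    """All non-reference alleles observed in a column, with counts."""
    out: dict[tuple[int, str, str], int] = {}
    ref_base = ref_seq[col.pos].upper()
    for base, count in col.counts.items():
        if base in "ACGT" and base != ref_base and count > 0:
            out[(col.pos, ref_base, base)] = count
    for ins, count in col.insertions.items():
        out[(col.pos, ref_base, ref_base + ins)] = count
    for dlen, count in col.deletions.items():
        ref_allele = ref_seq[col.pos: col.pos + 1 + dlen].upper()
        out[(col.pos, ref_allele, ref_base)] = count
    return out


def scan_mutations(
    case_pileup: Sequence[PileupColumn],
    control_pileup: Sequence[PileupColumn],
    ref_seq: str,
    params: ScanParams | None = None,
    case_name: str = "case",
    control_name: str = "control",
) -> list[MutationCandidate]:
    """Threshold filter of case against control pileups.

    Emits exactly the alleles with case support >= ``min_alt_reads``,
    control support <= ``max_control_alt_reads`` and both depths at their
    minima, ordered by position then allele.  Multi-allelic sites yield
    one candidate per alt allele.
    """
    params = params or ScanParams()
    control_by_pos = {c.pos: c for c in control_pileup}
    candidates = []
    for col in case_pileup:
        if col.depth < params.min_depth_case:
            continue
        ctrl = control_by_pos.get(col.pos)
        ctrl_depth = ctrl.depth if ctrl is not None else 0
        if ctrl_depth < params.min_depth_control:
            continue
        ctrl_alleles = (_column_alleles(ctrl, ref_seq) if ctrl is not None
                        else {})
        for key, count in sorted(_column_alleles(col, ref_seq).items()):
            if count < params.min_alt_reads:
                continue
            if ctrl_alleles.get(key, 0) > params.max_control_alt_reads:
                continue
            pos, ref, alt = key
            candidates.append(MutationCandidate(
                pos, ref, alt,
                {case_name: (count, col.depth),
                 control_name: (ctrl_alleles.get(key, 0), ctrl_depth)},
            ))
    return candidates


def shared_candidates(
    candidate_sets: Sequence[Sequence[MutationCandidate]],
) -> list[MutationCandidate]:
    """Candidates present in every set, keyed by (pos, ref, alt).

    Per-clone support maps are merged into the returned candidates.
    """
    if len(candidate_sets) < 2:
        raise ValueError("need candidate sets from at least two clones")
    keyed = [{c.key: c for c in cset} for cset in candidate_sets]
    common = set(keyed[0])
    for k in keyed[1:]:
        common &= set(k)
    out = []
    for key in sorted(common):
        merged = MutationCandidate(*key)
        for i, k in enumerate(keyed):
            for name, sup in k[key].support.items():
                merged.support[f"{name}{i + 1}" if name in merged.support
                               else name] = sup
        merged.impact = keyed[0][key].impact
        out.append(merged)
    return out


# ---------------------------------------------------------------------------
# functional impact
# ---------------------------------------------------------------------------

def _cds_index(gene: GeneModel, pos: int) -> int | None:
    """Coding-sequence index of genomic position, or None if non-CDS."""
    positions = gene.cds_positions()
    try:
        return positions.index(pos)
    except ValueError:
        return None


def _is_splice_site(gene: GeneModel, pos: int) -> bool:
    """Within the first/last two bases of an intron."""
    for (s1, e1), (s2, _) in zip(gene.exons, gene.exons[1:]):
        if e1 <= pos < e1 + 2 or s2 - 2 <= pos < s2:
            return True
    return False


_COMP = str.maketrans("ACGT", "TGCA")


def annotate_impact(
    candidate: MutationCandidate,
    genes: Sequence[GeneModel],
    genome: GenomeModel,
) -> str:
    """Classify a candidate's functional impact against gene models."""
    pos = candidate.pos
    if not 0 <= pos < len(genome):
        raise ValueError(f"candidate position {pos} outside genome")
    ref, alt = candidate.ref, candidate.alt

    for gene in genes:
        gstart, gend = gene.span
        if not (gstart - 2 <= pos < gend + 2):
            continue
        if _is_splice_site(gene, pos):
            return HIGH
        if candidate.is_snv:
            idx = _cds_index(gene, pos)
            if idx is None:
                continue
            coding = gene.coding_sequence(genome.sequence)
            codon_i = idx // 3
            within = idx % 3
            codon = list(coding[3 * codon_i: 3 * codon_i + 3])
            new_base = alt if gene.strand == "+" else alt.translate(_COMP)
            codon[within] = new_base
            old_aa = str(Seq(coding[3 * codon_i: 3 * codon_i + 3]).translate())
            new_aa = str(Seq("".join(codon)).translate())
            if codon_i == 0 and "".join(codon) != "ATG":
                return HIGH  # start loss
            if new_aa == "*" and old_aa != "*":
                return HIGH  # stop gain
            if old_aa == "*" and new_aa != "*":
                return HIGH  # stop loss
            return LOW if new_aa == old_aa else MODERATE
        # indel: anchored at pos, event occupies pos+1 onwards
        net = len(alt) - len(ref)
        event_lo = pos + 1
        event_hi = pos + max(len(ref), 2) - (1 if net > 0 else 0)
        in_cds = any(
            s <= p < e
            for s, e in gene.cds
            for p in range(event_lo, max(event_hi, event_lo + 1))
        )
        if not in_cds:
            continue
        return HIGH if net % 3 != 0 else MODERATE
    return NONCODING
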