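"""Structural allele typing at a TE insertion/excision locus.

Reads overlapping the locus are assigned to allele classes by their
alignment signature:

* ``SCAR`` — the read spans the insertion point with anchored alignment on
  both sides and carries a small insertion matching the excision scar;
* ``TE_JUNCTION`` — the read is soft-clipped at the junction and the clip
  matches a TE terminal sequence, or its mate lies inside the element;
* ``INTACT`` — the read spans the insertion point with full anchors and no
  scar or clip signature;
* ``AMBIGUOUS`` — anything else (not informative).

Class counts over informative (non-ambiguous) reads give the variant
allele frequency with a Wilson 95% interval.  The inserted element itself
is reconstructed from the soft-clip flanks of junction reads: the longest
left/right clips are consensus-called and located elsewhere in the genome
by seeded ungapped search, pairing 5′ and 3′ hits to infer the element's
full length.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .alnio import AlignedRead
from .simdata import GenomeModel, Scenario, revcomp

INTACT = "INTACT"
TE_JUNCTION = "TE_JUNCTION"
SCAR = "SCAR"
AMBIGUOUS = "AMBIGUOUS"

CLASSES = (INTACT, TE_JUNCTION, SCAR)


@dataclass
class LocusAlleleModel:
    """Declarative alignment signatures of the allele classes at a locus.

    ``insertion_site`` is the 0-based reference coordinate of the target
    site; the TSD occupies ``[insertion_site, insertion_site + tsd_len)``.
    Reads from the TE allele clip on their right at
    ``insertion_site + tsd_len`` (clip = element 5′ terminus) or on their
    left at ``insertion_site`` (clip = element 3′ terminus); the excision
    scar is an insertion at ``insertion_site + tsd_len``.
    """

    locus: tuple[int, int]
    insertion_site: int
    tsd_len: int
    scar_seq: str
    te_terminal_5p: str
    te_terminal_3p: str
    known_variants: list[tuple[int, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.te_terminal_5p or not self.te_terminal_3p:
            raise ValueError("TE terminal sequences must be non-empty")
        if not self.scar_seq:
            raise ValueError("scar sequence must be non-empty")

    @property
    def scar_len(self) -> int:
        return len(self.scar_seq)

    @property
    def left_junction(self) -> int:
        """Reference position where right-clipped TE reads end."""
        return self.insertion_site + self.tsd_len

    @property
    def right_junction(self) -> int:
        """Reference position where left-clipped TE reads start."""
        return self.insertion_site

    @property
    def insertion_point(self) -> int:
        """Reference coordinate immediately right of the scar insertion."""
        return self.insertion_site + self.tsd_len

    def to_json(self, path: str | Path) -> None:
        data = {
            "locus": list(self.locus),
            "insertion_site": self.insertion_site,
            "tsd_len": self.tsd_len,
            "scar_seq": self.scar_seq,
            "te_terminal_5p": self.te_terminal_5p,
            "te_terminal_3p": self.te_terminal_3p,
            "known_variants": [list(v) for v in self.known_variants],
        }
        Path(path).write_text(json.dumps(data, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "LocusAlleleModel":
        data = json.loads(Path(path).read_text())
        return cls(
            locus=tuple(data["locus"]),
            insertion_site=data["insertion_site"],
            tsd_len=data["tsd_len"],
            scar_seq=data["scar_seq"],
            te_terminal_5p=data["te_terminal_5p"],
            te_terminal_3p=data["te_terminal_3p"],
            known_variants=[tuple(v) for v in data.get("known_variants", [])],
        )


def locus_model_from_scenario(scenario: Scenario,
                              terminal_len: int = 30,
                              locus_margin: int = 2000) -> LocusAlleleModel:
    """Build the allele model a simulated scenario implies."""
    te = scenario.te
    site = te.insertion_site
    elem = te.element_sequence
    return LocusAlleleModel(
        locus=(max(0, site - locus_margin),
               min(len(scenario.genome), site + locus_margin)),
        insertion_site=site,
        tsd_len=te.tsd_len,
        scar_seq=te.scar_footprint(scenario.genome.sequence),
        te_terminal_5p=elem[:terminal_len],
        te_terminal_3p=elem[-terminal_len:],
        known_variants=[v for h in scenario.haplotypes
                        for v in h.small_variants],
    )


@dataclass
class ClassifyParams:
    """Signature-matching thresholds.

    ``min_clip_match``: minimum clip length considered junction evidence;
    ``slop``: tolerated offset (bp) between an observed breakpoint and the
    model's junction; ``anchor``: aligned bases required on each side of
    the insertion point for a spanning (INTACT / SCAR) call;
    ``min_identity``: clip-vs-terminal identity; ``use_mate_evidence``:
    count an unmapped mate (a mate inside the element) as TE evidence.
    """

    min_clip_match: int = 12
    slop: int = 2
    anchor: int = 5
    min_identity: float = 0.9
    use_mate_evidence: bool = True


@dataclass
class ReadCall:
    read_id: str
    assigned_class: str
    evidence: dict = field(default_factory=dict)


def _identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    return sum(x == y for x, y in zip(a[:n], b[:n])) / n


def _edit_distance_le1(a: str, b: str) -> bool:
    """True iff Levenshtein distance between a and b is <= 1."""
    if a == b:
        return True
    la, lb = len(a), len(b)
    if abs(la - lb) > 1:
        return False
    if la == lb:
        return sum(x != y for x, y in zip(a, b)) <= 1
    if la > lb:
        a, b, la, lb = b, a, lb, la
    # b is one longer: a must equal b with one base removed
    i = 0
    while i < la and a[i] == b[i]:
        i += 1
    return a[i:] == b[i + 1:]


def _aligned_flanks(read: AlignedRead, point: int) -> tuple[int, int]:
    """Aligned (M) bases strictly left / right of reference ``point``."""
    left = right = 0
    r = read.start
    for op, n in read.cigar:
        if op in "M=X":
            left += max(0, min(r + n, point) - r)
            right += max(0, r + n - max(r, point))
            r += n
        elif op in "DN":
            r += n
    return left, right


def _insertions(read: AlignedRead) -> list[tuple[int, str]]:
    """(reference insertion point, inserted sequence) for each I op."""
    out = []
    q = 0
    r = read.start
    for op, n in read.cigar:
        if op in "M=X":
            q += n
            r += n
        elif op == "I":
            out.append((r, read.seq[q: q + n]))
            q += n
        elif op == "S":
            q += n
        elif op in "DN":
            r += n
    return out


def classify_read(
    read: AlignedRead,
    model: LocusAlleleModel,
    params: ClassifyParams | None = None,
) -> ReadCall:
    """Assign one aligned read to an allele class by its signature.

    Precedence: scar insertion, then junction clip / mate evidence, then
    anchored reference-like span; reads with none of these signatures —
    including short clips below ``min_clip_match`` at the junction — are
    AMBIGUOUS and excluded from VAF denominators.
    """
    params = params or ClassifyParams()
    if read.is_unmapped or not read.overlaps(*model.locus):
        raise ValueError(f"read {read.qname} does not overlap the locus")

    point = model.insertion_point
    slop = params.slop

    # spanning requires anchors outside the whole TSD block, so TE reads
    # aligned only within the duplicated target site cannot pass as INTACT
    left_aln, _ = _aligned_flanks(read, model.right_junction)
    _, right_aln = _aligned_flanks(read, point)
    spans = left_aln >= params.anchor and right_aln >= params.anchor
    if spans:
        for ipos, iseq in _insertions(read):
            if abs(ipos - point) <= slop + model.scar_len and \
                    _edit_distance_le1(iseq, model.scar_seq):
                return ReadCall(read.qname, SCAR, {
                    "insertion": iseq, "insertion_point": ipos,
                })

    # junction clips (aligned part must itself be anchored)
    aligned_len = sum(n for op, n in read.cigar if op in "M=X")
    rc = read.right_clip
    if len(rc) >= params.min_clip_match and aligned_len >= params.anchor and \
            abs(read.end - model.left_junction) <= slop:
        ident = _identity(rc, model.te_terminal_5p)
        if ident >= params.min_identity:
            return ReadCall(read.qname, TE_JUNCTION, {
                "clip_side": "right", "clip_seq": rc, "clip_len": len(rc),
                "identity": ident,
            })
    lc = read.left_clip
    if len(lc) >= params.min_clip_match and aligned_len >= params.anchor and \
            abs(read.start - model.right_junction) <= slop:
        term = model.te_terminal_3p
        a, b = lc[-min(len(lc), len(term)):], term[-min(len(lc), len(term)):]
        ident = _identity(a, b)
        if ident >= params.min_identity:
            return ReadCall(read.qname, TE_JUNCTION, {
                "clip_side": "left", "clip_seq": lc, "clip_len": len(lc),
                "identity": ident,
            })

    # mate inside the element (unaligned at the locus)
    if params.use_mate_evidence and read.mate_is_unmapped:
        return ReadCall(read.qname, TE_JUNCTION, {"mate_unmapped": True})

    if spans:
        junctions = (model.left_junction, model.right_junction)
        clip_at_junction = (
            (rc and min(abs(read.end - j) for j in junctions) <= slop)
            or (lc and min(abs(read.start - j) for j in junctions) <= slop)
        )
        if not clip_at_junction:
            return ReadCall(read.qname, INTACT, {
                "left_anchor": left_aln, "right_anchor": right_aln,
            })

    return ReadCall(read.qname, AMBIGUOUS, {})


def classify_reads(
    reads: Iterable[AlignedRead],
    model: LocusAlleleModel,
    params: ClassifyParams | None = None,
) -> list[ReadCall]:
    """Classify every mapped read overlapping the locus."""
    calls = []
    for read in reads:
        if read.is_unmapped or not read.overlaps(*model.locus):
            continue
        calls.append(classify_read(read, model, params))
    return calls


# ---------------------------------------------------------------------------
# VAF estimation
# ---------------------------------------------------------------------------

def wilson_interval(k: int, n: int, conf: float = 0.95
                    ) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    from scipy import stats as _st
    z = _st.norm.ppf(0.5 + conf / 2)
    if n == 0:
        return 0.0, 1.0
    p = k / n
    denom = 1 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return max(0.0, centre - half), min(1.0, centre + half)


@dataclass
class VAFEstimate:
    """k-of-n variant allele frequency with a Wilson 95% interval."""

    target_class: str
    k: int
    n: int
    ci_low: float
    ci_high: float

    @property
    def vaf(self) -> float:
        return self.k / self.n

    def as_dict(self) -> dict:
        return {"target_class": self.target_class, "k": self.k, "n": self.n,
                "vaf": self.vaf, "ci_low": self.ci_low,
                "ci_high": self.ci_high}


def estimate_vaf(calls: Sequence[ReadCall], target_class: str,
                 conf: float = 0.95) -> VAFEstimate | None:
    """VAF of ``target_class`` over informative (non-ambiguous) calls.

    Returns ``None`` when no call is informative.
    """
    informative = [c for c in calls if c.assigned_class != AMBIGUOUS]
    n = len(informative)
    if n == 0:
        return None
    k = sum(c.assigned_class == target_class for c in informative)
    lo, hi = wilson_interval(k, n, conf)
    return VAFEstimate(target_class, k, n, lo, hi)


def class_widths(model: LocusAlleleModel, params: ClassifyParams,
                 read_len: int) -> dict[str, int]:
    """Number of read start offsets yielding each class's signature.

    A read of length L from an INTACT haplotype must cover the TSD block
    plus ``anchor`` bases each side, so it is callable from
    L − tsd − 2·anchor + 1 start positions; a SCAR read additionally
    spends ``scar_len`` query bases on the insertion; a TE read is
    callable at either junction with ``min_clip_match`` clipped and
    ``anchor`` aligned bases.  Because these ascertainment windows
    differ, raw class counts over- or under-represent alleles; dividing
    each count by its width recovers per-copy rates (mate-only evidence,
    whose window depends on fragment length, is excluded from frequency
    estimation).
    """
    w_intact = read_len - model.tsd_len - 2 * params.anchor + 1
    w_scar = read_len - model.tsd_len - model.scar_len \
        - 2 * params.anchor + 1
    w_te = 2 * (read_len - params.min_clip_match - params.anchor + 1)
    if min(w_intact, w_scar, w_te) <= 0:
        raise ValueError("read length too short for these thresholds")
    return {INTACT: w_intact, SCAR: w_scar, TE_JUNCTION: w_te}


def class_rates(calls: Sequence[ReadCall],
                widths: dict[str, int]) -> dict[str, float]:
    """Ascertainment-corrected per-class rates (counts / width).

    Mate-evidence-only TE calls are dropped: their evidence window scales
    with fragment size, not read length.
    """
    counts = {cls: 0 for cls in CLASSES}
    for call in calls:
        cls = call.assigned_class
        if cls == AMBIGUOUS:
            continue
        if cls == TE_JUNCTION and "clip_side" not in call.evidence:
            continue
        counts[cls] += 1
    return {cls: counts[cls] / widths[cls] for cls in CLASSES}


def estimate_locus_vaf(
    calls: Sequence[ReadCall],
    model: LocusAlleleModel,
    target_class: str = SCAR,
    params: ClassifyParams | None = None,
    read_len: int = 150,
    conf: float = 0.95,
) -> VAFEstimate | None:
    """Ascertainment-corrected allele frequency of ``target_class``.

    Class counts are divided by their signature widths
    (:func:`class_widths`) so that each haplotype copy contributes equally
    regardless of class; the frequency is the target's share of the summed
    rates.  Reported ``k``/``n`` are rescaled to the target's width so
    that ``k/n`` equals the corrected estimate, with a Wilson interval at
    that effective sample size.  Returns ``None`` with no informative
    reads.
    """
    params = params or ClassifyParams()
    widths = class_widths(model, params, read_len)
    rates = class_rates(calls, widths)
    total = sum(rates.values())
    if total == 0:
        return None
    w_t = widths[target_class]
    k = int(round(rates[target_class] * w_t))
    n = max(k, int(round(total * w_t)))
    lo, hi = wilson_interval(k, n, conf)
    return VAFEstimate(target_class, k, n, lo, hi)


# ---------------------------------------------------------------------------
# element reconstruction from soft-clip flanks
# ---------------------------------------------------------------------------

@dataclass
class FlankSegments:
    """Consensus clip segments flanking the element.

    ``left`` is the consensus of right-side clips of reads aligned left of
    the element (= element 5′ terminus); ``right`` the consensus of
    left-side clips (= element 3′ terminus).
    """

    left: str
    right: str


def _consensus(clips: list[str], anchor_end: bool) -> str:
    """Majority-vote consensus over clips aligned at the junction end.

    ``anchor_end=False`` aligns clips at their start (5′ clips grow away
    from the junction rightward); ``anchor_end=True`` aligns at their end.
    Ties break toward the base from the longest clip.
    """
    if not clips:
        return ""
    longest = max(clips, key=len)
    length = len(longest)
    out = []
    for col in range(length):
        votes: dict[str, int] = {}
        for clip in clips:
            if anchor_end:
                idx = len(clip) - length + col
            else:
                idx = col
            if 0 <= idx < len(clip):
                b = clip[idx]
                votes[b] = votes.get(b, 0) + 1
        tie_base = longest[col]
        best = max(votes, key=lambda b: (votes[b], b == tie_base))
        out.append(best)
    return "".join(out)


def extract_flank_segments(te_calls: Sequence[ReadCall]) -> FlankSegments:
    """Consensus longest soft-clip flank on each side of the element.

    Right-side clips (reads ending at the left junction) are anchored at
    their first base; left-side clips (reads starting at the right
    junction) at their last base.  Sides with no junction clip return an
    empty segment.
    """
    right_clips = [c.evidence["clip_seq"] for c in te_calls
                   if c.evidence.get("clip_side") == "right"]
    left_clips = [c.evidence["clip_seq"] for c in te_calls
                  if c.evidence.get("clip_side") == "left"]
    return FlankSegments(
        left=_consensus(right_clips, anchor_end=False),
        right=_consensus(left_clips, anchor_end=True),
    )


@dataclass
class ElementHit:
    """A paired 5′/3′ flank match locating one element copy."""

    five_start: int
    five_end: int
    three_start: int
    three_end: int
    strand: str
    identity: float

    @property
    def element_start(self) -> int:
        return self.five_start if self.strand == "+" else self.three_start

    @property
    def element_end(self) -> int:
        return self.three_end if self.strand == "+" else self.five_end

    @property
    def element_length(self) -> int:
        return self.element_end - self.element_start


@dataclass
class SearchParams:
    seed_k: int = 15
    min_identity: float = 0.9
    max_element_len: int = 20_000


def _segment_hits(seq: str, segment: str, params: SearchParams
                  ) -> list[tuple[int, int, float]]:
    """Ungapped >=identity matches of ``segment`` in ``seq`` (one strand).

    Seeded with non-overlapping k-mers of the segment, extended without
    gaps across the full segment length.
    """
    k = params.seed_k
    if len(segment) < k:
        return []
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i: i + k], []).append(i)
    offsets = list(range(0, len(segment) - k + 1, k))
    if offsets[-1] != len(segment) - k:
        offsets.append(len(segment) - k)
    candidates: set[int] = set()
    for off in offsets:
        for pos in index.get(segment[off: off + k], ()):
            start = pos - off
            if 0 <= start <= len(seq) - len(segment):
                candidates.add(start)
    hits = []
    seg_arr = np.frombuffer(segment.encode(), dtype=np.uint8)
    seq_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    for start in sorted(candidates):
        window = seq_arr[start: start + len(segment)]
        ident = float(np.mean(window == seg_arr))
        if ident >= params.min_identity:
            hits.append((start, start + len(segment), ident))
    return hits


def locate_element(
    genome: GenomeModel,
    left_seg: str,
    right_seg: str,
    params: SearchParams | None = None,
) -> list[ElementHit]:
    """Locate element copies by pairing flank-segment matches.

    Each segment is matched on both strands by k-mer seeding and ungapped
    extension at >= ``min_identity``; 5′ and 3′ hits on the same strand in
    consistent order within ``max_element_len`` are paired, and the
    element length is the span from the 5′ hit start to the 3′ hit end.
    An empty list means no copy was found (not an error).
    """
    params = params or SearchParams()
    if min(len(left_seg), len(right_seg)) < params.seed_k:
        raise ValueError("flank segments shorter than the seed size")
    seq = genome.sequence
    hits: list[ElementHit] = []
    for strand in "+-":
        five = (left_seg if strand == "+" else revcomp(left_seg))
        three = (right_seg if strand == "+" else revcomp(right_seg))
        five_hits = _segment_hits(seq, five, params)
        three_hits = _segment_hits(seq, three, params)
        for fs, fe, fid in five_hits:
            for ts, te_, tid in three_hits:
                if strand == "+":
                    ordered = ts >= fs and te_ - fs <= params.max_element_len
                    h = ElementHit(fs, fe, ts, te_, "+", (fid + tid) / 2)
                else:
                    ordered = fe >= te_ and fe - ts <= params.max_element_len
                    h = ElementHit(fs, fe, ts, te_, "-", (fid + tid) / 2)
                if ordered and h.element_length > 0:
                    hits.append(h)
    hits.sort(key=lambda h: (h.element_start, h.strand))
    return hits
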