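"""Readers, writers and pileup construction for the standard formats the
pipeline touches (SAM/BAM, FASTA, FASTQ, GFF3, VCF, bedGraph, TSV).

All analysis modules consume :class:`AlignedRead` and :class:`PileupColumn`
so that format dialects stay out of the analysis code.  Coordinates are
0-based half-open internally; SAM/VCF/GFF output is 1-based per the
respective standards.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam

# SAM flag bits used here
FLAG_PAIRED = 0x1
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80

QUERY_OPS = frozenset("MISX=")
REF_OPS = frozenset("MDNX=")


class ParseError(ValueError):
    """A malformed alignment record."""


class OrderingError(ValueError):
    """Reads supplied out of coordinate order."""


@dataclass
class AlignedRead:
    """One read alignment.

    ``cigar`` is an ordered list of ``(op, length)`` with ops in
    ``M I D N S = X``; clip segments (``S``) may appear only at the ends.
    ``start`` is the 0-based leftmost reference position (-1 if unmapped).
    """

    qname: str
    rname: str | None
    start: int
    cigar: list[tuple[str, int]]
    seq: str
    mapq: int = 60
    flags: int = 0
    qual: str | None = None
    mate_rname: str | None = None
    mate_start: int = -1

    def __post_init__(self) -> None:
        if not self.is_unmapped:
            qlen = sum(n for op, n in self.cigar if op in QUERY_OPS)
            if qlen != len(self.seq):
                raise ParseError(
                    f"read {self.qname}: CIGAR consumes {qlen} query bases "
                    f"but sequence is {len(self.seq)} bp"
                )
            interior = [op for op, _ in self.cigar[1:-1]]
            if "S" in interior:
                raise ParseError(f"read {self.qname}: internal soft clip")

    # -- flag helpers -------------------------------------------------
    @property
    def is_unmapped(self) -> bool:
        return bool(self.flags & FLAG_UNMAPPED)

    @property
    def mate_is_unmapped(self) -> bool:
        return bool(self.flags & FLAG_MATE_UNMAPPED)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flags & FLAG_REVERSE)

    @property
    def strand(self) -> str:
        return "-" if self.is_reverse else "+"

    @property
    def end(self) -> int:
        """0-based exclusive rightmost reference position."""
        return self.start + sum(n for op, n in self.cigar if op in REF_OPS)

    # -- clip accessors ----------------------------------------------
    @property
    def left_clip(self) -> str:
        if self.cigar and self.cigar[0][0] == "S":
            return self.seq[: self.cigar[0][1]]
        return ""

    @property
    def right_clip(self) -> str:
        if self.cigar and self.cigar[-1][0] == "S":
            return self.seq[len(self.seq) - self.cigar[-1][1]:]
        return ""

    def overlaps(self, start: int, end: int) -> bool:
        return not self.is_unmapped and self.start < end and self.end > start

    def aligned_pairs(self) -> Iterator[tuple[int, int, str]]:
        """Yield ``(query_pos, ref_pos, op)`` for M/=/X columns."""
        q = 0
        r = self.start
        for op, n in self.cigar:
            if op in "M=X":
                for i in range(n):
                    yield q + i, r + i, op
                q += n
                r += n
            elif op in "IS":
                q += n
            elif op in "DN":
                r += n
        return


@dataclass
class PileupColumn:
    """Per-position base/indel counts for one sample."""

    pos: int
    counts: dict[str, int] = field(
        default_factory=lambda: {"A": 0, "C": 0, "G": 0, "T": 0, "DEL": 0}
    )
    insertions: dict[str, int] = field(default_factory=dict)
    #: deletion events keyed by deleted length, anchored (like insertions)
    #: at the column left of the deleted bases
    deletions: dict[int, int] = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


def _cigar_from_pysam(cig: list[tuple[int, int]]) -> list[tuple[str, int]]:
    ops = "MIDNSHP=XB"
    return [(ops[o], n) for o, n in cig]


def read_alignments(
    path: str | Path,
    region: tuple[str, int, int] | None = None,
) -> Iterator[AlignedRead]:
    """Stream reads from a SAM/BAM file, optionally restricted to a region.

    Only mapped reads overlapping ``region = (rname, start, end)`` (0-based
    half-open) are yielded when a region is given; clip sequences are
    preserved.  Malformed records raise :class:`ParseError`.
    """
    path = Path(path)
    mode = "rb" if path.suffix == ".bam" else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
        for rec in af:
            try:
                read = AlignedRead(
                    qname=rec.query_name or "",
                    rname=rec.reference_name if rec.reference_id >= 0 else None,
                    start=rec.reference_start if not rec.is_unmapped else -1,
                    cigar=_cigar_from_pysam(rec.cigartuples or []),
                    seq=rec.query_sequence or "",
                    mapq=rec.mapping_quality,
                    flags=rec.flag,
                    qual=rec.qual,
                    mate_rname=(
                        rec.next_reference_name
                        if rec.next_reference_id >= 0
                        else None
                    ),
                    mate_start=rec.next_reference_start,
                )
            except ParseError:
                raise
            except Exception as exc:  # pragma: no cover - pysam internals
                raise ParseError(f"malformed record {rec.query_name}: {exc}")
            if region is None:
                yield read
            else:
                rname, start, end = region
                if read.rname == rname and read.overlaps(start, end):
                    yield read


def build_pileup(
    reads: Iterable[AlignedRead],
    region: tuple[int, int],
    min_mapq: int = 20,
    min_baseq: int = 20,
) -> list[PileupColumn]:
    """Build pileup columns over ``region`` (0-based half-open).

    Reads must be sorted by start position.  Deletions are counted in
    depth; clip segments are never counted.  Insertions are left-anchored:
    an insertion event is assigned to the column of the reference base
    immediately left of the inserted sequence (VCF convention).
    """
    start, end = region
    columns: dict[int, PileupColumn] = {}

    def col(pos: int) -> PileupColumn:
        c = columns.get(pos)
        if c is None:
            c = columns[pos] = PileupColumn(pos)
        return c

    last_start = -1
    for read in reads:
        if read.is_unmapped:
            continue
        if read.start < last_start:
            raise OrderingError(
                f"read {read.qname} at {read.start} after {last_start}"
            )
        last_start = read.start
        if read.mapq < min_mapq or not read.overlaps(start, end):
            continue
        q = 0
        r = read.start
        for op, n in read.cigar:
            if op in "M=X":
                for i in range(n):
                    pos = r + i
                    if start <= pos < end:
                        if read.qual is not None and (
                            ord(read.qual[q + i]) - 33 < min_baseq
                        ):
                            continue
                        base = read.seq[q + i].upper()
                        if base in "ACGT":
                            col(pos).counts[base] += 1
                q += n
                r += n
            elif op == "I":
                anchor = r - 1
                if start <= anchor < end:
                    ins = read.seq[q: q + n].upper()
                    c = col(anchor)
                    c.insertions[ins] = c.insertions.get(ins, 0) + 1
                q += n
            elif op == "S":
                q += n
            elif op in "DN":
                if op == "D":
                    anchor = r - 1
                    if start <= anchor < end:
                        c = col(anchor)
                        c.deletions[n] = c.deletions.get(n, 0) + 1
                    for i in range(n):
                        pos = r + i
                        if start <= pos < end:
                            col(pos).counts["DEL"] += 1
                r += n
    return [columns[p] for p in sorted(columns)]


# ---------------------------------------------------------------------------
# sequence / annotation writers
# ---------------------------------------------------------------------------

def write_fasta(path: str | Path, records: Sequence[tuple[str, str]],
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    out: list[tuple[str, str]] = []
    name = None
    parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    out.append((name, "".join(parts)))
                name = line[1:].split()[0]
                parts = []
            else:
                parts.append(line)
    if name is not None:
        out.append((name, "".join(parts)))
    return out


def write_fastq(path: str | Path,
                records: Iterable[tuple[str, str, str]]) -> None:
    """Write ``(name, seq, qual)`` records as Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def sam_header(ref_name: str, ref_len: int) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": ref_name, "LN": ref_len}],
    }


def write_sam(path: str | Path, header: dict,
              reads: Iterable[AlignedRead]) -> None:
    with pysam.AlignmentFile(str(path), "w", header=header) as af:
        for read in reads:
            rec = pysam.AlignedSegment(af.header)
            rec.query_name = read.qname
            rec.flag = read.flags
            if read.is_unmapped or read.rname is None:
                rec.reference_id = -1
                rec.reference_start = -1
            else:
                rec.reference_id = af.header.get_tid(read.rname)
                rec.reference_start = read.start
                ops = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4, "=": 7, "X": 8}
                rec.cigartuples = [(ops[o], n) for o, n in read.cigar]
            rec.mapping_quality = read.mapq
            rec.query_sequence = read.seq
            rec.query_qualities = pysam.qualitystring_to_array(
                read.qual if read.qual is not None else "I" * len(read.seq)
            )
            if read.mate_rname is not None:
                rec.next_reference_id = af.header.get_tid(read.mate_rname)
                rec.next_reference_start = read.mate_start
            af.write(rec)


def write_gff3(path: str | Path, ref_name: str, genes) -> None:
    """Write gene models (``simdata.GeneModel`` records) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            gstart = min(s for s, _ in g.exons) + 1
            gend = max(e for _, e in g.exons)
            fh.write(
                f"{ref_name}\tclonevar\tgene\t{gstart}\t{gend}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{ref_name}\tclonevar\texon\t{s + 1}\t{e}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )
            for s, e in g.cds:
                fh.write(
                    f"{ref_name}\tclonevar\tCDS\t{s + 1}\t{e}\t.\t"
                    f"{g.strand}\t0\tParent={g.gene_id}\n"
                )


def read_gff3(path: str | Path) -> list[dict]:
    """Parse gene models written by :func:`write_gff3`.

    Returns one dict per gene with keys ``gene_id``, ``strand``,
    ``exons`` and ``cds`` (0-based half-open intervals), suitable for
    ``simdata.GeneModel(**d)``.
    """
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != 9:
                raise ParseError(f"malformed GFF3 line: {line.rstrip()}")
            ftype, start, end, strand, attrs = (
                cells[2], int(cells[3]) - 1, int(cells[4]), cells[6], cells[8]
            )
            fields = dict(kv.split("=", 1) for kv in attrs.split(";") if kv)
            if ftype == "gene":
                genes[fields["ID"]] = {
                    "gene_id": fields["ID"], "strand": strand,
                    "exons": [], "cds": [],
                }
            elif ftype in ("exon", "CDS"):
                parent = fields["Parent"]
                key = "exons" if ftype == "exon" else "cds"
                genes[parent][key].append((start, end))
    for g in genes.values():
        g["exons"].sort()
        g["cds"].sort()
    return list(genes.values())


def write_bedgraph(path: str | Path, ref_name: str,
                   values: Iterable[tuple[int, int, float]],
                   track_name: str = "track") -> None:
    """Write ``(start, end, value)`` intervals (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track_name}"\n')
        for start, end, value in values:
            fh.write(f"{ref_name}\t{start}\t{end}\t{value:g}\n")


def write_tsv(path: str | Path, rows: Iterable[dict],
              columns: Sequence[str], comment_lines: Sequence[str] = ()) -> None:
    with open(path, "w", newline="") as fh:
        for line in comment_lines:
            fh.write(f"# {line}\n")
        writer = csv.DictWriter(fh, fieldnames=list(columns), delimiter="\t")
        writer.writeheader()
        for row in rows:
            writer.writerow(row)


def write_vcf(path: str | Path, ref_name: str, ref_len: int,
              samples: Sequence[str], records: Iterable[dict]) -> None:
    """Minimal VCF v4.2 writer for mutation candidates.

    Each record dict carries ``pos`` (0-based), ``ref``, ``alt``,
    ``impact`` and per-sample ``ad`` / ``dp`` lists aligned with
    ``samples``.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={ref_name},length={ref_len}>\n")
        fh.write('##INFO=<ID=IMPACT,Number=1,Type=String,'
                 'Description="Predicted functional impact">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths (ref,alt)">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,'
                 'Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for rec in records:
            cells = [
                ref_name,
                str(rec["pos"] + 1),
                ".",
                rec["ref"],
                rec["alt"],
                ".",
                "PASS",
                f"IMPACT={rec['impact']}",
                "AD:DP",
            ]
            for ad, dp in zip(rec["ad"], rec["dp"]):
                cells.append(f"{ad[0]},{ad[1]}:{dp}")
            fh.write("\t".join(cells) + "\n")
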