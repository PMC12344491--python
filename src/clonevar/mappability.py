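"""Per-position mappability of a locus.

A length-``read_len`` window of the genome is *unique* when no other
genome location — on either strand — matches it within ``max_mismatches``
substitutions.  The score of a position is the fraction of windows
overlapping it that are unique, so a score of 1 across a locus rules out
alignment-uniqueness artifacts in read-based evidence there.

The search uses pigeonhole k-mer seeding (a window matching within *m*
mismatches must share at least one of *m*+1 exact seed parts) with full
Hamming verification; a quadratic all-vs-all scan serves as the test
oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simdata import GenomeModel, revcomp


@dataclass
class MappabilityTrack:
    """Scores in [0, 1] covering ``locus`` exactly."""

    locus: tuple[int, int]
    read_len: int
    max_mismatches: int
    scores: np.ndarray

    @property
    def min_score(self) -> float:
        return float(self.scores.min())

    @property
    def mean_score(self) -> float:
        return float(self.scores.mean())

    def bedgraph_intervals(self):
        """(start, end, score) runs of equal score, 0-based half-open."""
        start, _ = self.locus
        i = 0
        n = len(self.scores)
        while i < n:
            j = i
            while j + 1 < n and self.scores[j + 1] == self.scores[i]:
                j += 1
            yield start + i, start + j + 1, float(self.scores[i])
            i = j + 1


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _part_bounds(read_len: int, n_parts: int) -> list[tuple[int, int]]:
    size, rem = divmod(read_len, n_parts)
    bounds = []
    pos = 0
    for i in range(n_parts):
        ln = size + (1 if i < rem else 0)
        bounds.append((pos, pos + ln))
        pos += ln
    return bounds


def _window_unique_flags(
    seq: str, win_starts: np.ndarray, read_len: int, max_mismatches: int
) -> np.ndarray:
    """For each window start, is the window unique in the genome?

    Considers forward matches at other positions and reverse-complement
    matches at any position.
    """
    n = len(seq)
    fwd = _encode(seq)
    rc = _encode(revcomp(seq))
    bounds = _part_bounds(read_len, max_mismatches + 1)

    # substring indexes of both strands, one per distinct part length
    lengths = sorted({e - s for s, e in bounds})
    index: dict[tuple[str, int], dict[str, list[int]]] = {}
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for ln in lengths:
            d: dict[str, list[int]] = {}
            for q in range(n - ln + 1):
                d.setdefault(s[q: q + ln], []).append(q)
            index[(strand, ln)] = d

    flags = np.ones(len(win_starts), dtype=bool)
    max_start = n - read_len
    for wi, p in enumerate(win_starts):
        p = int(p)
        window = seq[p: p + read_len]
        wenc = fwd[p: p + read_len]
        unique = True
        for strand, arr in (("+", fwd), ("-", rc)):
            cand: set[int] = set()
            for (ps, pe) in bounds:
                part = window[ps:pe]
                for q in index[(strand, pe - ps)].get(part, ()):
                    start = q - ps
                    if 0 <= start <= max_start:
                        cand.add(start)
            for start in cand:
                if strand == "+" and start == p:
                    continue  # the window itself
                if np.count_nonzero(arr[start: start + read_len] != wenc) \
                        <= max_mismatches:
                    unique = False
                    break
            if not unique:
                break
        flags[wi] = unique
    return flags


def mappability_track(
    genome: GenomeModel,
    locus: tuple[int, int],
    read_len: int = 50,
    max_mismatches: int = 0,
) -> MappabilityTrack:
    """Mappability scores over ``locus`` at one mismatch allowance.

    ``score(pos)`` is the fraction of length-``read_len`` windows
    overlapping ``pos`` (those that exist within the genome) that are
    unique.  Increasing ``max_mismatches`` can only lower scores.
    """
    n = len(genome)
    start, end = locus
    if read_len > n:
        raise ValueError("read_len exceeds genome length")
    if not (0 <= start < end <= n):
        raise ValueError("locus outside genome")
    if read_len > end - start:
        raise ValueError("read_len exceeds locus length")

    win_lo = max(0, start - read_len + 1)
    win_hi = min(n - read_len, end - 1)  # inclusive last window start
    win_starts = np.arange(win_lo, win_hi + 1)
    flags = _window_unique_flags(genome.sequence, win_starts, read_len,
                                 max_mismatches)

    # prefix sums -> fraction of unique windows overlapping each position
    cum = np.concatenate([[0], np.cumsum(flags)])
    scores = np.empty(end - start, dtype=float)
    for i, pos in enumerate(range(start, end)):
        lo = max(win_lo, pos - read_len + 1)
        hi = min(win_hi, pos)  # inclusive
        a, b = lo - win_lo, hi - win_lo + 1
        scores[i] = (cum[b] - cum[a]) / (b - a)
    return MappabilityTrack((start, end), read_len, max_mismatches, scores)


def brute_force_track(
    genome: GenomeModel,
    locus: tuple[int, int],
    read_len: int = 50,
    max_mismatches: int = 0,
) -> MappabilityTrack:
    """Quadratic all-vs-all reference implementation (test oracle)."""
    n = len(genome)
    start, end = locus
    if read_len > n:
        raise ValueError("read_len exceeds genome length")
    fwd = _encode(genome.sequence)
    rc = _encode(revcomp(genome.sequence))
    all_wins = np.lib.stride_tricks.sliding_window_view(fwd, read_len)
    rc_wins = np.lib.stride_tricks.sliding_window_view(rc, read_len)

    win_lo = max(0, start - read_len + 1)
    win_hi = min(n - read_len, end - 1)
    win_starts = np.arange(win_lo, win_hi + 1)
    flags = np.ones(len(win_starts), dtype=bool)
    for wi, p in enumerate(win_starts):
        w = fwd[p: p + read_len]
        mm = np.count_nonzero(all_wins != w, axis=1)
        mm[p] = read_len  # exclude the window itself
        if mm.min() <= max_mismatches:
            flags[wi] = False
            continue
        mm_rc = np.count_nonzero(rc_wins != w, axis=1)
        if mm_rc.min() <= max_mismatches:
            flags[wi] = False

    cum = np.concatenate([[0], np.cumsum(flags)])
    scores = np.empty(end - start, dtype=float)
    for i, pos in enumerate(range(start, end)):
        lo = max(win_lo, pos - read_len + 1)
        hi = min(win_hi, pos)
        a, b = lo - win_lo, hi - win_lo + 1
        scores[i] = (cum[b] - cum[a]) / (b - a)
    return MappabilityTrack((start, end), read_len, max_mismatches, scores)
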