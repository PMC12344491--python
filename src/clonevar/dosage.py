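"""Tetraploid SNP allele dosage and binned coverage-dosage profiles.

Clonal identity between a progenitor and a putative clone is confirmed by
comparing maximum-likelihood allele dosages (0–4 alternate copies) at
shared heterozygous sites; large-scale chromosomal variants are screened
with binned, control-normalised coverage ratios scaled to ploidy units.

The dosage model is a binomial: at true dosage *d* of ploidy *p*, an
alternate read is observed with probability clamp(d/p, e, 1−e) where *e*
is a small error rate absorbing sequencing error and mapping bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .alnio import AlignedRead


@dataclass
class SnpDosageCall:
    """Maximum-likelihood dosage at one biallelic site."""

    site: int
    ref_count: int
    alt_count: int
    dosage: int
    log_likelihoods: np.ndarray  # indexed by candidate dosage 0..ploidy

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def log_lr(self) -> float:
        """Log-likelihood margin of the best dosage over the runner-up."""
        ll = np.sort(self.log_likelihoods)
        return float(ll[-1] - ll[-2])


def estimate_snp_dosage(
    ref_count: int,
    alt_count: int,
    ploidy: int = 4,
    error_rate: float = 0.01,
    site: int = -1,
) -> SnpDosageCall | None:
    """ML alternate-allele dosage under the clamped binomial model.

    Returns ``None`` (no-call) at zero depth.  Ties in likelihood resolve
    to the smallest dosage (argmax convention); they occur only in
    degenerate cases such as error_rate = 0.5.
    """
    if ref_count < 0 or alt_count < 0:
        raise ValueError("counts must be nonnegative")
    depth = ref_count + alt_count
    if depth == 0:
        return None
    d = np.arange(ploidy + 1)
    p = np.clip(d / ploidy, error_rate, 1 - error_rate)
    ll = stats.binom.logpmf(alt_count, depth, p)
    return SnpDosageCall(site, ref_count, alt_count, int(np.argmax(ll)), ll)


@dataclass
class ClonalityReport:
    """Dosage concordance between two samples at shared sites."""

    n_shared: int
    n_concordant: int
    discordant_sites: list[int]
    threshold: float = 0.95

    @property
    def concordance(self) -> float:
        return self.n_concordant / self.n_shared

    @property
    def is_clone(self) -> bool:
        return self.concordance >= self.threshold


MIN_LOG_LR = float(np.log(10.0))


def clonality_check(
    calls_a: dict[int, SnpDosageCall],
    calls_b: dict[int, SnpDosageCall],
    min_depth: int = 10,
    threshold: float = 0.95,
    min_log_lr: float = MIN_LOG_LR,
) -> ClonalityReport:
    """Fraction of co-called sites with equal ML dosage.

    A site is co-called when both samples reach ``min_depth`` and both
    calls are confident (best-vs-runner-up likelihood ratio of at least
    e^``min_log_lr``, 10:1 by default).  Without the confidence gate,
    sites whose read counts sit near a dosage decision boundary flip
    between neighbouring dosages from sampling noise alone, depressing
    concordance between true clones at moderate depth.  Raises if no
    shared site survives.
    """
    shared = [
        s for s in calls_a.keys() & calls_b.keys()
        if calls_a[s].depth >= min_depth and calls_b[s].depth >= min_depth
        and calls_a[s].log_lr >= min_log_lr
        and calls_b[s].log_lr >= min_log_lr
    ]
    if not shared:
        raise ValueError("no shared sites at the required depth")
    discordant = sorted(
        s for s in shared if calls_a[s].dosage != calls_b[s].dosage
    )
    return ClonalityReport(len(shared), len(shared) - len(discordant),
                           discordant, threshold)


@dataclass
class DosageProfile:
    """Binned copy-number ratio of a sample against a control.

    ``ratio`` is (sample bin coverage / sample mean) ÷ (control bin
    coverage / control mean) × ploidy, i.e. ~ploidy where the sample
    matches the control.  Bins with zero control coverage are masked
    (NaN), never divided.
    """

    bins: list[tuple[int, int]]
    sample_cov: np.ndarray
    control_cov: np.ndarray
    ratio: np.ndarray
    flagged: np.ndarray  # bool per bin
    ploidy: int = 4
    deviation_threshold: float = 0.5
    min_run: int = 3

    def bedgraph_intervals(self):
        """(start, end, ratio) per unmasked bin, for bedGraph output."""
        for (s, e), r in zip(self.bins, self.ratio):
            if not np.isnan(r):
                yield s, e, float(r)


def _binned_depth(reads: Iterable[AlignedRead], region: tuple[int, int],
                  bin_size: int) -> tuple[list[tuple[int, int]], np.ndarray]:
    start, end = region
    depth = np.zeros(end - start, dtype=np.int64)
    for read in reads:
        if read.is_unmapped:
            continue
        r = read.start
        for op, n in read.cigar:
            if op in "M=X":
                lo, hi = max(r, start), min(r + n, end)
                if lo < hi:
                    depth[lo - start: hi - start] += 1
                r += n
            elif op in "DN":
                r += n
    edges = list(range(start, end, bin_size))
    bins = [(s, min(s + bin_size, end)) for s in edges]
    cov = np.array([depth[s - start: e - start].mean() for s, e in bins])
    return bins, cov


def dosage_profile(
    sample_reads: Iterable[AlignedRead],
    control_reads: Iterable[AlignedRead],
    region: tuple[int, int],
    bin_size: int = 10_000,
    ploidy: int = 4,
    deviation_threshold: float = 0.5,
    min_run: int = 3,
) -> DosageProfile:
    """Control-normalised binned coverage ratio in ploidy units.

    Bins whose |ratio − ploidy| exceeds ``deviation_threshold`` over at
    least ``min_run`` consecutive bins are flagged as candidate
    chromosomal variants.  The ratio is scale-invariant in both samples'
    total coverage.
    """
    bins, s_cov = _binned_depth(sample_reads, region, bin_size)
    _, c_cov = _binned_depth(control_reads, region, bin_size)
    if s_cov.sum() == 0 or c_cov.sum() == 0:
        raise ValueError("a sample has no coverage in the region")
    ratio = np.full(len(bins), np.nan)
    ok = c_cov > 0
    ratio[ok] = (s_cov[ok] / s_cov[ok].mean()) / \
        (c_cov[ok] / c_cov[ok].mean()) * ploidy

    deviant = np.zeros(len(bins), dtype=bool)
    deviant[ok] = np.abs(ratio[ok] - ploidy) > deviation_threshold
    flagged = np.zeros(len(bins), dtype=bool)
    run = 0
    for i, dv in enumerate(deviant):
        run = run + 1 if dv else 0
        if run >= min_run:
            flagged[i - run + 1: i + 1] = True
    return DosageProfile(bins, s_cov, c_cov, ratio, flagged, ploidy,
                         deviation_threshold, min_run)


def dosage_calls_from_pileups(
    columns, ref_seq: str, ploidy: int = 4, error_rate: float = 0.01,
    min_alt_frac: float = 0.1, min_depth: int = 10,
) -> dict[int, SnpDosageCall]:
    """Call dosage at apparently heterozygous pileup sites.

    A convenience for clonality checks: sites where the strongest
    non-reference base reaches ``min_alt_frac`` of depth are dosage-typed
    against the reference base.
    """
    calls: dict[int, SnpDosageCall] = {}
    for col in columns:
        ref = ref_seq[col.pos].upper()
        if ref not in "ACGT":
            continue
        alts = {b: c for b, c in col.counts.items()
                if b in "ACGT" and b != ref and c > 0}
        if not alts:
            continue
        alt, alt_count = max(alts.items(), key=lambda kv: kv[1])
        depth = col.counts[ref] + alt_count
        if depth < min_depth or alt_count < min_alt_frac * depth:
            continue
        call = estimate_snp_dosage(col.counts[ref], alt_count, ploidy,
                                   error_rate, site=col.pos)
        if call is not None:
            calls[col.pos] = call
    return calls
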