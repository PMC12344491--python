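# Methods

`clonevar` analyses clonal variants of an autotetraploid crop at a
structural locus where a cut-and-paste DNA transposon (TE) either sits
intact, or has excised leaving a small footprint ("scar") on one
chromosome copy.  The situation it models is a set of clonally selected
potato strains that differ from their progenitor cultivar by a somatic
TE excision in the maturity gene *CDF1*: the progenitor is
*CDF1.1/CDF1.1/CDF1.3/CDF1.3* (two intact-like copies, two TE-carrying
copies) and the improved strains carry a new excision allele *CDF1.2*
with a 7-bp scar, present only in a subset of the shoot's meristem cell
layers.  All computations here run on synthetic data produced by the
package's own simulator; nothing in the test suite or the acceptance
script touches external data.

## Structural allele model

A TE insertion duplicates the `tsd_len` bases at the target site
(target-site duplication, TSD), giving the haplotype structure
`prefix · TSD · element · TSD · suffix`.  Excision removes the element
and leaves a footprint derived from the TSD; by default the footprint is
the first `scar_len` bases of the TSD, so the excision haplotype differs
from the never-inserted one by exactly a `scar_len`-bp insertion.
Defaults: `tsd_len = 8` (typical for hAT-family elements),
`scar_len = 7`, element length 800 bp.  Whether a real hAT footprint is
exactly a TSD prefix or includes novel bases varies by event; the
footprint sequence is configurable (`TEInsertionSpec.footprint`) and is
never asserted to be TSD-derived by the classifiers — they match the
declared scar sequence with one edit of tolerance.

Coordinate maps accompany every derived haplotype: `ref_of[i]` is the
source coordinate of base `i`, or −1 for bases with no reference
correspondence (element interior, scar footprint, inserted alleles).
The second TSD copy maps back to the original target-site bases, which
is where an aligner would place it; composing the insertion map with the
excision map reproduces the map of a direct scar insertion (tested
base-by-base).

## Read simulation

DNA libraries are paired-end, 2×150 bp, 400±60 bp fragments, 40-fold
coverage by default (within the 30–50× range typical of the study
design), substitution errors at 10⁻³ per base and no indel errors — the
substitution-only model keeps truth edit descriptions unambiguous.
Fragments sample (i) a meristem layer (L1/L2/L3) by the chimera's cell
fractions, (ii) one of the four haplotype copies, (iii) a fragment
position.  Copy sampling is weighted by each copy's number of valid
fragment placements (length − mean fragment + 1): uniform shearing of
equal amounts of each chromosome produces uniform per-offset read-start
density across copies, which is the property the frequency estimators
rely on; sampling copies uniformly would under-cover the longer
TE haplotype by ~8% per base pair.

Truth output is a coordinate-projected SAM: reads crossing a TE junction
carry soft clips, scar-spanning reads carry the 7-bp insertion, reads
wholly inside the element are recorded unmapped (their mapped mates thus
carry the mate-unmapped flag — the "mate in element" signature), and
spliced RNA reads carry `N` skips.  A TSV truth table labels each read
with its source haplotype, layer and allele class.

RNA libraries sample transcript molecules proportional to per-copy
expression weights and fragment them uniformly per base, so read counts
scale with weight × transcript length while junction-window read density
scales with the weight alone.  The ~3/4 intact-class contribution
scenario is therefore recovered from *informative* (junction-window)
reads, which is also what an analyst counts when assigning RNA reads to
alleles.

## Periclinal chimera model

Leaf tissue mixes three meristem-derived lineages: L1 (epidermis), L2
(mesophyll/parenchyma), L3 (vasculature).  Default leaf cell fractions
are (f_L1, f_L2, f_L3) = (0.24, 0.56, 0.20).  These were chosen once so
that a simplex somatic allele confined to L1 has expected VAF
0.24/4 = 0.06 and one in L2+L3 has (0.56+0.20)/4 = 0.19, matching the
empirical leaf VAFs (~0.06 and ~0.2) reported for layer-restricted
potato mutations; both cannot be matched exactly simultaneously since
0.24 + 0.80 > 1.  Layer inference compares binomial log-likelihoods of
the observed k-of-n at each candidate pattern's expected VAF.  The
default candidate set is {L1}, {L2,L3}, {L1,L2,L3}: single L2 or L3
patterns are excluded because layer invasion tends to homogenise L2 and
L3 (configurable).  A likelihood ratio of 10:1 over the runner-up marks
a confident call.  At the study's sequencing depth a single locus yields
only ~40 informative reads, where the 0.19-vs-0.25 decision is
unreliable; the acceptance checks therefore pool independent libraries
to ≥2,000 informative reads, at which point patterns separate cleanly.
At n = 500 the exact ML decision boundary still leaves ~5% confusion
between expected VAFs 0.19 and 0.25 (the tests assert the exact
binomial decision-boundary rate rather than a round number).

## Read classification and VAF

Reads are assigned to allele classes by signature: SCAR (anchored span
plus an insertion within edit distance 1 of the scar), TE_JUNCTION
(soft clip ≥ 12 bp at a junction matching a TE terminal at ≥90%
identity, or an unmapped mate), INTACT (anchored span, no clip or scar
at the junctions), else AMBIGUOUS.  Spanning calls require ≥ 5 aligned
bases on each side of the *whole TSD block*, not just the insertion
point — otherwise TE reads aligned only across the duplicated target
site leak into the INTACT class.  Breakpoint positions tolerate ±2 bp.

Raw class counts are not comparable: a TE copy presents two junctions
(and mate evidence), while a scar read spends 7 query bases on the
insertion, so each class is observable from a different number of read
start offsets.  `estimate_locus_vaf` divides each class count by its
ascertainment width — intact: L − tsd − 2·anchor + 1; scar:
L − tsd − scar − 2·anchor + 1; TE: 2·(L − clip − anchor + 1) — and
reports the target's share of the summed per-copy rates, rescaled to an
effective k/n with a Wilson 95% interval.  Mate-only TE evidence is
excluded from frequency estimation because its window scales with
fragment length, not read length.  The uncorrected k/n estimator
(`estimate_vaf`) is kept for arbitrary call sets.  AMBIGUOUS reads are
never in the denominator; counting them as reference support would bias
VAF downward.

## Element reconstruction

The longest soft-clipped segments of junction reads are consensus-called
per side (majority vote per column, anchored at the junction-proximal
end, ties broken toward the longest clip) and located elsewhere in the
genome by 15-mer seeding with ungapped extension at ≥90% identity, on
both strands.  5′ and 3′ hits on the same strand in consistent order
within 20 kb are paired; the element length is the span from the 5′ hit
start to the 3′ hit end.  This is an exact-seeded search rather than a
BLAST call — at desk scale the flanks are near-error-free consensus
sequences and gapped alignment adds nothing.

## Dosage and clonality

Allele dosage d ∈ {0..4} at a biallelic site is the ML argmax under a
binomial with success probability clamp(d/4, e, 1−e), e = 0.01 (the
published analyses rely on prior in-house tooling; this model is
declared, not inferred).  Clone identity is the fraction of co-called
sites with equal dosage.  "Co-called" requires both samples to reach
minimum depth (10) and a confident call — best-vs-runner-up likelihood
ratio ≥ 10:1.  The confidence gate matters: at 40× a duplex site is
miscalled ~8% of the time because counts near the d=1/d=2 boundary flip
by sampling noise, capping naive all-site concordance near 0.85 even
for true clones; gating restores ≥0.95 concordance at the cost of
calling ~70% of sites.  The clone threshold (0.95) is a declared
convention.  Coverage dosage profiles are per-bin sample/control depth
ratios scaled to ploidy units (bin default 10 kb at desk scale), with
zero-coverage control bins masked and deviations |ratio − 4| > 0.5
sustained over ≥3 bins flagged.

## Mutation scan and impact

The somatic scan is a deterministic threshold filter, mirroring the
study's relaxed search: case alt reads ≥ 3, control alt reads = 0, both
depths ≥ 10, evaluated per allele (indels keyed by exact allele string).
No statistical test or FDR control is applied — the design accepts a
high false discovery rate in exchange for sensitivity to low-VAF
chimeric alleles, and intersection across independent clones is the
intended secondary filter.  Impact classes follow the common
variant-effect convention: HIGH = stop gain, stop loss, start loss,
frameshift indel, splice-dinucleotide change; MODERATE = missense or
in-frame indel; LOW = synonymous; NONCODING otherwise.  (Stop loss is
included in HIGH by that convention even though it is absent from some
shorter taxonomies.)

## Mappability

A window of `read_len` bases is unique if no other genome location — on
either strand — matches it within `max_mismatches` substitutions; a
position's score is the fraction of its overlapping windows that are
unique.  Defaults: read length 50, mismatch allowances {0, 1, 2}.  The
production path uses pigeonhole seeding (a match with ≤ m mismatches
shares one of m+1 exact parts) with full Hamming verification; a
quadratic all-vs-all scan is retained in the module as the test oracle
and the two are asserted equal on small genomes with planted exact,
inexact and reverse-complement duplications.

## Problem sizes

The synthetic locus is 10 kb with two genes (the TE inserted mid-CDS in
the second exon of gene 1, so the scar is a frameshift; the intact
copies carry an in-frame 3-bp CDS deletion; 40 intergenic duplex SNPs
support dosage work).  Element reconstruction and mappability scenarios
use 100 kb genomes.  VAF checks pool independent 40× libraries to
≥2,000 informative reads (~55 replicates); the mappability oracle
comparison runs on ≤8 kb genomes.

## Known limitations

The error model is substitution-only with uniform base quality; no PCR
duplicates, GC bias, indel errors or alignment ambiguity, so passing
tests demonstrate correctness of the estimators under the generative
model, not robustness to real-aligner artifacts (soft-clip placement
slop and the ±2 bp breakpoint tolerance are the only concessions to
aligner noise).  Truth alignments stand in for an aligner throughout.
Layer fractions are model inputs, not estimated from data.  The dosage
module does not segment genome-wide CNVs, and the element search does
not do gapped alignment or genome-wide TE discovery.
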