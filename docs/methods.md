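# Methods

## Coordinate and signal model

All coordinates are 0-based half-open (BED convention) throughout;
annotation input is documented as such. Strand affects only TSS/TTS
orientation and profile flipping, never interval algebra. Coverage lives
in fixed-width bins (default 50 bp — fine enough to resolve kb-scale
regions at desk-scale memory); every base within a bin carries the bin's
value, and all range sums/means integrate that step function exactly, so
binned arithmetic agrees with a per-base computation to rounding error.
bedGraph input is rebinned by length-weighted averaging with uncovered
bases counted as zero; overlapping bedGraph records are rejected as
ambiguous.

## Peak calling

The caller is deliberately simple and fully specified: per-bin Poisson
upper-tail p-values against λ = max(genome-wide mean, centred 10-kb local
mean), Benjamini–Hochberg control at FDR 0.05 across all bins, merging of
significant bins separated by ≤ 100 bp, a 200 bp minimum length, summit
at the highest bin. Including the peak itself in the local window makes
the local λ conservative for broad enrichments; at the enrichment levels
this assay produces (several-fold over background) that costs little
sensitivity and keeps the null calibration clean (on pure-noise tracks
the called fraction of the genome stays below the FDR; verified by
Monte-Carlo in the tests). There is no input/control subtraction and no
broad-peak mode.

## M-A normalization and the degradation test

Two samples are normalized on their common peaks, under the assumption
that peaks present in both samples are on average unchanged. With
densities (reads/kb) x₁, x₂ and pseudocount c = 1:
M = log2((x₂+c)/(x₁+c)), A = ½·log2((x₁+c)(x₂+c)); an ordinary
least-squares fit of M on A over max-overlap-paired common peaks gives a
line that is removed from every pair, which rescales sample 2 onto
sample 1's scale. The orientation (M measures sample 2 over sample 1)
makes a doubled sample-2 depth fit intercept +1. Because each pair is
corrected at its own A, re-fitting after rescaling returns slope and
intercept of exactly zero on noiseless input — the rescaling is
idempotent.

Per-peak significance of a 0 h → 4 h drop uses the Audic–Claverie
equal-library model on rounded normalized counts
(count = density × length/1000): given the 0-h count x, the 4-h count is
NegBin(n = x+1, p = ½), and the one-sided p-value is P(Y ≤ x₄). With this
convention swapping the samples maps p to exactly 1 − p. The Bayesian
machinery of the original MAnorm significance model is intentionally not
reproduced; the closed-form test plays the same decision role and is
verifiable against direct summation.

A region is called degraded when its 0-h peak has no overlapping
(≥ 1 bp, configurable) 4-h peak at all, or when a common peak has
normalized M ≥ 1 and p < 0.01. Overlapping calls merge; a merge involving
any differential call is labelled `differential_common`, and merged-region
statistics keep the strongest evidence (max M, min p). Loosening α or the
M threshold can only grow the called set. PA200-dependent regions are the
wild-type degraded regions overlapping no knockout degraded region; the
symmetric knockout-minus-wild-type set is emitted by the pipeline as a
clearly secondary output.

## Methylation

Hyper/hypo classification is strict at 0.5: a region is hyper iff its
unweighted mean CpG level is > 0.5, hypo otherwise, and `no_data` with
fewer than 3 CpGs (guarding against single-CpG regions). Headline
percentages use classified regions only (hyper + hypo) in the
denominator and round half away from zero. Genome "areas" are defined
here as fixed 10-kb windows classified by the same rule and merged when
adjacent windows share a label, with no-data windows breaking merges;
the construction is exposed via the window size because no canonical
area definition exists for this quantity — only the ratio arithmetic is
treated as reproducible.

The DMR caller is likewise this package's own: fixed windows (1 kb), a
minimum mean difference of 0.2, a per-window test (coverage-weighted
two-proportion z when per-CpG coverage is available on both sides, else
Welch's t on site levels; zero-variance windows with a real shift count
as significant), Benjamini–Hochberg at 0.05 across tested windows, and
merging of adjacent same-direction windows. It is not a smoothing-based
caller and does not separate CHG/CHH contexts.

## Expression

The DEG rule combines a pseudocounted depth-normalized log2-ratio with a
"diverge probability" defined through the Audic–Claverie posterior
predictive: given count x in library A and sizes N_A, N_B, the library-B
count is NegBin(n = x+1, p = N_A/(N_A+N_B)), and the diverge probability
is 1 − 2·min(lower tail, upper tail) at the observed count — a
two-sided-tail score in [0, 1]. The provider-pipeline statistic this
stands in for is not publicly specified; this definition is the
package's own, chosen because it is closed-form, zero-safe (no
pseudocount in the probability), exactly symmetric under sample swap for
equal libraries, and oracle-verifiable by direct summation. Both
thresholds (ratio ≥ 1, probability ≥ 0.8) are inclusive and exposed. No
multiple-testing correction is applied — the rule is a plain threshold —
and no replicate-based dispersion estimation is attempted.

## Profiles

Metagene matrices use 100 equal body segments with integer boundaries
(round(i·L/100)); genes shorter than the segment count are skipped and
counted. Flank bins are fixed-width (300 bp for 21-kb flanks; 50 bp for
1.5–2.5-kb windows). Minus-strand rows are column-reversed so column 0
is always biologically upstream. Cells that reach outside the chromosome
are NaN and excluded from column means. Tracks are depth-normalized to
reads-per-million before profiling where profiles from different
libraries are compared; the profiling functions themselves are linear in
the track, so scaling commutes exactly. Ratio profiles are computed on
column summaries, optionally normalizing each side to a reference (H3)
first. Overlapping genes are profiled independently, with no masking.

## Synthetic data

The generator emulates the study's signal structure so that planted
truth is recoverable by the pipeline, with all counts Poisson (tracks)
or negative binomial (gene counts) and every track drawing from its own
seeded integer RNG stream (full determinism under a fixed seed).

Reference conditions: 2 chromosomes × 10 Mb, 200 non-overlapping genes
(5–30 kb), 60 planted degraded regions (1.5–3 kb, bin-aligned, kept
2 kb clear of TSSs) of which 40 are PA200-dependent. Background 5
reads/bin; planted regions 8-fold enriched at 0 h in both genotypes. At
4 h a region retains a configured fraction of its 0-h mean: 0.2 in the
wild type (and at the 20 shared regions in the knockout), 0.85 at the 40
PA200-dependent regions in the knockout. The knockout is globally scaled
by 0.7, reflecting its lower labeled-histone enrichment. All four tracks
carry a triangular TSS enrichment (6-fold apex, ±1 kb) — labeled
histones concentrate at start sites — and the knockout 4-h track
multiplies TSS windows by an accumulation factor of 1.5. That factor's
magnitude is not an empirically known quantity; it is a free simulation
parameter, and the corresponding check only asks that the pipeline
recover whatever value was planted.

Mark tracks: H3 is uniformly enriched over gene bodies and identical
between genotypes; H3K4me3 is TSS-shaped, H3K56ac and Pol II body-wide;
the knockout's per-gene enrichment is multiplied by 2^±1 for planted
up/down genes, coupling mark changes and Pol II to the expression
classes. The methylome places CpGs every 100 bp (real CpG-density
variation is out of scope) with Beta-distributed levels (concentration
20) of mean 0.8 in hyper domains and 0.15 elsewhere; 8% of the
PA200-dependent regions (rounded) are covered by a hyper domain, the
rest stay hypo. A separate generator lays out separated hyper/hypo
domains with CpG-free gaps for validating the area segmentation (each
planted domain maps to exactly one area). Counts are negative binomial
with dispersion 0.02 — the near-technical dispersion appropriate to a
single-library digital comparison; with biological-replicate dispersion
the Poisson-based divergence score would be anti-conservative by
construction. Planted fold changes are 2^±2 on 30 + 30 genes, and the
emitted library sizes are the true simulated depths rather than column
sums, so planted fold changes do not leak into the normalization as
composition bias. One replicate per condition, matching the assay's
n = 1 design.

What the generator does *not* emulate: read-level artifacts (GC bias,
mappability, fragment-length effects), overlapping genes, CpG islands,
replicate structure, and genuinely diffuse or nested enrichment. Passing
the planted-truth checks therefore demonstrates the pipeline's logic and
calibration, not its performance on real libraries.

## Numerical choices and degenerate inputs

Pseudocounts: 1.0 in M/A and in expression log-ratios (never in the
diverge probability); 0.1 in per-gene mark-ratio summaries. The DMR
mean-difference threshold is applied with a 1e-9 tolerance so an exact
threshold shift is called. All-zero tracks yield empty peak lists, an
empty 0-h peak list yields an empty degraded set, and fewer than 10
common peaks refuse a normalization fit rather than returning an
unstable one. Percentages are rounded half away from zero via decimal
arithmetic. Classification counts are invariant to record and region
order; merging is performed on coordinate-sorted calls with stable
tie-breaking.

## Problem sizes

The default study (2 × 10 Mb, 400 k bins per track) runs the full
pipeline in well under a minute on one core. Null-calibration batches
use 20 seeds of a 1 × 2 Mb genome — large enough for a few hundred peaks
per sample, small enough to repeat twenty times — and the area-recovery
check uses a ~36 Mb single-chromosome methylome holding all 807 planted
domains.

## Known limitations

The unique-at-0h rule inherits the peak caller's false positives: a
noise peak at 0 h with no 4-h partner becomes a (short) degraded region,
which is the dominant source of spurious PA200-dependent calls (a few
percent under reference conditions). The area construction and the DMR
caller are this package's own definitions and will not numerically match
other tools' area or DMR counts on real data. The MAnorm-style fit
assumes common peaks are mostly unchanged; in the knockout, retained
planted regions violate this mildly, which biases the fitted line but
not the unique-peak route that drives the headline calls. The diverge
probability is a stand-in definition; published DEG counts from pipelines
using the original provider statistic are not expected to be reproduced
exactly.
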