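# Methods

## Scope and data model

`pioneerscan` operates downstream of alignment and peak calling.  Its
inputs are interval files (BED3–6, ENCODE narrowPeak), bedGraph signal
tracks, JASPAR-style position weight matrices, and a chromatin-state
segmentation BED; read alignment, duplicate removal, peak calling, de
novo motif discovery and segmentation training are deliberately out of
scope.  All coordinates are 0-based half-open.  Signal is held as a
`SignalTrack`: one dense float vector per chromosome at a fixed bin size
plus a boolean coverage mask.  A bin's value is the mean per-base signal
over the bin with unobserved bases counted as zero; the mask records
whether any base of the bin was observed.  bedGraph records are
rasterized onto this grid with coverage-weighted means, and input
subtraction (IP − input) retains negative values, because the sampling
analysis depends on near-zero signed differences and the upstream
coverage arithmetic does not clip.

## Signal extraction

`average_over_interval` returns the overlap-weighted mean of bin values
over an interval (uncovered bases contribute zero to the numerator but
stay in the denominator) together with the covered fraction.
`central_window_mean` applies the same statistic to a fixed-width window
centered on `floor((start + end)/2)`; windows are clipped at chromosome
edges with the denominator reduced, which keeps edge means unbiased.  The
default window width of 100 bases matches the central-window convention
used throughout (motif signal, turnover at peaks).  Reference-point
matrices treat out-of-genome bases as zero signal (or NaN on request) and
can drop all-zero rows.  Peak-width standardization recenters every peak
on its midpoint and fixes the width at the peak set's mean width, rounded
half-up to whole bases.

## Accessibility classification

A peak is *accessible* when its mean DNase-seq RPM over the full peak
exceeds the cutoff (default 0.05 RPM) and otherwise *resistant*.  An
exact tie is called resistant: the underlying predicates (`> t` for
accessible, `< t` for resistant) leave ties unassigned, a total
classifier must place them somewhere, and resistant is the conservative
side when the downstream claim is pioneer activity.  The cutoff is
exposed as a parameter; its empirical calibration on real fibroblast data
is not reproduced here.  Turnover has no published absolute cutoff, so
the high/low split defaults to the median central-window H2B mean over
the peak set, overridable with an absolute value.

Binned motif enrichment sorts peaks by DNase value into `n_bins`
equal-size bins (floor(n/k) peaks per bin; the remainder joins the final,
most accessible bin — a deterministic, documented rule).  For each
(motif, bin) pair the foreground is the bin and the background all other
bins; hit frequency is the fraction of standardized peak sequences with
at least one PWM match at the matrix's own score threshold.  Enrichment
is `log2((f_fg + ε)/(f_bg + ε))` with `ε = 1/(2·bin size)` as a
continuity correction, significance is a one-sided binomial test of the
foreground hit count at the background frequency, and adjustment is
Benjamini–Hochberg across all (motif, bin) pairs.  A motif is reported
when `−log10(p_adj) > 2` and the foreground frequency exceeds 5%.
GC-matched backgrounds and randomized-lasso variable selection are not
implemented; bins serve as each other's background.

## Heterochromatin local-density subtypes

Domains are merged per mark (bookended intervals joined) before
intersection; a peak belongs to a mark when it overlaps a merged domain
by at least one base and may carry both marks.  Each assigned site gets a
center signal (1-kb window on the peak center) and a flank signal (mean
of two 2-kb windows at ±5 kb), and the ratio
`center / (flank + ε)` maps to *high* (≥ 1.5), *low* (≤ 0.67) or
*moderate* otherwise.  The window geometry and thresholds are this
package's operationalization of a grouping that is qualitative in the
source material (focally enriched vs. domain-level vs. local-gap
binding); they are defaults calibrated so that a three-way synthetic
fixture separates cleanly, and all are parameters.  The stabilizer
`ε` is 1% of the track's median nonzero value, so subtype calls are
invariant under uniform rescaling of the mark track.

## Motif sampling

The genome-wide motif set comes from a log-odds PWM scan (bits against
the PWM's background; both strands; windows containing N skipped;
same-locus opposite-strand duplicates resolved to the higher score with
ties to the + strand).  Each instance is scored by central-window mean
and covered fraction on the input-subtracted IP track.  Instances with
covered fraction ≤ 0.75 are set aside as *filtered* — the coverage rule
retains well-covered sites and discards low-coverage and unmappable
regions.  A motif overlapping a consensus peak is *bound* regardless of
its signal (peak intersection takes precedence).  For the rest, the null
comes from the motif list translated +10 kb: after the same coverage
filter, the background's central-signal distribution yields a threshold
at the 95th percentile, and motifs above it are *sampled*, the remainder
*unsampled*.  No numeric sampled/unsampled rule is published for the
assay this emulates; the background-quantile construction is this
package's operationalization of "specific low-level signal vs. none at
shifted controls", and the quantile is a parameter.  Shifted background
instances that land inside peaks are retained in the null (no exclusion
is applied).  Class fractions are reported over unfiltered motifs, and
condition-to-condition transition tables count only motifs unfiltered in
both conditions.

## Peak-set comparison

Consensus peaks are replicate-1 peaks overlapping (≥ 1 base, the
bedtools default) at least one peak in every other replicate.  Between
conditions, *shared* loci are detected in ≥ 1 replicate of each
condition (deduplicated keeping the baseline condition's coordinates),
and *unique* peaks are present in all replicates of one condition and no
replicate of the other.  Retained % = shared-with-B fraction of A's
consensus; gained % = B-unique count over A's consensus count.  Using
the baseline's consensus count as the single denominator is the only
convention under which gained percentages above 100% are possible, and it
is stated here because the convention is not otherwise fixed.

## Chromatin-state overlap enrichment

For segmentation state `s` and motif class `c`,
`fold(s, c) = (bases of c in s / total bases of c) / (bases of s / G)`.
Overlaps are half-open and counted in bases, not motif instances, making
the statistic insensitive to motif length.  The segmentation must tile
the genome; gaps are reported as errors with their spans.  Two identities
follow from the definition and are enforced by tests: a single-state
segmentation gives fold 1 everywhere, and for each class the
genome-fraction-weighted mean fold over states is exactly 1.

## Synthetic genome generator

The generator emulates the data model of an ectopic-factor ChIP
experiment in fibroblasts at toy scale — default 4 chromosomes × 2 Mb at
10-base bins, which runs the whole pipeline in seconds while leaving room
for 1,000 motifs and multi-kilobase domains.

*States and domains.*  Chromosomes are tiled with 100-kb blocks assigned
to open-naive / closed-naive / H3K9me3-domain / H3K27me3-domain states by
largest-remainder apportionment of the requested fractions followed by a
seeded shuffle; adjacent same-state blocks merge into broad domains.
DNase and H2B-turnover tracks are state-conditional Gaussians (open:
0.5 RPM DNase, 1.0 RPM turnover; elsewhere 0.01 and 0.05 RPM; 10%
coefficient of variation, floored at zero).  Mark tracks sit at 1.0 RPM
inside their own domains and 0.02 RPM outside.  Inside domains the
generator plants: spontaneous gaps (Poisson per domain, default rate 2,
width 2 kb, signal multiplied by 0.1) and three classes of
density sites for classifier validation — *high* (a Gaussian bump of
2× the domain level, sd 300 b), *flat* (untouched domain interior) and
*gap* (a carved depression).  Sites keep 8 kb mutual separation and 6 kb
domain-edge margins so that one site's feature cannot contaminate
another's flank windows.

*Motifs and IP signal.*  Motif instances (consensus planted into a
seeded i.i.d. background sequence, random strand) are placed uniformly
with 1.2-kb minimum separation and assigned bound/sampled/unsampled
labels by exact largest-remainder apportionment plus a seeded shuffle, so
truth-level fractions carry no sampling error.  The IP track is a sparse
background — Poisson-placed 300-b fragments (rate 4 × 10⁻⁵ per base)
with exponential pileup heights of mean `noise_sd` — plus Gaussian bumps
(sd 200 b, approximating the 300–500 bp ChIP fragment footprint) of
height 10 RPM at bound and 1 RPM at sampled motifs.  The zero-inflated
background is deliberate: an input-subtracted coverage track is exactly
zero over most unread bases, and a dense Gaussian background would make
the unsampled-motif signal distribution identical to the shifted
background, which no threshold can separate better than its own quantile.
Peaks (400 b, summit at the motif center) are emitted at bound motifs in
two pseudo-replicates with configurable dropout (default 0); the
consensus is their intersection.

*What the generator does not emulate.*  Realistic sequence composition,
mappability structure (coverage is complete by default; the coverage
filter is exercised with hand-built masks in tests), replicate-dependent
signal variation, fragment-length variability, and copy-number or GC
biases.  Passing recovery tests therefore demonstrates correctness of
the classification logic under the stated signal model, not robustness
to every artifact of real sequencing data.

## Numerical choices and degenerate inputs

Ties: accessibility ties go to resistant; strand ties in the scanner go
to +; subtype-majority ties break high > moderate > low; equal-size
binning puts remainders in the last bin.  Quantiles use numpy's default
linear interpolation.  Empty peak lists, empty backgrounds after
filtering, segmentation gaps, overlapping bedGraph records and
non-tiling segmentations raise errors rather than degrade silently.
Determinism: a fixed generator seed yields byte-identical fixture files
and output tables across runs; all randomness flows from
`numpy.random.default_rng(seed)`.

## Problem sizes

Tests and the acceptance script use the default 4 × 2 Mb genome for
sampling recovery (1,000 motifs), 2 × 1 Mb genomes (400 motifs) for
accessibility recovery, and a domain-rich 4 × 2 Mb genome (330 planted
density sites) for heterochromatin recovery — sizes chosen so the full
suite completes in well under a minute of compute per stage while keeping
per-class counts in the hundreds.
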