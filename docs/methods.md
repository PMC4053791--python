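# Methods

## DREAM methylation quantification

DREAM creates methylation-specific 5′ read signatures by sequential
digestion of the CCCGGG site: SmaI cuts only unmethylated sites and
leaves blunt ends, so unmethylated-allele reads start `GGG`; XmaI cuts
regardless of methylation and leaves a four-base 5′ overhang which,
after end fill-in, puts `CCGGG` at the start of methylated-allele reads.
`classify_read_signature` tests the XmaI prefix first (it is a
superstring of the SmaI prefix); reads shorter than the signature or
with an `N` in the signature region are UNCLASSIFIED and excluded from
counts — dropping them is unbiased, whereas forcing a call would not be.
A site is keyed by the coordinate of its internal CpG and both fragment
ends are pooled.  Alignment is out of scope; the FASTQ reader therefore
expects the mapped locus encoded in the read id (`chrom:pos`), as the
simulator and upstream mapping exports produce.

Per-site methylation is the raw fraction `m/(m+u)`; no shrinkage or beta
prior is applied, so reported values are directly interpretable as
molecule fractions.  Sites must reach 100 tags in **every** sample of a
comparison (inclusive boundary); the threshold is configurable
(`--min-coverage`) since lower-coverage analyses (10 or 3 tags) trade
precision for breadth.

Region summaries average the per-site fractions **unweighted** across
sites (promoter `[TSS−1000, TSS+1000)`, gene body `[TSS+1000, TES)` in
transcription orientation; bodies are empty for transcripts ≤ 1 kb).  A
coverage-weighted mean is available behind `weighted=True` but is not
the default: the unweighted mean treats each CpG as one observation of
the region's methylation state rather than letting high-coverage sites
dominate.

Call rules use the thresholds exactly as stated in the parameter
registry, with inclusive boundaries (≤ 1 %, > 2 %, ≤ 10 %, ≥ 70 %,
20-point delta).  The 20-point delta comparison carries a 1e-12 epsilon
so that e.g. 0.30 − 0.10 (not exactly representable) still qualifies.
The FDR of a rule is the number of calls divided by the number of
eligible units on a null pair of equivalent samples; eligibility mirrors
the rule's baseline band (promoter gains: measured baseline ≤ 1 %).

## Coordinates and windows

All internal coordinates are 0-based half-open; BED is consumed
natively and refFlat's 0-based txStart / exclusive txEnd map onto the
same convention on read.  Windows stated in transcription-relative
offsets `[a, b)` map to genomic `[tss+a, tss+b)` on the plus strand and
mirror to `[tss−b, tss−a)` on the minus strand, so transcription offset
`d` on the minus strand is genomic `tss − 1 − d`.  The histone-mark
window (−1 kb/+0.5 kb) is deliberately distinct from the methylation
promoter window (±1 kb); both live in `AnalysisParameters` and are never
conflated.  Membership tests (gene in PMD, peak at promoter) use any
1 bp overlap, and gene-level annotation membership is evaluated on the
promoter interval.  The pipeline is assembly-agnostic: all inputs of one
run must share a coordinate system, recorded as a label in the run
configuration.  Operations are per-transcript; gene-level summaries can
collapse by "any transcript qualifies" (marks) or by the
highest-expressed transcript (fold changes) via `collapse_transcripts`.

## Chromatin states and switches

States are the four-way decomposition of the two mark indicators.  A
"K4↔K27 switch" defaults to: exclusively one mark before, carrying the
other (exclusively or bivalently) after; the strict
exclusive-to-exclusive variant is also computed, since published switch
counts rarely state whether bivalent intermediates qualify.  Peak scores
are ignored for marking — marking is defined by peak location only.
Footprints are merged-union lengths, invariant to interval order and
pre-splitting.

## Expression normalization

`mode_normalize` histograms per-gene log₂ ratios (genes ≥ 20 raw tags in
both samples) in bins of width 0.1 over ±8 and returns
`2^(−modal bin center)` as the factor for the second sample.  Bins are
**centered on integer multiples of the bin width**: a pure global c-fold
scaling then lands in the bin centered nearest log₂ c, so the factor is
exact for c a power of two and errs by at most half a bin in general.
Ties between maximal bins break toward the center nearest zero,
preferring the positive side; a secondary peak within 5 % of the maximum
raises a multimodality warning.  The total-count factor and its relative
difference from the mode factor are reported as a diagnostic on every
run (they agree closely only when the transcriptome is stable — this is
data-dependent and therefore never enforced).

Fold changes add a pseudocount of 1 to the normalized values on both
sides of the ratio (zeros occur; the pseudocount biases extreme fold
changes toward zero by ~0.15 log₂ units at expression ~300 tags, which
the recovery tolerances account for).  Categories: HIGH at ≥ 9-fold
(4-fold for monolayer-vs-sphere style comparisons), MODERATE at ≥ 2-fold
— a boundary this package defines, since "moderate" is otherwise
unspecified — else UNCHANGED.  The 2×2 switching-vs-highly-altered table
uses Fisher's exact test (sample odds ratio).

## TSS meta-profiles and smoothing

Observations (per-site methylation, per-position peak occupancy) are
assigned signed strand-aware distances to each subset gene's TSS,
aggregated per distance (or per uniform grid bin with `anchor="bins"` —
both anchorings are provided because figure conventions differ), and
smoothed by a k-neighbor running mean (k ∈ [25, 50], default 35).  The
running mean uses **circular (wrap-around) windows** over the ordered
bins: the smoother is then doubly stochastic, so it conserves the global
mean of the track exactly instead of distorting it at the ends; the cost
is that the few bins at the extreme negative and positive distances
average in a little of the opposite tail, both of which are background
at the default ±10 kb span.  Windows are capped at the track length and
rounded to odd size.

"Peak intensity" defaults to binary per-base occupancy (1 inside any
peak), which needs no read-level data; a score-weighted variant uses the
BED score column.  The methylation-gain/K27-gain coupling statistic is
the mean occupancy change (comparison − baseline) over each gene's CpG
sites within ±1 kb of the TSS, contrasted between gain genes and matched
no-change genes; significance is a seeded one-sided gene-label
permutation test (default 1,000 permutations, add-one corrected).

## Synthetic data: what it emulates and what it does not

The generator's defaults are the study conditions: 2 chromosomes × 5 Mb
with 2,000 genes (sized so every recovery property runs in seconds),
PMDs covering 40 % of the genome (±2 % realized, in 100 kb blocks), CpG
islands on 90 % of promoters, LADs on 30 %, repeats (SINE/LINE/
satellite) on ~15 %.  Baseline methylation: CGI promoters uniform in
[0, 0.9 %], non-CGI promoters intermediate, gene bodies Beta-distributed
around 20 % (PMD) / 40 % (non-PMD), intergenic background around
70–85 %.  Planted effects: +5 points on the promoter sites of 90 CGI
genes, and −25 points on 18.6 % of baseline-methylated (≥ 70 %) sites,
drawn inside PMDs first.  DREAM tags are Binomial(coverage, p) with
Poisson coverage around 200 by default.  Chromatin states draw from
planted per-condition fractions and a transition matrix; peaks fully
cover the mark window (K27 peaks broader, as domain callers produce),
and gene packing reserves margins so no peak can reach a neighbor's
windows — discrete recovery (states, switch matrices) is therefore exact
in noiseless mode, separating logic errors from statistical tolerance.
Optional Gaussian edge jitter is off by default.  Expression is
negative-binomial (Gamma–Poisson, dispersion 0.1) with log-normal
per-gene means (median 300 tags), ×1/32 on K4→K27 switchers, ×5 on
K27→K4 switchers, a configurable library-size multiplier, and a
monotone (1−m)³ repression of expected expression by promoter
methylation.

Not emulated: read-mapping artifacts, GC bias, incomplete digestion,
copy-number variation, spatial autocorrelation of methylation beyond the
PMD block structure, and realistic peak-caller noise.  Passing recovery
tests therefore demonstrates correctness of the estimators under the
assumed sampling models, not robustness to those real-data pathologies.

Determinism: `simulate_all` spawns one child generator per stage from a
single seed sequence, so regeneration under the same seed and
configuration is byte-identical file for file.

## Numerical and testing choices

The normalization-recovery check runs the generator with dispersion 0
(pure Poisson count noise, i.e. technical replicates of a stable
transcriptome): library-size recovery to half a bin is a property of the
depth estimate, and biological dispersion of 0.1 widens the log-ratio
distribution (σ ≈ 0.65 log₂ units) far beyond the bin width, making the
modal bin itself a noisy estimator.  The switch-coupling recovery study
uses 800 genes at 50/50 K4/K27 with 50 % transition probability (~200
genes per switching class) and mean expression 1,000 tags so the
pseudocount bias stays within the ±0.3 recovery tolerance.  Permutation
p-values are one-sided with add-one correction and never exactly zero.
Degenerate inputs (constant vectors, empty classes, empty gene subsets,
zero-coverage sites) return flagged NaN results or raise, as documented
per function; undefined methylation (zero coverage) propagates as NaN
and the unit is skipped and counted rather than imputed.
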