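# Methods

This note documents the models, conventions, and design choices behind
`cnvhotspots`, in the order the pipeline runs.

## Coordinates and the mappable genome

All internal coordinates are 0-based half-open (BED convention); readers
for 1-based formats convert at the boundary, and chromosome names pass
through verbatim. A `MappableGenome` couples chromosome sizes with a sorted
disjoint exclusion mask (assembly gaps, unmappable sequence). Which mask
defines "mappable" is an input, not a built-in: real analyses should
supply their assembly's gap track. Every permutation statistic samples
only placements that lie entirely in mappable sequence.

## CNV regions

CNVs longer than 2.5 Mb (strictly greater) are omitted before merging so
that chromosome-arm-scale events cannot nominate spurious hotspots; the
filter runs before merging, in the order the procedure is defined.
Merging is single-linkage: two CNVs share a region iff connected by a
chain of pairs that overlap or are separated by at most 750 kb (a gap of
exactly 750 kb merges — "no more than"). Merging deliberately ignores CNV
type and treatment; members keep their labels for downstream
stratification. Classes: singleton (1), cluster (2–4), hotspot (≥ 5
members). The per-region median member size uses the lower midpoint for
even counts, so it is always an observed value and deterministic.

## Permutation statistics

The null re-places each interval, length preserved, uniformly over all
valid start positions genome-wide — implemented by exact inverse-CDF
sampling over the valid-slot counts of the mappable runs, which makes a
chromosome's probability proportional to the slots it offers. Placements
are independent and may overlap; `allow_overlap=False` switches to
rejection sampling (10⁴ attempts cap), and `placement="same_chrom"`
restricts shuffling to the source chromosome.

Overlap scores: `boolean`, `fraction_of_span` (overlapped bp / span),
`longest_feature_bp`, and `length_weighted_mean` (bp-weighted signal mean
over the span, for RPKM or timing tracks). Group enrichment compares the
group-mean score with its distribution over iterations; p-values always
use the add-one rule and so are never zero.

**Directionality.** By default the one-sided direction is chosen by the
sign of (actual − iteration median) — this is what reported
enrichment/depletion calls mean, but it bounds the null p at ~0.5 and such
p-values are *not* uniform. For calibration, and whenever a direction is
known a priori, pass `direction="enriched"` or `"depleted"`; those
p-values are uniform on (0, 1] under the null (KS-checked in the
acceptance suite over 200 null datasets).

**Clustering significance.** The headline statistic is the probability
that uniformly re-placed CNVs, merged with the same gap, yield any region
with ≥ k members. Because that statistic is a small integer, its empirical
p-values are intrinsically discrete; the module therefore also provides
the continuous statistic *total merged-region span* (smaller = more
clustered, lower tail), which is exactly exchangeable with its null and is
the statistic used for calibration checks. At the synthetic data's CNV
density (300 events on 180 Mb, an order of magnitude denser per bp than a
genome-wide screen) chance ≥ 5-member regions are common, so the ≥ k
probability saturates near 1 while the span statistic still detects the
planted clustering; both are reported.

## TU calling

Coverage is binned (default 1 kb) per strand; RPKM = reads / kb / million
mapped reads, with a shared genome-wide read total. The calling threshold
defaults to a two-component Gaussian mixture on log₁₀ RPKM of nonzero
bins, returning the posterior-equality crossing between the component
means; an effectively unimodal fit (mean separation < 0.5 σ) falls back to
a genome-wide quantile with a warning, and fixed thresholds are supported.
Supra-threshold bins are chained, sub-threshold runs ≤ 10 kb are bridged
(nascent-RNA dropouts), spans < 10 kb are dropped, and TU RPKM is computed
over the whole called span, introns included, since nascent transcription
covers gene bodies. Bin size, bridge, and minimum length are parameters;
the defaults resolve TUs at the smallest scale the analysis
discusses (tens of kb) while tolerating coverage noise. Conditions can be
merged before calling by summing counts and totals.

## Replication timing

Timing tracks are piecewise-constant segments with a declared source:
Repli-seq scores (higher = earlier) or Repli-chip log₂ ratios at probes.
Probe-level data are projected to segments by the nearest-probe midpoint
rule, terminal probes extending to chromosome ends. Interval timing is the
bp-weighted mean over covered bp; intervals with no coverage propagate NaN
and are excluded (and counted) in group summaries — never a silent zero.
Late segments: Repli-chip ratio strictly below −0.8 ("below"), or a
configurable strict score threshold for Repli-seq-style tracks; an
externally computed late-segment BED (e.g. a mid-S4-to-G2 segmentation)
can be supplied as-is. Stratified timing histograms are bp-weighted and
normalized to 100% per stratum; transcribed + untranscribed bp always
equals mappable bp. RPKM strata default to quantiles (quartiles) because
no canonical boundaries exist.

## Percent-coordinate profiles

`to_relative` is the affine strand-aware map sending TSS → 0 and
TES → 100 (invertible to < 1 bp). CNV crossing profiles use a grid from
−100% to 200% (one TU length of flank each side, step 1%); a CNV
contributes to every eligible TU it intersects (profiles are per-TU
alignments, not a partition; `multi_tu="best_tu"` restricts to the
most-overlapped TU). Length strata: large > 500 kb, small 50–200 kb.
Relative timing samples the track at each grid point's bp (the exclusive
TES coordinate samples the last bp inside the TU) and rescales by the
min/max within the TU body; TUs with fewer than two distinct values are
excluded and counted. A CNV endpoint is "inside a TU" if the CNV's own
first or last bp lies within a TU span.

## Closed-form statistics

Fisher's exact test enumerates all tables with fixed margins in exact
integer arithmetic and sums, as an exact rational, the probabilities of
tables no more probable than the observed one (the convention that
reproduces the published 1.4 × 10⁻⁷ on the 15/1 vs 20/65 CNV-count
table). Spearman's rho uses mid-ranks; its p-value is a seeded two-sided
permutation test (default 10⁴ permutations). Group differences between
region classes use two-sided Mann-Whitney U with tie correction — the
choice of test is an assumption, documented as such; equal constant groups
return p = 1.

## Synthetic study conditions

The generator is the testbed's definition of "data like the study's", with
all randomness flowing from one seed through named substreams (genome /
TUs / coverage / timing / CNVs), so a model is one reproducible dataset.

- *Genome*: 3 chromosomes × 60 Mb; 2% excluded in 4 gaps per chromosome.
- *TUs*: 200 non-overlapping units (minimum 50-kb separation); body
  lengths log-normal (median 60 kb, σ = 1) plus five planted large TUs of
  1.0–2.0 Mb spread across chromosomes; strands random; log₁₀ RPKM normal
  (μ = 0, σ = 0.5) with correlation −0.5 against log length, reproducing
  the observation that the largest units are not the most intensely
  transcribed.
- *Coverage*: Poisson reads per 1-kb bin, 20 expected reads per RPKM unit
  over TU spans on the TU's strand, background 0.1 reads/bin/strand —
  deep enough that the mixture threshold separates signal from noise, as
  in a real nascent-RNA library.
- *Timing*: Repli-seq-style score, late baseline 35 off-TU, early baseline
  75 over TUs, minus a sinusoidal mid-TU delay of 25 units per Mb of TU
  length (capped at 60), plus N(0, 1) segment noise at 10-kb resolution.
  This encodes "TUs replicate early except that large TUs delay toward
  their middles", which yields the monotone length → later-timing
  relationship and the mid-TU minimum of the relative profiles.
- *CNVs*: 200 deletions + 100 duplications; lengths log-normal with median
  186 kb (the human median event size). Each event picks a locus with
  weight `(L / N_s)²` per TU (N_s = 300 kb) against a uniform background
  weight of 3 × 10⁻⁷ per mappable bp (≈ 20% background events). Deletion
  centers are N(50%, 15%) truncated to the TU body; duplication centers
  come from flank lobes at −25% and 125% (σ = 15%).

What the generator does *not* emulate: sequence context (A/T-rich
flexibility islands, breakpoint microhomology), recurrent NAHR events,
treatment-specific CNV spectra, cell-line heterogeneity, and real
hg19/mm9-scale genome size — the synthetic genome is ~17× denser in CNVs
per bp, which inflates chance clustering (see above). Passing tests
therefore demonstrate the correctness and calibration of the machinery
and its power on planted structure, not genome-wide human effect sizes.

## Problem sizes

Default test-suite scales: calibration uses 200 null datasets (1 × 30-Mb
genome, 25 CNVs, 199 iterations each); structure recovery uses 20 seeds of
the default model; TU-caller recovery uses 20 planted TUs (50 kb–2 Mb,
SNR ≥ 5) on a 2 × 40-Mb genome; enumeration checks cover all 46,375
contingency tables with N ≤ 30. These sizes were chosen so the whole suite
runs in well under a minute per component while leaving Monte-Carlo
margins far from the asserted thresholds.

## Known limitations

- The permutation null treats region lengths as fixed and placements as
  independent; it does not condition on inter-region spacing.
- The mixture threshold assumes a two-population log-signal; promoters or
  enhancer-like intermediate bins in real data may call for the quantile
  or fixed methods.
- Merged CNV regions may span excluded gaps while permuted placements
  cannot; on dense masks this mildly biases enrichment nulls (the
  calibration setup keeps the merge gap below the gap size, where the
  effect vanishes).
- `clustering_significance`'s ≥ k statistic is density-sensitive;
  genome-scale conclusions require genome-scale inputs.
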