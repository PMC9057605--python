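# Methods

This note records the models, parameter choices, and numerical
conventions behind the pipeline, and what the synthetic data do and do
not establish.

## Coordinates and formats

All coordinates are 0-based half-open (BED/bedGraph convention),
everywhere. Chromosome names match as exact strings. Strand is carried in
the TSS table but deliberately ignored by signal extraction, overlap
logic, and promoter windows (all windows are symmetric around a point);
none of the implemented statistics is strand-aware. Signal tracks are
piecewise-constant interval lists; uncovered bases have value 0, and
overlapping input intervals are a format error rather than being summed.

## Tile-based differential methylation

The genome is partitioned into adjacent tiles of `tile_bp` (default
400 bp; the last tile of a chromosome is truncated). Within a tile and
condition, a CpG contributes only when its coverage reaches
`min_cov_per_cpg` (default 10) in **every** sample of that condition — a
deliberately strict rule that keeps the pooled counts comparable across
replicates; a position absent from a sample counts as coverage 0.

The per-tile test is a two-sided Fisher exact test on the pooled
2 × 2 table [[M₁, T₁−M₁], [M₀, T₀−M₀]]. The two-sided p follows the
classical convention: the sum of hypergeometric probabilities of all
tables with the observed margins whose probability is ≤ the observed
probability, with a relative tie tolerance of 1e−7 so that floating-point
round-off cannot split exact ties. Tables with grand total ≤ 500 are
evaluated in exact integer arithmetic; larger ones via log-gamma.
Fisher on pooled counts ignores between-replicate overdispersion, so its
p-values are anti-conservative in isolation; the emitted-call criteria
(|Δ| ≥ `min_delta`, BH q ≤ `q_max` over eligible tiles, ≥ `min_cpg` CpGs
in both conditions, replicate consistency) are what control the realized
false-call rate, which the null simulation in the test suite measures
directly (≈ 0 emitted calls at the default thresholds).

Replicate consistency is operationalized as: every pairwise difference
(case replicate fraction − control replicate fraction), over the same
eligible CpGs, has the same strict sign as the pooled Δ. Directionality
only — per-replicate significance is not required.

Both difference presets from the study design are exposed: `min_delta`
0.10 (the cross-comparison scan) and 0.20 (the stringent preset); the
default is 0.10. Multiple testing is Benjamini–Hochberg over eligible
tiles only. Venn counts use the ≥ 1 bp single-partner overlap rule; the
intersection count is the number of regions of the first set that touch
any region of the second, so the displayed fraction is relative to the
first set.

## Ranked-signal knee and enrichment

Region signal is the coverage-weighted mean over [center − h, center + h)
with h = 2.5 kb; uncovered bases contribute 0, and clipping at
chromosome bounds shrinks the denominator to the in-bounds length.
Signals are used raw: the knee is invariant under positive affine
transforms (chord and curve transform together), so within-track scaling
is immaterial.

The knee of the ascending ranked curve is the rank maximizing the
vertical gap below the chord through the end points — exactly where a
translated ("slid") copy of that diagonal becomes tangent to a monotone
hockey-stick curve. For a fixed chord slope the perpendicular-distance
argmax coincides with the vertical-gap argmax. Ties resolve to the
largest rank (the most conservative High set), and a maximal gap ≤ 1e−9
(curve indistinguishable from its chord, e.g. a constant or linear curve)
yields no knee. High = ranks above the knee; Low = remaining regions with
signal < `low_threshold` (default 0.5, track units); Mid = the rest. High
takes precedence over Low, so the three labels always partition the set.

Enrichment of a region subset in a class is the Fisher exact test on
(group ∩ class, group ∖ class, others ∩ class, others ∖ class), reported
with fold enrichment (share of the group in the class divided by the
class's overall share) and an α = 0.05 significance flag. The end-point
chord makes the knee sensitive to a single extreme signal value; with the
default generator the knee can land either just below the signal plateau
or inside it, but the planted-enrichment contrast (coupled set
p ≪ 0.01, random set fold ≈ 1) holds in both regimes across seeds.

## NB differential expression

Filtering keeps genes with ≥ `min_count` (10) counts in ≥ `min_samples`
(2) samples; normalization is plain counts per million (no TMM-style
composition factors — a documented simplification). Testing uses size
factors sᵢ = library/mean(library) as offsets.

Dispersion: the raw per-gene estimate is a bias-corrected method of
moments on scaled counts, φ̂ = max(0, (v − m)/(m² − v/n)) per condition
(the −v/n term corrects E[m̂²] = μ² + σ²/n at small n), pooled across
conditions by degrees of freedom. The values used for testing are shrunk
toward a mean–dispersion trend φ(μ) = a + b/μ fitted by three rounds of
weighted least squares across genes, with per-gene empirical-Bayes
weights Vg/(Vg + τ²), where Vg approximates the estimator's sampling
variance (2(1/m + φ)²/df) and τ² is the excess between-gene variance of
the raw estimates around the trend. When the data carry no real
dispersion spread, τ² → 0 and every gene collapses onto the trend. This
replaces a simpler fixed-weight (0.5) shrink toward the median, which
measurably mis-calibrates the likelihood-ratio test at small n: the
median of the noisy per-gene estimates is biased low and the 6-df
estimation noise is correlated with the test statistic, inflating the
small-p tail (null fraction p < 0.05 of 6–9% instead of 5%). With the
trended estimator the null p-value distribution passes KS uniformity at
α = 0.01 in the packaged calibration simulations; the fixed-weight
variant remains available via `shrink_weight`. The median ("common")
dispersion is still computed and reported.

The test itself is a likelihood-ratio test with fixed φ̂ per gene:
H0 one mean μ, H1 condition-specific means, both with offsets; the mean
is fitted by Newton iteration on log μ (concave in log μ; with equal size
factors the initial value Σy/Σs is already the MLE), the statistic is
2(ℓ₁ − ℓ₀) against χ²₁, and BH runs over all tested genes. φ̂ < 1e−8 is
treated as Poisson. log₂FC uses offset-adjusted condition means with a
0.5 pseudocount. Agreement with an independent GLM implementation
(statsmodels, NB family with fixed alpha) is verified in the tests to
~1e−8 in p. This NB-LRT is an explicit, calibrated approximation of the
generalized-model machinery RNA-seq packages provide, not a clone of any
of them (no quantile-adjusted CML, no exact test).

The z-score table takes the `n_top` (500) genes by variance of
log₂(CPM + 1) across samples (ties by gene id), standardized per gene with
the n−1 variance; constant genes are never selected while enough
non-constant genes exist.

Activation grouping compares two contrasts of the same curated list:
Group 2 (repressed in the mutant) when log₂FC_other − log₂FC_case ≥ 1
with the case contrast below zero or below the other; Group 1
(concordant) when the signs agree and the contrasts differ by < 1;
anything else is unclassified. The two margins (1.0 log₂ unit each) are
package conventions, config-exposed; the 65%/35% split is demonstrated on
the planted closed-loop fixture only and is not claimed for any real
dataset, where the authors' assignment rule is unknown.

## Integration

Promoter methylation is the unweighted mean of per-CpG (or bin-center)
methylation fractions in [TSS − 1 kb, TSS + 1 kb). Quartile bins are
left-closed right-open with the last bin closed
([0, .25) [.25, .5) [.5, .75) [.75, 1]) — the printed overlapping
brackets are resolved into a true partition. The 20% rule is an absolute
difference of methylation fractions (≥ +0.20 hyper, ≤ −0.20 hypo, with a
1e−9 guard against float round-off at the boundary), consistent with the
Δ thresholds of the methylation caller. Cross-tabulation uses the
intersection of the two gene universes and logs its size; the DE table
passed in defines the universe, so the caller chooses between "all
filtered genes" and "DE genes only". Region–gene association is nearest
TSS by center distance within 50 kb (ties to the smaller gene id), with a
promoter flag for overlap with TSS ± 1 kb — a deliberately simple,
deterministic surrogate for regulatory-domain association tools, adequate
for bookkeeping but not for ontology claims.

## Synthetic data

The generator's defaults are the study conditions at roughly 1/20 scale:
one chromosome of 2,900 × 400 bp tiles; planted hypermethylated sets of
139 (tet2ko) and 106 (tet2kit) tiles with a 46% overlap target achieved
constructively (shared tiles drawn first, so the realized overlap is
exact up to rounding); 20 CpGs per tile; Poisson(30) coverage;
beta-binomial methylation with baseline 0.30, effect +0.30, and precision
ν = 60 (per-CpG, per-sample π ~ Beta(pν, (1−p)ν); replicates share
centers), which puts visible biological overdispersion between replicates
without drowning the planted effect. Two replicates per genotype, as in
the study design.

The ChIP track is a constant background (0.2) with super-enhancer
intervals of 2 kb at amplitude 30 (log-normal jitter, σ = 0.1; overlaps
merged at the maximum) centered on 80% of the tet2ko HMR tiles plus a few
extra sites. A constant background makes the degenerate no-enhancer
design exactly chord-like (no knee), and the modest amplitude jitter
keeps the plateau coherent so the knee separates background from
enhancers rather than splitting the plateau.

Expression: 2,000 genes with log-normal baseline means (median 100,
log-sd 2 — heavy-tailed so that stable, highly expressed genes dominate
library mass; with a light-tailed baseline the planted up-regulated genes
would shift the library totals enough to make plain CPM normalization
fabricate "down" calls, which is a composition artifact, not a test
defect). Dispersion follows a trend φ(μ) = 0.02 + 3/μ unless a constant
is requested (the calibration designs use φ = 0.1). The curated list is
31 concordant + 17 repressed genes at high baseline mean (1,000), which
is what makes the closed-loop grouping exactly recoverable at two
replicates per condition. Half of the repressed genes have their TSS
placed on 5-tile (2 kb) planted hyper blocks of the mutant genotype so
the promoter window, which spans 2 kb, actually registers the gain; these
block tiles are carved out of the mutant set's exclusive budget so
planted set sizes stay exact.

What the synthetic data do **not** emulate: real CpG density maps and
MspI fragment structure, read-level artifacts, TMM-worthy composition
shifts, correlated dispersion structure, genuine enhancer–gene looping.
Passing tests therefore establish internal correctness and calibration of
the statistics under the stated generative assumptions — not performance
on real sequencing data.

## Problem sizes and determinism

Default runs use the 1/20-scale genome (2,900 tiles), 2,000 genes, and
2–4 replicates; an end-to-end run takes a few seconds, and the
calibration suites (2,000 tiles / 2,000 genes) run in well under a minute
each. Everything downstream of a seed is drawn from one
`numpy.random.Generator`, so identical configs produce byte-identical
data files and reports; the pipeline report contains only seeds,
thresholds, and computed counts (no paths or timestamps) to keep that
property checkable by byte comparison.
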