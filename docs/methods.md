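# Methods

This note documents the models, statistics and numerical choices behind
`eventmap`, in the package's own terms: what each stage computes, which
parameters matter, what the synthetic-data generator does and does not
emulate, and where the design was genuinely open.

## The analysis in one paragraph

Sixteen objects are experienced along a one-way route through a 2D
environment, giving every object pair a spatial distance (Euclidean
between map positions) and a temporal distance (summed traversal time of
the intervening route segments). Teleporter segments bridge a large
spatial span in negligible time, decorrelating the two domains across the
120 pairs. Before and after learning, the same picture-viewing task (PVT)
presents the 16 objects plus a target 12 times each in identical order.
Multivoxel activity patterns for every trial are correlated across trials
(excluding same-block combinations), averaged per object pair, and the
post-minus-pre difference of these 16×16 matrices — the pattern-similarity
change, PS′ — is compared against each participant's remembered (or the
objective) pairwise distances with Spearman correlation. First-level
inference standardizes the observed coefficient against a 10,000-shuffle
null; second-level inference tests the mean subject z with a 10,000-flip
sign-flip test, one-tailed in the negative direction (closer remembered ⇒
larger similarity increase), with Benjamini–Hochberg FDR over the
ROI × model family. A searchlight variant runs the identical computation
in 9 mm spheres and corrects family-wise error with the max-statistic
(min-T) sign-flip distribution, optionally restricted to a small-volume
mask.

## Pattern extraction

Stimulus presentation is locked to volume onsets; the analyzed volume of
a trial with onset index v (0-based) is v + 2, i.e. the third volume after
image onset, covering 4540–6810 ms post-onset at the 2.27 s repetition
time. Before extraction, each voxel's time series is residualized against
an intercept plus the six motion parameters (ordinary least squares).
Constant motion columns (e.g. the all-zero default of the synthetic
generator) carry no information beyond the intercept and are dropped;
genuinely collinear regressors raise an error naming the redundant
columns. Residualization is idempotent and extraction is invariant to
trial-row order. Target-object trials are discarded. Whether the residual
series is additionally demeaned is inert downstream, since Pearson
correlation is location/scale invariant.

## Cross-correlation and PS′

Every trial's voxel vector is Pearson-correlated with every other trial's
except combinations within the same block; with B blocks this gives
B² − B ordered combinations per distinct object pair (132 at B = 12) and
B(B−1)/2 unordered combinations on the diagonal (66). Cell means average
raw correlation coefficients; a Fisher-z-averaging option exists.
Zero-variance trial vectors are excluded from the affected means and the
per-cell inclusion counts are reported. PS′ is the cell-wise post − pre
difference. Model fits use only the 120 off-diagonal pairs in a fixed
canonical order (row-major upper triangle); self-similarity cells never
enter because distance models are undefined for self-pairs.

## Model variants

Five remembered-distance variants: spatial, temporal, their product
("combined", computed on min-max-normalized [0, 1] ratings so the lowest
values mark pairs close in both domains), and each single domain after the
other has been regressed out of the PS′ pair vector (OLS with intercept,
residuals carried forward). Objective variants use the route's Euclidean
and along-route-time distances; with per-repetition duration jitter
enabled, the temporal distance is the median traversal time across
repetitions, which reduces to the plain segment sum in the no-jitter
default.

## Nonparametric inference

First level: the observed Spearman coefficient is standardized against
surrogate coefficients obtained by permuting the model pair vector against
the fixed PS′ vector: z = (ρ − mean)/sd. Mean/sd standardization is used
because it alone yields a statistic on all of ℝ; the empirical quantile is
reported alongside. For pair vectors of ≤ 8 entries all permutations are
enumerated. Pair-level shuffles ignore the within-matrix dependence of PS′
entries; a Mantel-style object-label permutation mode is available
(`mode="label"`), but the pair-level default is retained because the null
calibration experiment (below) shows it to be accurate for this generator.

Second level: surrogate means of randomly sign-flipped subject statistics.
With 2ⁿ ≤ 2²⁰ the full flip set is enumerated and p is the exact fraction
of surrogate means at or beyond the observed one (so n identical negative
values give exactly 2⁻ⁿ); otherwise a Monte-Carlo sample with the add-one
correction (k+1)/(N+1). The default direction is one-tailed negative; FDR
(Benjamini–Hochberg, via statsmodels) is applied to the one-tailed p over
the full ROI × model family (15 for the remembered-distance analysis, 9
for the objective one).

The objective-distance 2×2 (high/low space × high/low time, by median
split per domain) analysis averages PS′ within the four cells per subject
and tests each effect with the paired-t contrast equivalence, which is
exact for a 2×2 within-subject design (F = t² on one denominator df of
n − 1); pingouin's repeated-measures ANOVA serves as an independent
cross-check in the test suite.

## Searchlight

Spheres of physical radius 9 mm (6 voxels at 1.5 mm isotropic; anisotropic
voxel sizes supported, distances measured between voxel centers in mm) are
centered on every brain-mask voxel, intersected with the grey-matter mask,
and dropped below 30 members. Each sphere runs the identical ROI
computation; the coefficient is written to the center voxel. Group
inference is a voxelwise one-sample T (negative tail) with family-wise
correction by the sign-flip min-T distribution over the correction mask —
an exact-FWER substitute for cluster-enhancement corrections, chosen
because it is simple to verify against enumeration; cluster enhancement is
a declared extension point. Voxels not analysed in every subject are
excluded and reported. Identical subject maps give zero between-subject
variance; T is then ±∞ with the natural ordering, so the flip-symmetry
bound p = 2⁻ⁿ is attained exactly.

## Synthetic-data generator

The generator's defaults are the study conditions: 16 objects, 3
teleporters, 12 blocks × 17 objects = 204 trials per session with a 50/50
split of 2/3-TR inter-trial intervals, identical pre/post recipes, 26
subjects per cohort, 240 distance-judgment trials.

**Routes.** Object coordinates are uniform on a 100-unit square; the route
order is a random permutation; segment durations are length/speed at a
constant 2 units/s; the three spatially longest segments (minimum span 40
units) become teleporters with a 1 s duration. Candidates are rejected
until the Pearson correlation of z-scored spatial and temporal pair
distances is below 0.1 in magnitude and all four high/low × high/low
median-split cells are populated (about two thirds of candidates pass;
a structurally coupled configuration, e.g. collinear boxes at constant
speed without teleporters, fails with an explicit error). Distance units
are arbitrary — only ranks and z-scores matter downstream.

**Recipes.** Twelve independent shuffles of the 17 objects are
concatenated; ITIs are a balanced permutation; recipes whose one-way F of
within-block positions across objects is significant at α = 0.05 are
discarded and regenerated. Within-block positions are used because block
offsets common to all objects would otherwise swamp the between-object
signal and the rejection rule would never fire. A 13-volume inter-block
gap emulates the 30 s rest.

**Behavior.** A rating is squash(a·z(own) + b·z(other) + ε) with the
logistic CDF as the bounded, monotone squash; defaults a = 0.6, b = 0.16
emulate the reported own/cross-domain influence, and the residual sd
0.78 ≈ √(1 − a² − b²) gives the latent judgment approximately unit
variance, so standardized regression on the ratings recovers (a, b)
(verified to ±0.1 across 26 simulated subjects). Slider values are treated
as continuous in [0, 1]. Free recall is an adjacency-biased walk over
route ranks (transition weight e^(−κ·gap), κ = 1) with recall count drawn
from N(13, 3²) clipped to [3, 16]; map responses are true coordinates plus
isotropic jitter of sd 0.155·map side (mean displacement ratio ≈ 0.19),
clipped to the map.

**Volumes.** Object patterns are rows of L·Q where Q is an orthonormalized
zero-mean Gaussian basis and L·Lᵀ is the target correlation matrix, so the
sample correlation structure is exact, not asymptotic. Pre-learning
patterns have an identity (configurable equicorrelation) structure; inside
the designated effect region the post-learning target adds a perturbation
whose sample Spearman correlation with the supplied distance model is
calibrated to `effect_size` by bisection (perturbation sd 0.06 on the
correlation scale, small enough that the target stays positive definite);
outside the region post patterns equal pre patterns. In the cohort
simulator the implant tracks each subject's remembered combined distance
structure, so all remembered-model variants carry signal. The analyzed
volume of each trial carries the pattern directly — no hemodynamic model,
since the pipeline reads exactly that volume; all other volumes are white
noise (sd `noise_sd`, default 1.0; float32). The motion table is zeros by
default with an optional sinusoidal nuisance. Everything is reproducible
bit-for-bit from the seeds.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: hemodynamic convolution and temporal
autocorrelation, physiological and motion artifacts (beyond the optional
sinusoids), spatial noise correlations and smoothness, registration and
distortion errors between sessions, grey-matter segmentation errors, and
any systematic pre-session similarity structure beyond the configured
base correlation. Calibration results transfer to real data only insofar
as the exchangeability assumptions of the shuffle and sign-flip tests
hold there.

## Calibration experiments and problem sizes

The cohort-level experiments in `eventmap.calibration` run the full
pipeline end to end on an 8³ grid with 4³ effect and control regions,
1000 shuffles and 1000 flips: 200 zero-effect cohorts of 26 subjects for
the null calibration (group rejection rate at α = 0.05 within the exact
binomial interval; pooled first-level z mean within ±0.05 and sd within
[0.9, 1.1]) and 100 implanted-effect cohorts (Spearman −0.6, trial noise
0.3) for power (spatial, temporal and combined models each significant in
≥ 95/100 cohorts; control region at its nominal false-positive level).
The grid size only scales the Monte-Carlo error of the pattern
correlations, not the validity of the statistics, and was chosen so both
experiments complete in a few minutes each.

## Degenerate inputs and tie handling

Spearman uses average ranks. Constant pair vectors, all-zero subject
statistics, zero-variance shuffle nulls, empty mask intersections and
sub-minimum recall sequences raise explicit errors or flagged results
rather than silent NaN. Fisher z of |r| = 1 is capped at the value for
r = 0.9999 and flagged so group tests stay defined on degenerate
synthetic cases. Rating-error vectors whose spread is at floating-point
rounding level (≤ 1e-10 on the z scale) are treated as constant.

## Known limitations

No multivariate noise normalization or cross-validated distance
estimators; no slice-time correction or registration (synthetic data is
generated pre-aligned); no cluster-extent or cluster-enhancement
inference; native voxel indices only (no template-space coordinate
reporting). The pair-level shuffle null is anti-conservative in principle
when both matrices share strong object-level structure — the label
permutation mode exists for that case.
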