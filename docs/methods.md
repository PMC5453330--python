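# Methods

## Data model

A `TimeCourse` is a feature × sample matrix of log2-scale values with
per-sample metadata: condition, zeitgeber time (ZT, decimal hours in
[0, 24)), day index and replicate id. An `OccupancyTable` adds a
per-locus "occupied in ≥1 sample" flag; that flag is an *input*
(computed upstream by peak calling) and all occupancy analyses restrict
to flagged loci. Two conventions run through everything:

* **ZT collapse.** Samples from consecutive days at the same ZT are
  replicates: the model depends on ZT mod 24 only. A single 24-h
  harmonic is fitted to the pooled samples rather than to timepoint
  means, so replicates and days contribute as independent observations.
* **Day/night split at ZT12.** Day = ZT ∈ [0, 12) (lights on), night =
  ZT ∈ [12, 24). In the canonical 6-timepoint design the day group is
  {ZT02, ZT06, ZT10} and the night group {ZT14, ZT18, ZT22}, both days
  pooled (6 vs 6 samples with 3 replicates per ZT, 2 vs 2 × 3 timepoints
  in the 12-sample ChIP design).

## Cosinor fit

Ordinary least squares on the design `[1, cos(2πt/T), sin(2πt/T)]`,
T = 24 h fixed (no period scan, no additional harmonics). Amplitude is
`sqrt(b1² + b2²)`; the acrophase is computed with the two-argument
arctangent, `φ = atan2(b2, b1)·T/2π` mapped into [0, T), which always
returns the time of the fitted maximum (a one-argument `atan(b1/b2)`
form is quadrant-ambiguous and agrees only where its quadrant is valid).
The rhythmicity test is the nested-model F against the intercept-only
model, `F = (SS_model/2)/(SS_resid/(n−3))`, with an exact F(2, n−3)
reference distribution; this is exact under Gaussian noise, and the test
suite verifies the implied type-I error calibration empirically.

Numerical edge cases: fits need ≥4 samples and ≥3 distinct ZTs (else
`InsufficientDataError`/`DegenerateDesignError`); features whose total
variation is at floating-point noise level are reported as constant
(b1 = b2 = 0, F = 0, p = 1); amplitudes ≤1e-12 get a missing phase;
features with missing values are flagged `ok = False` and carried
through rather than dropped. Phase values produced by the modulo can
round to exactly T and are mapped to 0 to keep the [0, T) contract.

## Rhythm calls and permutation FDR

A feature is rhythmic when p is *strictly* below the threshold (default
1e-4 for expression; "equal" is not rhythmic). The FDR of a call set is
estimated by permuting the sample→ZT assignment — one reshuffle per
permutation, applied jointly to all features so the gene–gene
correlation structure is preserved — refitting everything, and taking
`mean(permuted significant counts)/observed count`, clipped to [0, 1].
The estimate is undefined (reported missing, with a note) when nothing
is significant on the observed labels. Per-gene independent permutation
is the main alternative; joint permutation was chosen because columns,
not genes, are the exchangeable units under the null of no time effect.

## Amplitude filter and set comparison

The amplitude cutoff eliminates features with A strictly below 0.25
log2 units; equality survives. A log2 amplitude A corresponds to a
peak-to-trough fold change of `2^(2A)` (0.25 → 1.41), and helpers
convert in both directions. Venn partitions of 2–3 named rhythmic sets
are exact and disjoint. RCF curves use strict "greater than":
`freq(a) = #{x > a}/n`, hence non-increasing from ≤1 to ≥0. Phase
histograms use half-open hourly bins [k, k+1) labelled ZTk–(k+1);
inputs must be pre-normalised into [0, 24). Phase shifts between
conditions are wrapped differences in (−12, 12], summarised by the
*circular* mean (wrapped arithmetic means are biased when shifts
straddle the ±12 h wrap point); features with undefined phase are
excluded and counted. Heatmap row normalisation is min–max to [0, 1]
across the concatenation of all conditions' timepoint means (the
display convention is lowest → white, highest → red, which implies
range scaling rather than z-scoring); constant rows map to 0.5 and are
flagged.

## PAM clustering and k selection

Profiles are per-feature ZT means, z-scored per row (population SD) so
distances reflect the *shape* — i.e. the phase — of the daily profile
rather than amplitude or baseline; constant features are flagged and
set to zero. The metric defaults to Euclidean and is configurable.

PAM is the Kaufman–Rousseeuw algorithm: greedy BUILD initialisation
followed by best-improvement SWAP to convergence, with ties broken
toward the lowest index. The converged objective (total dissimilarity
to nearest medoids) is asserted non-increasing at every step. Because
SWAP is a local search, the implementation additionally restarts it
from seeded random medoid sets (default 10 starts including BUILD) and
keeps the best converged solution; on small instances this reliably
attains the exhaustive-search optimum, which the test suite checks
against a brute-force oracle. The k scan covers 2–10 by default; the
selected k maximises the mean silhouette width (per-point
`(b − a)/max(a, b)`, computed on the precomputed dissimilarities), with
ties going to the smallest k. All-identical profiles are rejected
(silhouette undefined). Clustering is performed on one (reference)
condition's profiles; other conditions are rendered in the same gene
order for display.

## Moderated day/night comparison

Two-group comparisons of occupancy scores use an empirical-Bayes
moderated t implemented from its closed forms so the stage is
self-contained and oracle-testable. Per locus, the pooled two-group
variance s² with d = n_a + n_b − 2 df is modelled as
`s² ~ s0²·(χ²_d/d)/(χ²_d0/d0)`; the prior df d0 and scale s0² are fitted
across loci by the method of moments on log variances (digamma/trigamma
moment identities, trigamma inverted by Newton iteration), the
posterior variance is `s̃² = (d0·s0² + d·s²)/(d0 + d)` — always between
s² and s0² — and the moderated t has d + d0 df (normal when d0 = ∞,
which the moment fit returns when the spread of log variances is within
chi-square sampling noise). Setting the prior df to 0 reproduces the
classical pooled two-sample t exactly; the test suite also
cross-checks prior df, prior variance, t and p against the reference
limma implementation (agreement to ~1e-15) when an R installation is
available. When data are (near-)deterministic and variances carry no
information, moderation is disabled with a warning rather than failing.

Conventions: M = night mean − day mean, A = their average (an exact
bijection with the two means). For the day/night wrapper, displayed M/A
use the day- and night-*timepoint averages* (matching the common MVA
display convention) while the t statistic uses all samples; in balanced
designs the two coincide. Significance is reported unadjusted at
p < 0.05 per comparison, recorded in the result metadata
(`p_adjust = "none"`); multiplicity handling is left to the caller.
The ZT-pair comparison (default ZT02 vs ZT10, the first and last
daytime timepoints) uses all samples at each ZT. The cosine-fit
fraction applies the cosinor F test at p < 0.05 per locus.

## Synthetic generator

The generator emulates the canonical two-day diurnal design: 6 ZTs
(ZT02…ZT22), 2 days, 3 replicates per timepoint per day for expression
(36 samples/condition; published designs use 3–6 replicates per
timepoint), 1 replicate per timepoint per day for occupancy
(12 samples/condition, as in typical spike-in-normalised ChIP designs).
Defaults: noise SD 0.2 log2 units (typical residual array noise);
planted amplitudes uniform on a configured range; phases drawn from a
discrete mixture. Noise is Gaussian on the log2 scale — both expression
values and log-ratio occupancy scores are already log-scale. One RNG
stream per dataset is seeded explicitly and per-feature noise
sub-streams are derived deterministically from it, so identical
(config, seed) pairs are bit-identical.

Condition structure: the first condition is the reference. A
non-reference condition reuses the reference's per-feature amplitude
and phase scaled by `amplitude_damping` and shifted by `phase_shift_h`
for the shared rhythmic core, and draws fresh parameters from its own
ranges for features rhythmic only in it. This encodes the standard
comparative scenarios — amplitude loss in a clock knockout, damping
plus a small phase advance under around-the-clock feeding — with exact
ground truth.

Occupancy scenarios plant additive effects on a configured fraction of
loci: a night effect on all ZT ≥ 12 samples (feeding response) and an
anticipation effect at the last daytime timepoint (ZT10) that is active
only when `clock_on` is true; a global `condition_offset` emulates
overall de-repression. The planted truth is returned alongside.

What the generator does *not* emulate: probe-level microarray effects,
normalisation artefacts, read-level ChIP-seq sampling, heteroskedastic
or heavy-tailed noise, and correlated noise between features. Passing
tests therefore demonstrate correctness of the estimators and their
calibration under the stated noise model, not robustness to real-data
artefacts upstream of the log-scale matrices this package ingests.

## Problem sizes and tolerances

The verification suite uses: 10,000 null features for type-I
calibration (binomial band [0.045, 0.055] at p < 0.05; KS uniformity at
the 1% critical value 1.63/√n); 2,000 features × 200 permutations for
FDR behaviour (null estimate within Monte-Carlo error of 1, evaluated
at p < 0.05 where the observed count is non-degenerate; planted
estimate ≤ 0.1 and power ≥ 0.95 at p < 1e-4); 100 random noiseless
(A, φ) draws recovered to <1e-8; 100 random instances against a
normal-equations oracle at 1e-8; 50 random n ≤ 8 instances against
exhaustive medoid search; 600 genes in three phase groups for cluster
recovery (k = 3, ARI ≥ 0.9); and 400–500-locus occupancy simulations
with 6-vs-6 group sizes for the operating characteristics
(sensitivity ≥ 0.9, FPR ≤ 0.07) and the feeding/clock scenario
dissociation, where "no excess" is assessed on direction-signed
significant calls. `scripts/acceptance.py` recomputes all of these from
a single seed.

## Known limitations

* Fixed 24-h period; no period estimation, multi-harmonic fits, or
  non-parametric rhythm detectors.
* The F test assumes Gaussian, homoskedastic residuals per feature.
* Permutation FDR returns a single global estimate, not per-feature
  q-values.
* PAM is quadratic in the number of profiles; no large-n approximation
  is provided.
* The moderated model assumes a single prior variance component (no
  robust or trended prior).
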