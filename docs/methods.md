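# Methods

This note documents the models, numerical choices, and synthetic-data
assumptions behind the package, and what the test suite does and does not
establish about real recordings.

## Signal model and cycle segmentation

The input is a uniformly sampled, dimensionless hand-aperture signal
(distance between third-digit tip and wrist divided by hand length), 60
samples/s, 10–15 s per trial. The open–close task occupies a 0.5–4 Hz band;
pose-estimation jitter sits higher. Before differentiation and peak
detection the signal is low-pass filtered with a zero-phase 4th-order
Butterworth at 8 Hz — above the task band, below the noise floor — because
most of the 23 features are derivative-based and finite differences amplify
high-frequency noise. Velocity and acceleration are central finite
differences of the smoothed signal.

Cycles are valley → peak → valley triplets. Peaks and valleys come from
prominence-based detection with prominence = 20% of the robust (5th–95th
percentile) signal range — making segmentation invariant to amplitude
rescaling — and a minimum separation of 0.2 s (no plausible open–close
cycle is faster than 2.5 Hz by much). Same-type neighbours are collapsed to
the more extreme event, ties toward the earlier sample. A trace endpoint is
admitted as a valley when it sits at the detected valley level (within half
a prominence), so cycles that start or end exactly at the recording edge are
not discarded; without this, a trace beginning mid-valley loses its first
cycle. A signal whose robust range is numerically zero has no oscillation
and raises an "insufficient cycles" error, as does any trace with fewer
than two complete cycles. Fewer than four cycles emits a warning: decay and
variability estimates on so few cycles are unstable but still defined where
their minimum (three cycles) is met.

## The 23-feature catalog

The catalog is configuration: 23 named entries across five families
(amplitude, speed/vigor, rhythm, variability, decrement), each with an
orientation flag. The downstream scoring machinery only consumes the
orientation metadata, so an alternative catalog (e.g. a site's own feature
definitions) can be swapped in as JSON without touching code.

Definitions of note:

- **frequency** = number of complete cycles / time spanned from first to
  last cycle boundary. Using the segmented span rather than the full trace
  duration makes the estimate exact for integer-cycle signals and
  insensitive to leading/trailing non-task samples.
- **decay slopes** (amplitude, opening/closing peak speed, per-cycle RMS
  velocity, cycle rate) are OLS slopes over cycle index, expressed as
  percent of the per-trace mean per cycle; they need ≥ 3 cycles and are
  reported missing (NaN), never zero, below that.
- **jerkiness** = mean |acceleration| / mean |velocity|; the normalization
  makes it invariant to amplitude rescaling, so it measures movement
  roughness rather than vigor.
- **n_hesitations** counts interior sub-threshold velocity dips (below 10%
  of the phase's peak speed, with a 10%-of-phase margin excluding the
  natural zero crossings at phase boundaries), per cycle.

Orientation defaults: amplitude, speed, and frequency features are
higher-is-better; durations, all coefficient-of-variation and consistency
features, and hesitations are lower-is-better. Decay features are *signed
slopes* — negative in disease, where amplitude and rate decline across the
sequence (the sequence effect) — and are oriented higher-is-better: a slope
moving toward zero means less within-sequence decrement and must count as
improvement. Orienting a signed decay slope lower-is-better would reward a
*faster* decrement, which contradicts the clinical meaning of the feature;
sites whose catalogs store decrement magnitudes (positive values) should
flag those entries lower-is-better instead. The opening/closing duration
ratio is oriented lower-is-better (prolonged opening relative to closing is
the common bradykinetic asymmetry); it is near-uninformative for symmetric
signals and correspondingly receives almost no weight there.

## DWIS scoring

Improvement cells are oriented percent changes against the patient's own
off-baseline, I(p, j) = s_j · 100 · (x_j(p) − x_j(off)) / |x_j(off)|. The
|·| denominator avoids sign flips for negative-valued features (decay
slopes). Cells with |x_j(off)| below 1e−9 × the column's magnitude scale
are masked with a warning rather than producing infinities; a fully masked
feature is reported excluded.

Responsiveness r_j is the sample standard deviation (n−1; program counts
are small, so the unbiased convention matters) of column j over programs,
masked cells excluded; fewer than two usable cells gives r_j = 0. Weights
are r_j normalized to sum to one, shrunk toward uniform *over the responsive
set* {j : r_j > 0} by λ; non-responsive features keep zero weight at every
λ, and an all-zero responsiveness vector falls back to uniform weights over
all features with a warning. λ = 0.1 is the default for the main analysis;
the sensitivity grid is 0–0.45 in steps of 0.05. DWIS(p; λ) is affine in
λ, so rank changes across the grid occur only at pairwise crossing points —
the stability report flags any change of the top program and gives
Kendall's τ against the λ = 0 ranking.

Per-program, weights are renormalized over that program's unmasked features
so missing cells do not silently deflate its score. DWIS ties are broken
toward the chronologically earlier program and reported explicitly. The
off condition is appended with DWIS exactly 0, so ΔDWIS vs off equals the
DWIS itself.

## Group statistics

Per-feature cohort summaries report the median oriented percent change at
each patient's optimal program, IQR, a percentile-bootstrap 95% CI for the
median (10,000 resamples by default; the seed is a required input), a
one-sided Wilcoxon signed-rank p for median > 0, and BH-FDR q across the
features (α = 0.05). Zeros are discarded before the Wilcoxon test; the
exact null distribution of W⁺ is used up to n = 25, computed by the
signed-rank generating polynomial on doubled midranks (exact under tied
magnitudes, equivalent to enumerating all 2ⁿ sign assignments); larger
samples use the normal approximation with continuity correction. Features
with more than 50% missing values are excluded with a warning. The count of
features significant after FDR is sensitive to convention choices (SD
denominator, zero handling, α); reported analyses of the same cohort can
legitimately differ by a feature or two, so the package always reports its
own computed count together with the per-feature p and q values rather than
a headline number.

The concordance model is a linear mixed-effects regression (REML, via
statsmodels' MixedLM — the module owns the model specification and
reporting, not the optimizer): UPDRS item 3.5 improvement (baseline −
program score) on ΔDWIS with a random intercept per patient-hand; the
robustness variant regresses the raw program score on ΔDWIS plus baseline
severity. Wald 95% CIs (β ± 1.96·SE). A zero cluster variance is reported
with a singular-fit flag, not an error; a constant ΔDWIS column is an
error (no fixed-effect variance). Per-feature raw-value models (value ~
condition, random intercept per subject) back the percent-change analysis
with an absolute-scale check, FDR-corrected across features.

## Sparse-PCA domains and congruence

The domain analysis takes the patients × features optimal-improvement
matrix, column-standardized by default (features live on wildly different
percent scales; a flag disables this to run the unstandardized variant),
and fits 3 sparse components with the ℓ1-penalized dictionary-learning
formulation (scikit-learn SparsePCA, penalty 1.0, fixed random state).
Because sparse components are not orthogonal, explained variance is
computed on QR-orthogonalized projection scores — the standard adjusted
variance for sparse PCA, which never double-counts and reduces to ordinary
PCA's value as the penalty → 0 (at penalty 0 the fit *is* the SVD).
Components are ordered by explained variance and sign-fixed so each
component's largest-magnitude loading is positive.

Tucker's congruence Φ(a, b) = Σaᵢbᵢ / √(Σaᵢ² Σbᵢ²) is reported signed in
the 3 × 3 cross-cohort matrix. The matched diagonal pairs components by
index after each cohort's own variance ordering; an optimal-assignment mode
(maximizing Σ|Φ|) exists for bootstrap alignment and permuted-structure
checks. The global similarity statistic is the mean |Φ| over matched pairs.
The permutation null relabels the features of one cohort: when that
cohort's raw matrix is available its columns are permuted and the sparse
fit recomputed per iteration; given only a loading matrix, its rows are
permuted directly — the ℓ1 fit is equivariant under feature relabeling, so
the refit-free variant is the same null at a fraction of the cost, and it
is what the calibration tests use. p = (1 + #{null ≥ observed}) / (1 +
iterations); fewer than 100 iterations warns of an unstable p.

Loading CIs are patient-level bootstrap percentiles (10,000 resamples);
each refit is aligned to the point estimate by |Φ|-maximal assignment with
sign correction before quantiles are taken, and resamples with too few
distinct patients (or a constant column) are skipped and counted.

## Synthetic cohort

Traces are concatenations of raised-cosine open–close cycles over a
baseline offset. Cycle k of K has amplitude A₀(1 + d_A/100 · (k − (K−1)/2))
and rate f₀(1 + d_f/100 · (k − (K−1)/2)): decrements are linear in cycle
index and *centred on the mean*, so A₀ and f₀ are per-trace means and a
planted d of −5%/cycle is recovered exactly by the %-of-mean decay readout.
Periods receive multiplicative Gaussian jitter (CV configurable) and are
rescaled so the cycles exactly fill the requested duration — a common
rescaling that leaves the planted per-cycle decays and jitter CV unchanged
while avoiding a flat, artifactual tail segment. White Gaussian noise is
added per sample. Defaults emulate a moderately bradykinetic medication-off
recording: 0.5 amplitude, 1.2 Hz, −3%/cycle amplitude decay, −2%/cycle
rate decay, 2% timing jitter, noise SD 0.005, 12 s at 60 Hz.

Sessions apply per-program multiplicative effects to the base trace
parameters. The default session plants one dominant program (+40%
amplitude, +30% frequency, decrement and jitter halved) and draws the
others below it on every axis, so the planted program dominates every
oriented feature and ranking recovery has a well-defined truth. Domain
cohorts are scores × loadingsᵀ + noise with disjoint, seed-randomized
sparse supports (per-column zero fraction 0.65, capped by disjointness at
7 active features per domain) — seed-randomized so that two cohorts with
different seeds are structurally independent, which the permutation-test
calibration requires. Concordance datasets generate a latent improvement
(cluster intercept + β·ΔDWIS + noise) subtracted from a moderate (2–3)
baseline item score, then rounded and clipped to the 0–4 scale; the
operating point keeps scale-end contact rare because censoring at the ends
would attenuate the planted slope, which is the estimand of the recovery
tests. All generators are pure functions of (spec, seed).

What the generator does *not* emulate: tremor superimposed on the aperture
signal (tremor-dominant phenotypes are out of scope), pose-estimation
dropouts and outliers, non-stationary task compliance, or correlated
feature noise beyond the planted low-rank structure. Passing tests
therefore establish the correctness of the computations and their
behaviour under the stated signal model, not robustness to every artifact
of real video kinematics.

## Problem sizes in the test and acceptance runs

The packaged checks use 100 seeded sessions for ranking recovery, 100
replicates × 1,000 permutations for null calibration of the congruence
test, 200 replicates for mixed-model CI coverage, and 2,000 bootstrap
resamples inside the cohort summary of the acceptance script; these sizes
give Monte-Carlo error comfortably below the asserted margins while keeping
a full run in minutes on one CPU. The statistical defaults of the library
itself remain 10,000 bootstrap resamples and 10,000 permutations.

## Known limitations

- The exact identities of a deployed site's 23 features may differ from the
  default catalog; the catalog is data, and all downstream results are
  conditional on it.
- With near-tied programs, DWIS ranks are sensitive to feature noise by
  construction; the separation metrics (Δtop2, Δtop-median) are the honest
  readout of that uncertainty.
- The Wald CIs of the mixed model are slightly anti-conservative at 15
  clusters; observed coverage in the recovery tests runs a point or two
  below nominal.
- The permutation test conditions on the fitted number of components (3)
  and the matched-diagonal pairing; it tests global structural similarity
  under feature relabeling, not any stronger notion of equality of loading
  matrices.
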