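# Methods notes

## Data model and assumptions

The package operates on parcel-resolved data: each run is a time ×
channel matrix in which channels are tagged as `parcel` (gray-matter
parcel averages), `WM`/`CSF` (tissue references), `global` (whole-brain
mean), alongside six motion realignment parameters and a framewise-
displacement (FD) trace. Working at parcel rather than voxel resolution
is mathematically equivalent for every linear denoising operator (the
operators commute with spatial averaging), with one exception — tissue-
mean extraction — which the synthetic generator supplies directly as
reference channels. No imaging formats are read or written; all
interchange is TSV/JSON.

Traits are assumed stable between the two sessions; the generator makes
them exactly stable, so test–retest metrics here isolate measurement and
processing variance, not true trait drift.

## The synthetic cohort generator

Per-subject target connectivity is an analytically known convex mixture
of correlation-scale components:

    C_i(session) = w_g·C_group + w_f·C_family(i) + w_s·C_subject(i)
                   + w_e·C_session(i, session) + w_n·I  (+ planted edges)

with default shares w_s = 0.35 (subject-stable "fingerprint"),
w_f = 0.15 (familial), w_e = 0.15 (session state), w_n = 0.15 (white
noise), w_g the remainder. Each component is a random low-rank factor
model normalized to unit diagonal. Time series are Gaussian with
covariance C_i (Cholesky mixing), so empirical FC converges to the known
target; eigenvalue clipping (floor 1e−4, then diagonal renormalization)
guarantees a valid covariance after planting edges.

Trait-linked edges are planted by adding `γ_e · z_trait` to selected
upper-triangle entries, with γ_e calibrated per edge so that the
cross-subject correlation between the target edge value and the trait
equals the requested effect size exactly (the trait z-score is clipped at
±2.5 for positive-definiteness headroom; empirical FC sampling noise then
attenuates the realized correlation slightly). Confound→FC effects use
the same mechanism.

Latent traits are multivariate normal with a default intercorrelation
matrix emulating the usual questionnaire pattern (Neuroticism
anticorrelated with Conscientiousness/Extraversion/Agreeableness at
−0.41/−0.34/−0.28; those three mutually positive; Openness weakly
related), decomposed into a family component and an individual component
with a familial correlation of 0.3 by default — so sibling trait
correlation equals that coefficient exactly.

Item responses invert sum-scoring: each item's Gaussian propensity is
`sign · 0.6 · trait + N(0, 1)` (sign matching the published reverse-coded
item lists), discretized at equal-probability cut points into {0..4}.
With these defaults Cronbach's α per factor lands in 0.76–0.81 at
n = 884, inside the 0.7–0.9 reliability regime typical of the instrument.

Motion is a scaled random walk whose mean FD matches the subject's
per-run motion summary (lognormal across subjects, median ≈ 0.065 mm);
FD is the sum of absolute backward differences of the translations plus
rotations converted to millimetres on a 50 mm sphere. Optional artifacts
(polynomial drift, FD-coupled signal, rare spikes) contaminate signal
channels; pipeline C is given artifact-free ("FIX-like") input.

**What the generator does not emulate:** hemodynamic autocorrelation
(innovations are white, so FC estimates at a given run length are
somewhat more precise than for real BOLD); physiological noise;
a dominant cross-subject mode of overall FC strength (arousal/vigilance);
spatial structure of parcels; non-Gaussian traits. Passing tests
therefore establish the statistical machinery, not effect sizes that
would transfer to real cohorts.

## Denoising

Operator order follows the three published recipes exactly; an execution
trace is attached to every run and asserted in tests. Notable numerical
choices:

* Butterworth filtering is zero-phase (forward–backward, `sosfiltfilt`),
  to avoid phase distortion of correlations; the recipe's order 1 is
  kept, which doubles to an effective order 2. A first-order band-pass
  has a shallow rolloff: on white-noise input ~17% of power remains
  outside 0.01–0.08 Hz asymptotically (|H|⁴ integral), more at finite
  length due to transients. Tests therefore compare against the bare
  filter's empirical transfer rather than asserting near-total stop-band
  suppression.
* Censored volumes are linearly interpolated before filtering and either
  absorbed by per-volume spike regressors (pipeline B; all volumes
  retained afterwards) or excluded from FC computation (pipeline C).
  Censoring is always a mask, never a deletion.
* The DVARS criterion (ratio 1.05 of run-median differenced-signal
  variance) censors liberally on the generator's white-like signals,
  because cross-parcel DVARS variability scales as √(2/P); this is the
  formula behaving as specified on data less smooth than real BOLD.
* Pipeline A applies its Gaussian low-pass (SD = 1 TR) before two further
  regression steps, which can reintroduce high-frequency content; the
  published order is followed deliberately.
* Nuisance channels are filtered identically to data channels before
  pipeline B's combined regression (the source recipe is silent on this).

## Prediction and evaluation

* Deconfounding is OLS on the training fold only; fitted weights are
  applied to training and test scores. The full confound set is gender,
  age, handedness, brain size, per-session motion, reconstruction
  version, and fluid intelligence (removed from its own confound set when
  it is the prediction target); the minimal set is reconstruction
  version, motion, brain size.
* Edge filtering converts the two-sided p < .01 criterion into the exact
  critical |r| via the t-quantile, which is mathematically identical to
  computing per-edge p-values and thresholding (both paths exist and are
  cross-checked bitwise in tests).
* The elastic net uses L1 ratio 0.01 (nearly ridge), features
  standardized by training mean/SD, and an α grid of 50 geometrically
  spaced values on [10⁻⁴, 1]·α_max, where α_max is the smallest penalty
  zeroing all coefficients. Inner model selection is 3-fold CV stratified
  on equal-count quartile bins of the training scores, minimizing mean
  squared error with ties resolved toward the larger (more regularized)
  α. The grid span/spacing and the standardization are this package's
  choices (unreported in the source recipe) and are logged with every
  fit.
* Metrics use the population (1/n) convention so that nRMSD² + R² = 1
  exactly. The conversion helper `nrmsd_from_r2(r2, n_obs=n)` also offers
  the finite-sample convention √((1−R²)(n−1)/(n−2)) — residuals scaled by
  the residual degrees of freedom of a fitted line against the (n−1)
  sample SD — which is the convention that reproduces published
  (R², nRMSD) triplets to three decimals at n = 884.
* Permutation inference shuffles raw scores uniformly between subjects;
  confounds, edges and the family-based folds stay fixed, and permuted
  scores are deconfounded against the *unpermuted* confounds within each
  fold (the literal "keeping everything else exactly the same"). The
  empirical p is (k+1)/(n_perm+1).

### A calibration caveat worth knowing

When traits and connectomes *both* carry familial components, scores are
not exchangeable under free shuffling — siblings share trait and FC
similarity — and the free-shuffling permutation p-values become
conservative (measurably superuniform in our experiments). The type-I
calibration test therefore uses cohorts with the familial trait
correlation set to zero, where the null is exact. Under kinship
co-structure the test errs on the safe side; this is a property of the
published scheme, not of this implementation.

Relatedly, ordinary leave-one-out CV is optimistic relative to
leave-one-family-out on cohorts with familial trait+FC components (the
bias LOFO exists to prevent); the acceptance battery demonstrates both
phenomena.

### Null-distribution shape

The univariate strength model's permutation null develops a heavier left
tail than the elastic net's as the sample grows (more edges pass the
p < .01 filter under the null, and the selection step reacts
asymmetrically to chance correlations). At n ≲ 120 with desk-scale edge
counts the contrast is within skewness sampling error; the battery
demonstrates it at n = 200 subjects, 60 parcels.

## Problem sizes used in the test battery

Chosen as the smallest scales at which each statistical claim is
informative: filter calibration at 10,000 edges × n = 200 × 50 seeds;
permutation calibration on 50 cohorts of n = 100 (60 parcels, 200
permutations each); planted-signal recovery at n = 400 with a 100-edge
network of effect 0.3 (99/39 permutations for the univariate/elastic-net
families); family-bias comparison over 10 seeds at n = 120 sibling
pairs; fingerprint dial at shares {0.02, 0.05, 0.10} (above ~0.1 the
identification rate saturates at 100% for 300-volume runs); null-shape
contrast at n = 200 with 600/300 permutations. End-to-end pipeline tests
use 600-volume runs so the 0.01–0.08 Hz band retains enough effective
degrees of freedom for stable FC.

## Known limitations

* ICA-FIX itself is not implemented; pipeline C consumes input flagged as
  FIX-like.
* No facet-level NEO scoring, no partial correlations / tangent-space
  connectomes / dynamic FC, no nonlinear prediction models, no
  multiple-comparison correction across analysis cells.
* The per-run motion summary consumed by the inclusion filter is a
  precomputed scalar; the filter does not recompute it from realignment
  parameters.
* `parcellate` (voxel→parcel averaging from a label map) is deliberately
  out of scope; the generator emits parcel-resolved channels directly.
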