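# Methods

`neuraxes` implements an analysis pipeline linking individual differences
in sensorimotor learning to patterns of seed-based functional
connectivity with the hand area of primary motor cortex, together with a
synthetic-cohort generator that plants known ground truth at every
stage.  This note records the models, the parameters that matter, the
numerical choices, and what the synthetic cohorts do and do not emulate.

## Behavioral models

### Visuomotor rotation (VMR) task

Subjects reach to one of 8 targets (45° apart, pseudorandom bins of 8)
while the cursor is rotated 45° clockwise relative to the hand.  All
angles are in degrees, counter-clockwise positive, wrapped to
(−180, 180]; the rotation is therefore −45, the unlearned error is −45,
and full compensation is +45.  The per-subject measures are

* **explicit** learning: circular mean of (reported aim − target) over
  report trials, discarding the first 8 reports and averaging the final
  8 (subjects often misunderstand the reporting procedure at first);
* **implicit** learning: circular mean of (hand direction − reported aim)
  over the same trials;
* **early error** (performance): arithmetic mean of signed cursor errors
  over the first 32 learning trials.  Signed errors are used for
  learning curves (decay from −45 toward 0); absolute errors are used
  only in the reaction-time-bin analysis, which asks about accuracy.

Trial filtering marks too-early starts, timeouts, cursor jumps, trials
above the cross-subject (1 − 0.0005) RT/MT quantile, and trials with
RT < 100 ms.  The RT-bin analysis splits each subject's valid learning
trials at their 20/40/60/80% RT percentiles and computes the Spearman
correlation between per-bin mean RT and per-bin mean |error| (average
ranks on ties; an undefined correlation is reported as 0 with a flag).

### Reward-based path tracing

Subjects trace a visible half-sine path (amplitude 0.15 × the 60 mm
target distance) without cursor feedback and are secretly rewarded for
the mirror-image path.  The displayed point score interpolates the
lateral position at each cm of forward travel, sums absolute deviations
from the mirror path, normalizes by the same sum for a 0.5-amplitude
half-sine, and maps to 100·(1 − ratio), clamped to [0, 100].  This is
the unique reading of the normalization consistent with both anchors: a
perfect mirror trace scores 100 and a perfect visible trace scores 40.

The **lateral movement score** is the mean lateral position over a
uniform grid of forward displacements, sign-flipped so positive points
toward the rewarded side, and expressed in units of the target distance
(dimensionless).  The unit choice matters: the sigmoid priors below are
only scale-consistent with a score of this magnitude (a perfect mirror
trace scores ≈ +0.096, and the prior mean of 0 on the upper asymptote
is then the midpoint between perfect learning and no learning).

### Bayesian sigmoid learning curves

Lateral movement scores across trials are modelled as
y_i ~ Normal(f(x_i), σ²) with

    f(x) = L + (U − L) / (1 + exp(−k (x − m)))

where x is the trial index scaled by 100.  Priors: m ~ N(1.7, 0.5),
L ~ N(−0.2, 0.25), U ~ N(0, 0.25), k ~ N(7, 2), σ ~ half-N(0, 0.25).
The model is fit with an adaptive random-walk Metropolis sampler:
3 chains of 5,000 retained draws, the first 1,500 discarded as burn-in.
The proposal covariance adapts during burn-in only (empirical posterior
covariance scaled by 2.38²/d, with a Robbins–Monro global scale steering
acceptance toward ≈ 0.28) and is frozen afterwards, so retained draws
form a valid Markov chain.  Each retained draw is preceded by 5 proposal
updates — the random-walk analogue of one gradient-based sampling step —
which brings the effective sample size to a level where the split-chain
potential scale reduction factor R̂ (classic Gelman–Rubin on
half-chains, cross-checked against `arviz`) is reliably below 1.01 on
well-behaved data.

Epochs are defined from the posterior-mean curve's quantile crossings,
x_q = m − ln((1 − q)/q)/k: the pre-learning epoch ends at the 2.5%
crossing, the learning epoch starts at the 5% crossing, and the
post-learning epoch starts at the 97.5% crossing (a 95% figure-caption
variant exists in the literature for the last boundary; 97.5% is the
default and both are accepted via configuration).  Windows of 100
imaging volumes are laid out at 3 volumes per trial (configurable; the
TR-to-trial correspondence is approximate) and clipped to the scan
extent with a warning.  Near-flat fits (|U − L| below 0.05) are flagged,
not errored — such subjects are recorded as having extremely low
learning rates.  The learning rate is the posterior mean of k, except
for subjects flagged for fallback segmentation, where it is the
least-squares slope of scores over the learning epoch (score units per
trial).

## Covariance geometry

Epoch covariances (100 volumes × p regions) are estimated with the
Ledoit–Wolf shrinkage estimator, implemented directly from the optimal
shrinkage-toward-scaled-identity formulas (and tested for exact
agreement with scikit-learn's independent implementation).  Shrinkage
keeps estimates strictly positive definite even when p exceeds the
number of volumes.

Static subject-level covariance differences dominate task-related
modulation, so covariances are centered on the SPD manifold under the
affine-invariant metric: each subject's epoch covariance is projected
onto the tangent space at the subject's Karcher mean,
computed within each task's scanning session (the two tasks were
acquired in separate sessions; a joint subject mean would let one
task's connectivity modulation bleed into the other task's centered
readout),
T = S̄ᵢ^{1/2} log(S̄ᵢ^{−1/2} S S̄ᵢ^{−1/2}) S̄ᵢ^{1/2}, then
parallel-transported to the grand Karcher mean via G T Gᵀ with
G = S̄^{1/2} S̄ᵢ^{−1/2}.  Karcher means use the standard fixed-point
iteration (step size 1, tolerance 1e-8 on the Frobenius norm of the mean
tangent residual, at most 100 iterations; matrix functions via
eigendecomposition, batched across matrices).  Seed connectivity is read
out post-centering as the mean of the tangent matrix's seed rows against
each non-seed region (the averaged-seed-signal variant, computed before
covariance estimation, is not the default).

## Neural axes

For each behavioral outcome, a ridge regression of the (standardized)
outcome on subjects' (standardized) seed-connectivity profiles is fit
with a separate penalty multiplier per brain network.  The explicit and
implicit axes residualize both the outcome and every predictor column on
early error first (removing performance-related variance); the
performance axis uses sign-inverted early error with no residualization.
Penalties are λ₀·multiplier(network); λ₀ and the multipliers
(initialized at 1) are tuned by alternating passes (10 outer iterations)
over a 25-point log-spaced multiplier grid on [1e−3, 1e3] and a global
grid for λ₀, minimizing the closed-form leave-one-out (LOO) error
(computed in the dual n×n form when p > n).  Selection uses a
one-standard-error rule: candidates whose LOO error is within one
standard error of the minimum count as ties, and ties resolve toward
stronger shrinkage.  Without this rule the alternating search visits
enough candidates to overfit the LOO criterion itself, producing
spuriously positive cross-validated R² on signal-free data; with it,
null cohorts yield cv R² near or below zero while planted signals are
still recovered.  cv R² = 1 − SS_LOO/SS_tot at the final penalties; like
the analogous internally-tuned procedures in the literature it is still
an in-sample-tuned quantity, not a nested cross-validation estimate.

Axis **expression** in a new connectivity profile is the Pearson
correlation with the axis's coefficient vector (zero-variance inputs
score 0 with a flag).  The **explicit-alignment** summary axis is
rank(β_explicit) − rank(β_implicit) per region with average ranks on
ties.  Cross-task coupling is the Pearson correlation between
learning-epoch expression scores and reward-task learning rates, with
t = r√((n−2)/(1−r²)) and a two-sided p from the t distribution on n−2
degrees of freedom.

## Spatial nulls

The correlation between two parcel maps is tested against a
spin-permutation null that preserves spatial autocorrelation: each
permutation draws one uniform random 3-D rotation, applies it to
left-hemisphere parcel centroids on the unit sphere and the x-mirrored
rotation to the right hemisphere, reassigns each parcel the value of its
nearest rotated neighbour (duplicates permitted), and recomputes the
correlation.  The two-tailed p-value uses the +1 permutation correction,
p = (1 + #{|null| ≥ |obs|})/(1 + n_perm), with 1,000 permutations by
default.  On signal-free maps the empirical type-I error at α = 0.05
calibrates within [0.02, 0.09].  Variogram-matching surrogates and
vertex-level spins are out of scope.

## Synthetic cohorts

The generator (`neuraxes.synth`) realizes a 36-subject, 120-region
cohort by default, with 4 seed regions standing in for the contralateral
hand area and the remaining regions split into 8 named networks.

* **Behavior.** Per-subject explicit and implicit angles, early errors,
  and sigmoid parameters are drawn from configurable cohort
  distributions (defaults: explicit ~ N(20, 12)°, implicit ~ N(12, 6)°,
  early error ~ N(−25, 8)°, k ~ N(7, 2) truncated at 0.5, residual score
  SD 0.05, motor noise 3°).  VMR compensation follows an exponential
  approach whose time constant is solved so the noise-free mean error
  over the first 32 learning trials equals the planted early error;
  targets outside the feasible range (−45, explicit+implicit−45) are
  clipped and the realized value recorded as truth.  This clipping
  induces a correlation between early error and total adaptation —
  behaviorally realistic (better learners make smaller errors) and the
  reason the axis construction residualizes on error.  Reward-task
  trajectories are half-sine paths whose amplitudes reproduce the
  sigmoid-plus-noise lateral scores exactly.
* **Timecourses.** Each subject draws a correlation-like base covariance
  (Wishart with 3p degrees of freedom, rescaled to unit diagonal, plus
  0.2²·I observation noise) shared across that subject's epochs —
  the static subject-level differences the centering must remove.  The
  VMR early-learning epoch adds increments to the seed rows equal to a
  per-region effect map times the z-scored covariates; the reward-task
  learning epoch adds the explicit effect pattern times the z-scored
  true learning rate, planting the cross-task coupling.  The default
  effect map places each covariate on a disjoint 8-region set (one
  network each), graded hub-style within the set (base 0.12 covariance
  units, tapering 1.6→0.6) — real network involvement is graded, not
  uniform, and the gradient gives attribution tests a well-defined
  strongest region.  Increments that would break positive definiteness
  are damped by the smallest factor restoring a positive-definite
  margin, with a warning (minimal damping preserves the planted linear
  relation as far as possible).  Samples are multivariate normal;
  volumes are exchangeable within an epoch.

The effect scale keeps increments within the near-linear regime of the
tangent map: much larger effects mix covariates into non-planted
regions through the map's curvature and trigger frequent
positive-definiteness damping.  Even so, the generative noise level is
optimistic relative to real fMRI, and cross-validated R² values on
synthetic cohorts run higher than is typical of real data.

What the generator does **not** emulate: hemodynamics and temporal
autocorrelation, head motion and physiological artifacts, spatial maps
or volumes (parcel centroids are abstract points on a sphere),
non-Gaussian noise, and report-trial response biases.  Passing recovery
tests therefore demonstrate the correctness and statistical calibration
of the estimators under the stated generative model, not robustness to
fMRI artifacts.

## Numerical choices and degenerate inputs

* Angles wrap to (−180, 180]; a circular mean with resultant below
  1e-12 is an error ("undefined mean direction").
* Matrix functions reject eigenvalues ≤ 1e-12 (a non-PD input signals
  upstream failure); symmetry is enforced to 1e-10 and outputs are
  re-symmetrized.
* Ledoit–Wolf with a constant column applies a small deterministic
  jitter with a warning.
* Ridge solves fall back to a penalty floor if singular; a
  zero-variance covariate in residualization returns the demeaned
  outcome with a warning.
* Tied RT quantiles merge the affected bins with a warning.
* All randomness flows from a single master seed split per stage
  (`numpy.random.SeedSequence`); identical configuration and seed give
  byte-identical pipeline outputs.

## Problem sizes

Default analyses use 36 subjects, 120 regions, 100-volume epochs, 200
VMR trials and 270 reward trials per subject; recovery claims in the
test suite are evaluated over 50 independently seeded replicates of the
full pipeline, and spin-test calibration over 200 null runs of 1,000
permutations on 100 parcels.

## Known limitations

* The group-ridge tuning procedure is a specified alternative to the
  GRridge empirical-Bayes algorithm, matching its contract
  (network-level penalties tuned by internal LOO) but not its internals.
* cv R² is tuned and reported on the same LOO residuals (mitigated, not
  eliminated, by the one-standard-error rule).
* The spin test implements the classic centroid-rotation variant;
  other null variants (vertex resampling, variogram matching) can give
  different p-values on real data.
* The sampler is a random-walk method; heavily multimodal posteriors
  (not expected for this model) would require a different sampler.
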