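# Methods

## Model

The package models preprocessed mouse-tracking data: per subject i and
trial j, a sequence of movement angles y_{ij,0:N} in [0, pi], obtained by
rescaling the raw cursor path to [-1, 1] x [0, 1], resampling it to N + 1
equally spaced points over the recorded sample index, and applying the
four-quadrant inverse tangent.  The generative model is

* a latent AR(1) Gaussian walk per subject, z_{i,n} = z_{i,n-1} +
  sigma_i eps, shared across that subject's trials, with a N(z0_mean,
  z0_var) prior on z_{i,0};
* a two-component von Mises mixture for each angle, with fixed component
  directions mu_1 (distractor side) and mu_2 (target side) and estimated
  concentrations kappa_1, kappa_2;
* a logistic link pi_{ijn} = (1 + exp(-beta_j - z_{i,n}))^(-1) giving the
  probability that the angle comes from the distractor component;
* the stimuli equation beta_j = sum_k d_jk gamma_k + x_j (eta + sum_k
  d_jk delta_k), a linear predictor over the categorical factor (K
  levels), a continuous covariate, and their interaction, with delta_1 =
  0 for identifiability.

Parameters estimated: gamma (K), eta, delta_2..delta_K, kappa_1, kappa_2.
Fixed quantities and defaults: mu_1 = 3pi/4 and mu_2 = pi/4 (the screen-
corner geometry), sigma_i = 1, z_{i,0} ~ N(0, 1).  Concentrations are
handled on the log scale throughout inference so their positivity needs
no boundary treatment.

### Conventions and degenerate inputs

* Angles are folded into [0, pi] by absolute value, |atan2(y, x)|: small
  downward excursions reflect upward, preserving the left/right
  (distractor/target) information the mixture models.  The simulator
  folds identically, keeping generator and likelihood consistent.
* The degenerate start pair (0, 0) gets the neutral angle pi/2.
* The complete-data density counts each subject's latent-path prior once
  (the path is shared across trials); a compatibility flag restores the
  literal per-trial counting of the factorized form.  The measurement
  term includes step 0, matching the filter, which updates at every step.
* The logistic link is implemented literally (pi increases with beta +
  z); a `sign_convention=-1` switch mirrors it for analyses that read pi
  as decreasing in beta + z.  Inference always uses the literal form;
  the switch affects reporting functions only.

## Filtering

The per-subject marginal likelihood f(Y_i | Theta) and latent-path
moments come from a recursive Gaussian approximation filter.  Each step
performs the standard predict stage (m, P) -> (m, P + sigma^2) and then
closes the non-Gaussian update in the Gaussian family:

* **Moment matching (default).**  The pooled measurement log-likelihood
  of all trials at step n is evaluated on a 21-node Gauss–Hermite grid
  centered on the predictive Gaussian; normalizing those weights yields
  the exact (to quadrature) posterior mean and variance, which define the
  next Gaussian, and the same quadrature gives the marginal-likelihood
  increment.  This is assumed-density filtering; it makes the
  approximate likelihood smooth in Theta, which the surrounding MCMC
  requires.
* **Mode matching (option `method="mode"`).**  A Laplace-style update:
  safeguarded Newton maximization of the step's log-posterior (tolerance
  1e-8, at most 50 iterations, step halving, 401-point grid fallback on
  non-concavity) with curvature-based variance, floored at 1e-10.

Both closures coincide when the measurement carries no information about
the state (identical mixture components), where the filter reproduces
the prior recursion P_n = z0_var + n sigma^2 exactly.  On informative
data, moment matching tracks a 100,000-particle bootstrap particle
filter roughly an order of magnitude more closely than the mode update
(per-subject gaps of order 0.01–0.2 nats vs. 1–3 nats at kappa ~ 20–50),
which is why it is the default.  The residual gap is the price of the
Gaussian closure itself: it grows with the concentrations and with the
length of the series, and quadrature refinement does not reduce it.  The
bootstrap particle filter (systematic resampling, unbiased likelihood
estimator, delta-method standard error) is kept as an independent oracle
and is never used inside inference.

Smoothing is the standard backward Rauch–Tung–Striebel recursion on the
stored predictive and filtered moments.

## Inference

The sampler is marginal Metropolis–Hastings on the working-scale vector
(gamma, eta, delta_2.., log kappa_1, log kappa_2), with the latent paths
integrated out by the filter and independent N(0, 25) priors on every
working coordinate.  Study-scale defaults: 20 chains x 10,000 iterations,
burn-in 2,500, adaptation interval H = 25; all scalable via
`InferenceConfig`.

* **Starting values** maximize the static mixture likelihood (latent
  state pinned at 0), multi-started; the initial proposal covariance is
  the regularized inverse negative Hessian of that static likelihood,
  tempered with the prior precision (Sigma_0 <- (Sigma_0^-1 + I /
  prior_var)^-1).  The tempering matters when the likelihood is flat in
  some direction — e.g. with the concentrations pinned near zero — where
  a bare eigenvalue floor would blow the proposal up by orders of
  magnitude and freeze the chains; the posterior is never flatter than
  the prior, so the prior curvature is the correct fallback.
* **The gamma-level ridge.**  Adding a constant c to every gamma_k while
  shifting all latent paths by -c changes the likelihood only through
  the z_0 prior, so the common level of gamma is pinned weakly, with
  posterior variance ~ z0_var / I.  Three consequences are handled
  explicitly: (i) the static optimum is offset along this ridge whenever
  the latent walk wanders, so initialization finishes with a two-stage
  grid line search of the filter likelihood along the level direction;
  (ii) the static Hessian is blind to the ridge, so the analytic level
  variance z0_var / I is added to the initial proposal covariance; and
  (iii) every fourth proposal is a dedicated scalar random-walk step
  along the level direction with sd 2.4 sqrt(z0_var / I), keeping the
  slow direction mixing whatever the adapted covariance looks like.
* **Adaptation.**  During burn-in a Robbins–Monro step tunes a global
  proposal scale toward 0.234 acceptance every H iterations, and — once
  the history holds at least 150 d iterations — the proposal covariance
  (2.38^2 / d) Sigma is re-estimated from the second half of the history.
  The gate matters: a d-dimensional covariance estimated from a few
  hundred autocorrelated transient samples is strictly worse than the
  analytic starting Sigma (in side-by-side runs it raised the worst
  R-hat from 1.02 to 2.1), while scale-only adaptation already
  calibrates the step size; study-scale burn-ins clear the gate and get
  the full re-estimation.  All adaptation freezes at the end of burn-in
  so the kept draws target a fixed kernel.
* A filter failure at a proposal rejects the proposal with a logged
  warning; chains are seeded independently from the master seed and runs
  are bit-reproducible.

Diagnostics: classic (non-split) Gelman–Rubin R-hat per parameter, with
R-hat = 1 by convention for degenerate constant chains, plus effective
sample size (arviz).  The posterior table reports q0.05, mean, q0.975 and
R-hat on the natural scale (kappa back-transformed); note the asymmetric
interval spans 92.5% probability — it is reproduced as the conventional
reporting layout for this model.  Latent-path point estimates are the
posterior mean of smoothed means over kept draws thinned by 10.

## Synthetic data

The generator is the model run forwards, so closure tests are exact in
distribution.  The default scenario emulates a lexical-decision-style
study: I = 22 subjects, J = 72 trials balanced over K = 3 stimulus-type
levels (24 each), N = 101 normalized time steps, a standard-normal
per-trial covariate, components at the screen corners with kappa = (20,
45), and design coefficients gamma = (0.34, 1.30, 1.31), eta = 0.40,
delta = (0, -0.385, -0.336) — magnitudes typical of published fits of
this model family.  Dimension overrides keep the structure, so
scaled-down instances are the same study in miniature.

A subtlety worth knowing: simulated angles are folded into [0, pi] by
absolute value, exactly as preprocessing folds observed trajectories,
but the likelihood is the *unfolded* mixture on the circle.  At the
concentrated component directions the model is built for (kappa of
order 10 and above) the folded mass is negligible and the two agree; at
diffuse concentrations they do not, and folded near-uniform data would
be attributed to moderate spurious concentration.  For that reason
`simulate_angles(..., fold=False)` draws from the exact model density on
the full circle — this is what the simulation-based calibration tests
use, since calibration is only meaningful when the generator *is* the
model — while the fold remains the default for study-like data.

What the generator does *not* emulate: anticipatory sub-movements, pauses and
re-entries, trial-to-trial carry-over, device sampling jitter, or
subject-specific sigma_i; passing tests therefore certify the
implementation against its own model class, not robustness to real-data
violations of it.

## Evaluation

* **Posterior predictive fit.**  M parameter vectors (default 5,000) are
  drawn with replacement from the kept draws; each simulates a replicate
  dataset.  Observed and replicate angles are binned into 36 equal cells
  on [0, pi]; the index is 100 (1 - 0.5 L1-distance) between the
  observed histogram and the replicate average — 100% iff identical,
  0% iff disjoint.  The *overall* index uses replicates with fresh
  latent paths from the AR(1) prior and asks whether the fitted model
  reproduces the experiment's pooled angle distribution.  The
  *by-subject* index asks whether the model reproduces a given subject's
  angles conditional on that subject's inferred dynamics, so its
  replicate paths are drawn from the subject's smoothed posterior
  marginals at the posterior-mean parameters (for a pooled histogram
  only the per-step marginals matter).  With fresh prior paths instead,
  the by-subject index saturates near 66% even for the true model at
  full study size — it would measure latent-path variability rather than
  misfit — which is why the subject-conditional form is used.
* **Attraction curves** evaluate the logistic link at posterior-mean
  beta per factor level (and at the minimum / median / maximum of the
  covariate when active) over a latent grid; **p_Delta** is the plain
  mean of an attraction curve over an inclusive window of step indices
  (e.g. the 30–50% span of process time).
* **Profile clustering** groups subjects by Ward-linkage agglomerative
  clustering on the Euclidean distance between smoothed-mean latent
  paths (optionally pre-smoothed by a 5-point moving average);
  `k="auto"` scans 2..min(8, I-1) and keeps the silhouette maximizer;
  identical profiles degenerate to one cluster with a warning.

## Problem sizes used by the test suite

The acceptance-style tests run the full machinery at sizes chosen to
exercise every property in minutes on one CPU: oracle equivalence on 20
random 2 x 4 x 50 instances against 100,000 particles; recovery on a 10
x 36 x 101 study with 4 chains x 2,000 iterations; calibration over 20
prior-predictive replications at 5 x 12 x 51 with 2 x 1,200; prior
recovery on 4,000 thinned kept draws; predictive closure at 8 x 18 x 51
with M = 500.  The same structure at full study scale is available by
changing `InferenceConfig` and scenario dimensions.

## Known limitations

* The filter is an approximation; its likelihood error (though
  validated against the particle oracle) is not propagated into
  posterior uncertainty, so credible intervals inherit a small,
  unquantified approximation bias, most visible at large kappa.
* The common level of gamma is identified only through the initial-state
  prior; analyses should interpret level contrasts (gamma_k - gamma_k')
  rather than absolute levels.
* Univariate latent state; one factor plus one covariate; logistic link
  with unit slope in z.  Multivariate states, richer designs, and free
  link slopes are out of scope.
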