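# Methods

`riskscape` implements a joint top-down/bottom-up analysis of mesopredator
movement for an Arctic predator–prey system: a top predator (polar bear)
whose daily habitat selection defines a predation-risk landscape, and a
mesopredator (ringed seal) whose habitat selection, movement persistence and
diving behaviour respond to that risk, to prey availability, and to the
physical environment (sea ice, bathymetry).  Every stage is a model object
fitted to data (`Model(...).fit() -> Results`), and every stage has a
generative counterpart in `riskscape.synthetic`, so the whole pipeline can
be validated by parameter recovery with no field data.

## Track state-space model

Raw satellite (Argos-class) locations are irregular and noisy.  The latent
movement model is a continuous-time correlated random walk: per planar
coordinate, velocity follows an Ornstein–Uhlenbeck process
`dv = -beta v dt + sigma dW` and position integrates velocity.  The two
coordinates are independent and share `(beta, sigma)`, so one covariance
recursion serves both.  Transition moments over an arbitrary gap are exact,
giving the exact marginal likelihood through a Kalman filter over the
4-dimensional state.  Observation error is Gaussian with class-specific
SDs (defaults 3: 0.25, 2: 0.5, 1: 1.5, 0: 4, A: 6, B: 10 km — conventional
values, configurable), optionally scaled by one estimated multiplier.

Before fitting, tracks are cut wherever transmission halted for more than
12 h, and segments shorter than 100 locations are discarded; both
thresholds are arguments.  Fitting maximises the likelihood over
log-parameters (L-BFGS with restarts).  The position prior at the first
observation is centred on that observation with a 50-km SD; the velocity
prior is the stationary OU distribution.  Smoothing (RTS) yields regular
2-h predictions anchored at each segment's first observation
(`floor(span/step) + 1` points); one-step-ahead standardised innovations
are the goodness-of-fit diagnostic (the first observation is excluded
because the prior is centred on it); and a forward-filter backward-sampling
pass draws joint posterior tracks used for location-error propagation.
Near-zero gaps can make the exact transition variance negative by
floating-point cancellation; it is clamped at zero.

## Predator-risk landscape

Predator use is contrasted with availability (uniform over water cells and
uniform over study days) in a logistic regression over sea-ice
concentration, bathymetry and distance to coast, fitted with an L1 penalty
on z-scored covariates.  The penalty weight is chosen by K-fold
cross-validated deviance with folds blocked by bear (available rows are
spread randomly across folds); the 1-SE rule is optional.  `lambda_max`,
the smallest penalty that zeroes all coefficients, comes from the KKT
condition `max |X'(y - ybar)| / n`.  Daily risk rasters are the
exponentiated linear predictor min–max normalised to [0, 1] over water
nodes (land set to 0, degenerate surfaces to 0.5); normalisation is
per-day, so within-day ranking is unaffected by it.

## Mesopredator habitat selection

Predicted locations are thinned to one per seal per UTC day; availability
is 25 uniform points per used point from the minimum convex polygon of all
seal locations buffered 30 km and clipped to water.  Because the used
process is normalised over the whole study window, availability timestamps
are uniform over study days.  The model is a plain logistic GLM
(used/available), bathymetry in every candidate.  The candidate set is the
7 non-empty combinations of {ice, prey, risk}, plus prey×risk with and
without ice (9 models), plus a null — ranked by
`AICc = -2 logLik + 2k + 2k(k+1)/(n-k-1)` with `n` the total row count,
applying the parsimony rule (smallest model within 2 ΔAICc wins).
Covariate z-scoring is available and stored with the fit; AICc differences
are invariant to it.

Leave-one-individual-out validation refits on all other seals, scores the
held-out seal's used points and the availability sample on the link scale
(the natural "prediction" of a logistic GLM; even-increment bins of the
exponentiated intensity collapse under skew), cuts the realised score
range into ten even-increment bins, and correlates bin rank with the
area-adjusted frequency (used share / available share) by Spearman rank.
Location error is propagated by rerunning thin → match → availability →
fit on each posterior track draw; thinning and availability sampling reuse
one seed across draws so the spread of coefficients reflects location
uncertainty alone (with error-free tracks all draws coincide and the CI
width is exactly zero).

## Move persistence

Displacements of the regular 2-h predicted track follow
`d_t = gamma_t d_{t-1} + e_t` with isotropic Gaussian noise and
`logit(gamma_t) = x_t' beta + b_i`, `b_i ~ N(0, sigma_b^2)` per seal.
Covariates are first-order only (interactions are rejected by contract).
The random intercept is integrated out by a Laplace approximation whose
inner mode is found by damped Newton with analytic first and second
derivatives; covariate columns are z-scored internally for optimiser
conditioning and coefficients are reported on the original scale.
Transitions never cross segment boundaries.  The behaviour summary splits
risk into equal-count bins and tabulates fitted gamma classes (default
breaks: tertiles of fitted gamma) per bin.

## Dive models

Transmitted dive summaries carry duration, maximum depth and five
intermediate (depth, %-elapsed) points.  Ascent speed is the last
intermediate depth divided by the time from that point to surfacing (the
maximum-depth variant is switchable); rows whose last point sits at 100%
have no ascent interval and are dropped.  Dive frequency is dives per seal
per UTC day, with tracked no-dive days entered as zero.  Rows are thinned
to every 10th dive per seal (first retained index = k, 1-based).  Each
response is a Gaussian LMM with per-seal covariance
`sigma_b^2 J + sigma_e^2 R(phi)`, `R` AR1 over the thinned sequence order.
The likelihood is computed exactly in O(n) per seal via the analytic
tridiagonal inverse of R and a Woodbury rank-one update, with fixed
effects profiled by GLS; ML is the default criterion (REML available).
Candidate sets and ranking mirror the habitat-selection stage, with dive
depth as a fixed effect everywhere, including the null.  Dive frequency is
modelled as a Gaussian LMM for comparability across responses even though
it is a count.

## Synthetic world

The generator emulates the study system on a 600×600-km planar grid
(10-km cells) with a sinuous western coastline: bathymetry increases
smoothly away from shore; daily ice concentration follows a freeze-up
trajectory (~30% to ~95% over 90 days) plus spatially correlated noise
(Gaussian-kernel fields; correlation at lag h is `exp(-h^2/(4 sigma^2))`);
annual prey biomass is log-Gaussian per species on a coarse 50-km grid,
from which Gini–Simpson diversity (`1 - sum p_i^2`) is derived.
Observation gaps are exponential (mean 1.3 h) with a 2% chance of an
inserted >12-h gap.

Used points (predator and seal) are drawn by rejection sampling of
(day, location) pairs jointly, with density proportional to
`exp(x'beta)` evaluated through the same bilinear interpolation the
matching stage uses — so the pooled used/available logistic model
downstream is exactly well-specified and recovery tests are sharp.
Sampling locations per day with fixed counts would condition out the
seasonal part of the signal that a single-intercept RSF estimates, which
is why the day marginal is sampled jointly.

Default truth values are chosen once to give a realistic, identifiable
system: predator coefficients (ice +0.015 %^-1, bathymetry -0.003 m^-1,
distance-to-coast -0.004 km^-1) spread the normalised daily risk surface
broadly over [0, 1] rather than collapsing it onto a few hotspot cells;
seal coefficients (bathymetry -0.008, ice +0.025, prey +2, risk -4,
prey×risk +8) put the system in the "hazardous duty pay" regime in which
risk tolerance reverses sign across the realised prey-diversity range
(~0.1–0.6) — the qualitative pattern this model family exists to detect.
Persistence truth raises gamma with risk (logit slope +2, individual SD
0.3); dive-duration truth carries the crossing interaction (prey -40,
risk -60, prey×risk +120 s) with AR1 phi = 0.4, sigma_b = 20 s,
sigma_e = 30 s.  Dive profiles are constructed so the derived ascent speed
reproduces the generated one exactly; positivity of dive metrics is
enforced by resampling innovations, not truncation.

What the generator does not emulate: tag duty-cycling and transmission
physics, behaviourally coupled predator–prey pursuit, ice drift and
mechanistic ice physics, tidal or diel structure in diving, and
non-Gaussian (t-distributed) Argos error.  Passing recovery tests
therefore demonstrate correctness of the estimators under their own
assumptions, not robustness to every field artefact.

## Validation experiment sizes

The recovery experiments (in `riskscape.validation`, shared by the test
suite and `scripts/acceptance.py`) use: 200 short segments for the
state-space likelihood oracle; 50 tracks × ~500 observations for
denoising/recovery; 60 worlds of 26 seals × 90 days for coefficient
coverage; 60 interaction-truth and 400 null-truth worlds of 13 seals × 45
days for model-selection operating characteristics (the null rate sits
near its margin, so it gets the largest replicate count); one 26×90 world
for the Boyce experiment (plus 100 score permutations); 40 posterior
draws × 3 error levels for propagation; 80 replicates of 26 seals × 200
dives for the AR1 model (REML, since the variance components are the
recovery target); and 40 replicates of 20 seals × 300 steps for move
persistence.  These sizes keep each experiment's Monte-Carlo error small
relative to its margin while remaining desk-scale.

Two recovery quantities sit at known statistical limits under these
conditions and are worth stating plainly: the CTCRW reversion rate has a
median relative sampling error near 15% at 500 fixes under the default
Argos error mix (it is unbiased; the spread is the information content of
the data), and the dive random-intercept SD cannot beat a ~10% median
relative error with 26 seals regardless of estimator (its precision is
governed by the number of individuals, not the number of dives).  The
null-model selection rate across the 9-candidate set has an expected
value of ~0.85 from chi-square multiplicity alone.

## Numerical notes and limitations

- The Kalman core is JIT-compiled (numba); covariances are propagated in
  scalar 2×2 form, and smoother/backward-sampler inversions guard tiny
  determinants.
- CTCRW innovations variances are floored at 1e-12 to survive the
  zero-noise limits used in contract tests.
- The move-persistence Laplace approximation is exact only as the per-seal
  information grows; with very short tracks sigma_b is weakly identified
  and is reported near its boundary rather than truncated.
- AR1 LMM AICc counts k = p + 3 (fixed effects + phi + two variance
  components); move-persistence counts k = p + 2.
- Used/available AICc treats n as the total row count — the only
  self-consistent choice for a logistic fit, though the "sample size" of a
  used/available design is a known conceptual wrinkle.
- The LASSO stage relies on scikit-learn's saga solver with a fixed sweep
  seed; coefficients below 1e-10 are reported as exact zeros (KKT-level
  truncation).
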