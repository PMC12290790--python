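# Methods

This note documents the models, the inference machinery, the synthetic
data generator, and the numerical choices behind `hierpet`, in the order a
reader would meet them in the pipeline.

## Kinetic forward models

**Two-tissue compartment model (2TCM).** Regional tissue activity is

    C_T(t) = [phi_1 e^{-alpha_1 t} + phi_2 e^{-alpha_2 t}] * C_p(t)

with `*` denoting convolution with the metabolite-corrected arterial
plasma curve `C_p`; `alpha_{1,2} = (s ∓ sqrt(s^2 - 4 k2 k4))/2`,
`s = k2+k3+k4`, `phi_1 = K1 (k3+k4-alpha_1)/(alpha_2-alpha_1)`,
`phi_2 = K1 (alpha_2-k3-k4)/(alpha_2-alpha_1)`.  The measured signal adds
a vascular term: `C(t) = (1-vB) C_T(t) + vB C_wb(t)`.  Whole plasma stands
in for whole blood in `C_wb` (whole blood was not part of the emulated
acquisition), and is never scaled by the plasma-free fraction fP even when
the input is.  Binding outcomes: `BP_ND = k3/k4`, `V_ND = K1/k2`,
`BP_P = BP_ND V_ND`, `V_T = V_ND + BP_P`, `BP_F = BP_P / fP`.

**SRTM.** `C(t) = R1 C_r(t) + (k2 - R1 k2a) [C_r * e^{-k2a t}](t)` with
`k2 = R1 k2'`, `k2a = k2/(1+BP_ND)`; no blood data required.

**Frame predictions are time averages.** The model value reported for a
frame is the average of the continuous solution over the frame, not a
midpoint sample: early frames are 20 s long and the activity peak moves
through them.  Input curves are piecewise linear on a dense knot grid;
for such inputs both the exponential convolution and its running time
integral have closed forms per segment (series expansions guard small
`alpha h`), so frame averages carry no quadrature error beyond the
piecewise-linear representation of the input itself.  Against adaptive
ODE integration of the state equations the frame predictions agree to
~1e-9 relative; the acceptance suite checks 1e-6 over 50 random
parameter sets.

**Decay and weights.** Stored TACs are decay-corrected to injection time.
The weighted-NLS frame weights follow the convention
`w_i = sqrt(duration_i x activity_i^{uncorrected})` with carbon-11
half-life 20.364 min used to un-correct internally; weights are
normalized to mean 1 per TAC, negative frame values are floored at zero
before the square root, and an all-zero TAC falls back to uniform weights
with a warning.  The printed frame schedule of the emulated protocol —
20 frames over 110 min — is implemented as 3x20 s, 3x1, 3x2, 2x5,
9x10 min (the only reading of the schedule that sums to 110 min over 20
frames).

## Conventional NLS quantification

Each TAC is fitted independently by weighted nonlinear least squares on
the natural-log scale of the parameters, in three 2TCM parameterizations
(`bpnd`: log K1, log V_ND, log BP_ND, log k4, log vB; `bpp`: BP_P in
place of BP_ND; `bpf`: input scaled by fP, so K1/fP, V_ND/fP, BP_F) and
for SRTM (log R1, log k2', log BP_ND).  V_ND is unconstrained across
regions.  Bounds keep rates positive and plausible (upper bounds leave
headroom for the fP-scaled parameterization, whose natural values are
10-30x larger); starting values come from a crude graphical prefit
(integral ratio for V_T) plus jittered multi-start (default 5 starts;
ties broken by residual sum of squares, then by the smaller binding
value).  Starting values and bounds are package choices, not published
constants.

For SRTM fitting, the `R1 C_r` delivery term uses the observed reference
frame values directly (they already *are* frame averages), and only the
convolution term goes through a continuous interpolant of the reference.
This makes a target identical to its reference fit exactly by
`R1 = 1, BP_ND = 0`, which is the behaviour one wants from the estimator.

## The hierarchical multivariate models

Both hierarchical analyses share one multilevel structure for the vector
of log kinetic parameters of each TAC:

    theta[t] = mu + beta age/sex + gamma (group x region, BP only)
             + u_region[r] + u_indiv[i] + u_tac[t]

* Fixed effects: age (centred, per decade) and sex on log K1 and
  log V_ND (log k2' for SRTM parameters) and on log BP; a group-by-region
  interaction on log BP only, with no overall group term, so each
  coefficient is that region's group difference against the reference
  (healthy volunteer) group.
* Random deviations for region, individual and TAC on every parameter.
  Individual-level deviations are correlated across all parameters
  through a full correlation matrix (tanh canonical-partial-correlation
  Cholesky parameterization); region and TAC deviations are independent
  across parameters.
* Priors: global intercepts Normal(pooled-NLS centre, 0.5) — the centres
  are computed from a handful of conventional fits of the same data at
  build time, overridable; covariate effects Normal(0, 0.3); each
  group-contrast coefficient Normal(0, 0.2) on the log scale (64% prior
  mass on differences below 20%, 81% below 30%, 9% one-sided above
  +30%); half-normal SD priors with scale 0.3 (K1/V_ND/BP-like) or 0.2
  (k4/vB/k2'-like) per level; Normal(0, 0.5) on the unconstrained
  partial-correlation coordinates (a weakly regularising, LKJ-like
  choice); random projection slopes (below) half-normal(0.1).

**Simultaneous TAC-level model.** The likelihood is the 2TCM frame
prediction of every TAC given its composed parameters.  Residuals are
Student-t with degrees of freedom estimated above a floor of 3; the
per-frame scale is `exp(ls0 + delta_t) x A_t / w_frame`, i.e. a global
log-scale plus a per-TAC log-normal deviation, normalized by the TAC's
mean absolute activity `A_t` and divided by the conventional frame
weights — the same heteroscedasticity model the weights encode for NLS.
TAC-level deviations are uncorrelated across parameters (the original
reports do not state whether they were correlated; uncorrelated is the
simpler choice and the residual covariance can absorb the remainder).

**Parameter-level model.** For SRTM the reference-tissue functionality is
analysed in two stages: conventional NLS vectors (log R1, log k2',
log BP_ND) per subject x region become a multivariate-normal response
with the same multilevel structure; the TAC-level deviation *is* the
residual, with a full 3x3 covariance (Cholesky-parameterized).
Estimation uncertainty of the NLS inputs is not propagated — estimates
are data.  This is the standard limitation of two-stage multivariate
analysis and is visible as slight over-dispersion absorbed into the
residual covariance.

**Raphe-versus-projection contrast.** A refit with a different contrast
design: per non-reference group, one coefficient for the raphe and one
for the mean of the serotonin projection regions, plus random slopes
(shared SD) letting each projection region's difference vary around the
mean.  Reported: `P[beta_RN - beta_proj > 0]`, both contrasts, and the
posterior of the slope SD.

## Inference: MAP + Laplace via ECM

Posterior computation is maximum a posteriori with a Laplace (Gaussian
curvature) approximation, organised as expectation-conditional-
maximization:

* The **inner step** runs L-BFGS over global effects, contrasts,
  deviations and measurement-error parameters with the variance
  components held fixed.  Coordinates are Jacobi-preconditioned by
  `1/sqrt(likelihood curvature + prior curvature)`, where the likelihood
  part is a per-TAC diagonal second-difference in the composed
  parameters, accumulated through the (linear) design.  Gradients are
  exact chain-rule expressions; the only numerical piece is a central
  difference of each TAC's log-likelihood in its P composed parameters
  (2P forward evaluations per gradient), verified against full finite
  differences to ~1e-6 relative.
* The **outer step** updates each random-effect SD in closed form from
  the stationary condition of the centred-parameterization posterior
  (`a/v - n - v/s^2 + 1 = 0` for `v = sd^2`, `a` the sum of squared
  deviations, `s` the half-normal scale) and the individual-level
  correlation matrix from the moderated sample correlation of the
  standardized deviations (4 pseudo-observations toward independence).
  The per-TAC error-scale SD updates the same way.
* Deviations are kept *centred* — the joint mode over deviations and
  scales in the non-centred form is degenerate (scales inflate), whereas
  the centred stationary conditions behave like penalized variance-
  component estimation.  Log-scales are box-bounded away from the
  zero-variance funnel spike.
* **Draws** come from the Laplace approximation around the final point
  with variance components held at their estimates — empirical-Bayes
  intervals in the spirit of REML-Wald practice.  The Hessian is a
  finite difference of the exact gradient over the free coordinates,
  eigenvalue-floored before inversion.  Point summaries are posterior
  modes; intervals and directional probabilities use the draws.
  Convergence diagnostics report optimizer status and the preconditioned
  gradient norm rather than MCMC statistics, because no Markov chain is
  involved.

Warm starts from the per-TAC NLS table (robust region/subject aggregates
seed the upper levels; TAC deviations start at zero) substantially cut
inner iterations on larger cohorts.

What this buys and what it costs: the posterior-mean/mode point estimates
and the shrinkage behaviour match what a full posterior simulation would
give on these well-identified scales; interval calibration is checked
empirically in the test suite (null coverage of the raphe contrast at
roughly the nominal 95% over seeded replicates) rather than inherited
from sampler guarantees; and hyperparameter uncertainty is not
propagated into the intervals.

## Synthetic cohort generator

The generator emulates the statistical structure of a three-group
serotonin-1A occupancy-style study (healthy volunteers, not-recently-
medicated and antidepressant-exposed patients; default sizes 57/50/53)
without reproducing any real measurement:

* **Regions.** Seven serotonin projection regions (DLPFC, MPFC, ACC,
  PCC, INS, HIP, AMY), a raphe-like region (RN), optionally cerebellar
  grey (CGM) and white matter (CWM).  Mean log parameters give curves
  with a plausible [11C]WAY100635-like character: low non-displaceable
  volume everywhere (V_ND ~ 0.23-0.36), high cortical/limbic BP_ND
  (3.5-5.5), a small low-binding raphe, and a CWM reference with the
  lowest V_ND (about 35% below the others) plus a small specific-binding
  contamination (BP_ND 0.15, toggleable) to exercise reference-tissue
  bias.  Exact values are generator defaults, calibrated qualitatively.
* **Hierarchy.** Subject-level log-parameter deviations are multivariate
  normal with SDs (0.12, 0.18, 0.22, 0.08, 0.15) and a plausible
  positive-leaning correlation matrix (K1-V_ND 0.6, V_ND-BP 0.4, ...);
  region x individual (TAC-level) jitter is small — (0.02-0.04) — so
  per-TAC estimation error is predominantly recoverable measurement
  noise, matching the emulated study's simulation structure in which
  hierarchical pooling removes most of the per-TAC error.
* **Effects.** The not-recently-medicated group gets +0.15 on log BP_ND
  in the raphe and +0.075 (half, on the log scale) in projection
  regions; the exposed group 0.  V_ND, K1 and the input are group-
  invariant.
* **fP.** Base 0.07 with log-normal subject noise (SD 0.2), in three
  modes: none; true group offsets reproducing an HV > AE > NRM ordering
  (0.08/0.07/0.06); or a smooth cosine assay drift over the sampling
  period (amplitude 0.4 on the log scale) with groups sampled
  inhomogeneously over time (volunteers early, patients late), which
  reproduces the apparent group differences as a pure confound.
* **Input function.** Feng-type whole plasma (linear rise to a dose-
  proportional peak near 0.75 min, tri-exponential decay) times a
  Hill-type parent fraction (fast metabolism, ~5% parent at 110 min),
  with log-normal subject-level jitter on amplitude, peak time, decay
  rates and metabolism speed.
* **Noise.** Frame noise is Gaussian with SD
  `noise_base x region multiplier x mean(TAC) / w_frame` — i.e. exactly
  the heteroscedasticity the frame weights encode — with `noise_base`
  0.05 and multiplier 3 for the raphe (1.5 CWM, 1.2 CGM): the smallest
  region is by far the noisiest, and its conventional log BP_ND
  estimates are frequently catastrophic, as expected for this tracer.

What the generator does **not** emulate: image-space effects (partial
volume, motion, reconstruction), AIF delay/dispersion, metabolite assay
error structure, fP dynamics within a scan, clinical covariates beyond
age/sex, and any real between-region covariance of the measurement
noise.  Tests passing on these cohorts therefore demonstrate statistical
behaviour of the estimators under the assumed data-generating model, not
performance on real images.

## Validation experiments and problem sizes

The heavier properties are checked by seeded simulation studies
(`hierpet.validation`), scaled for a single CPU:

* *Error reduction*: 20 subjects x 8 regions, default noise; RMSE of
  hierarchical versus per-TAC NLS estimates of log BP_ND and log V_ND,
  hierarchical fit warm-started from the same NLS table it is compared
  against.
* *Calibration*: 20 replicates of 18-subject null cohorts (3 regions);
  coverage of the 95% raphe-contrast interval for the univariate mixed
  model and the multivariate parameter-level model.
* *Outcome consistency*: 21 subjects x 3 regions with fP drift
  confounding; raphe contrasts from the three TAC-level
  parameterizations, and the univariate BP_F shift measured in the
  projection regions (the raphe univariate contrast is noise-dominated
  at this size and reported for information only).

## Numerical choices and degenerate inputs

* Blood tables interpolate linearly before the peak and log-linearly
  after it; beyond the last sample the curve extrapolates its last value
  with a warning.
* Repeated 2TCM macro-roots (possible only at measure-zero parameter
  combinations) are separated by a 1e-12 guard; the discriminant is
  clamped at zero (it is provably nonnegative for positive rates).
* Frame weights are floored at 0.05 inside the hierarchical likelihood
  (a zero weight would mean an infinite residual scale).
* vB is capped below 1 in the forward model; composed log parameters are
  clipped to [-30, 10] before exponentiation during optimization.
* All randomness flows from a single integer seed per entry point;
  regenerating a cohort with the same config and seed is bit-identical.

## Known limitations

* Intervals are Laplace/empirical-Bayes approximations: hyperparameter
  uncertainty is not propagated, and strongly non-Gaussian marginals
  (e.g. variance components near zero) are summarized by their mode.
* The parameter-level (SRTM) analysis ignores first-stage estimation
  uncertainty by construction.
* The penalized-spline fP drift analysis uses a cubic B-spline basis
  (size 10) with a second-difference penalty chosen by generalized
  cross-validation and approximate F-tests with effective degrees of
  freedom — a deliberately simple stand-in for full smoothing-model
  machinery; its role is the confounding logic (drift versus group), not
  exact smoother replication.
* No multiple-comparison adjustment is applied to regional contrasts;
  per-region intervals are reported as such.
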