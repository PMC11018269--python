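# Methods

## The model

`growthsurv` fits linear latent growth curve models for up to two
longitudinal outcomes — a standardized memory composite and the
standardized brain parenchymal fraction (BPF) — with a discrete-time
survival process that adjusts the trajectory estimates for death-related
attrition.

### Longitudinal part

For subject *i*, outcome *o*, visit *j* at subject-specific time
*t<sub>ij</sub>* (years in study):

    y_oij = eta0_oi + eta1_oi * t_ij + lambda_j * mu_p * 1[o carries practice] + eps_oij

* `(eta0, eta1)` per outcome are latent intercepts and slopes with means
  `alpha + Gamma' x_i` (covariates `x_i` shift both factors) and a joint
  2K x 2K covariance `Psi`; the entry between the two slopes is the
  memory-decline-by-atrophy covariance that the multiple-group analyses
  compare across reserve strata.
* Observation times are the subject's own (individually-varying time
  scores); the baseline visit is pinned at t = 0.
* The practice factor captures retest gains in repeated cognitive
  testing.  Its loading at 0-based visit order *j* is fixed at sqrt(j)
  (0, 1, sqrt(2) ~ 1.4); a one-decimal rounding mode reproduces the
  conventional fixed loadings 1 and 1.4.  By default the factor is a pure
  fixed effect (mean `mu_p` estimated, variance 0) attached to memory
  only; its variance can be freed (`practice_variance_free`), and BPF has
  no practice analogue.
* Residuals are homoscedastic across occasions per outcome (fewest
  parameters, the standard default) with an optional within-occasion
  memory-brain covariance `theta_cross` (estimated by default in
  bivariate models, the standard parallel-process choice).
  Occasion-specific residual variances are available by config for
  single-outcome models (`occasion_residuals=True`).
* Missing outcome entries are dropped from the subject's stack and the
  multivariate-normal density is evaluated on what remains (FIML); no
  imputation, no deletion of subjects.

### Survival part

With three planned visits there are two risk intervals.  The hazard of
death in interval *k*, conditional on survival so far, is

    h_k(eta) = expit(tau_k + gamma0 * eta0 + gamma1 * eta1)

with `(eta0, eta1)` the growth factors of the hazard-carrying outcome
(memory by default; configurable in bivariate models).  The logit link is
the conventional discrete-time choice; probit is available by flag.  A
subject contributes `log(1 - h_k)` for each survived interval and
`log h_K` if death occurred in interval *K*.  Subjects lost for other
reasons contribute longitudinal FIML terms and censored survival terms
(missing-at-random assumption).

Data convention: the death flag sits on a subject's last observed row and
means death in the immediately following interval.  A subject without the
flag is treated as having survived through the interval following their
last visit.  The synthetic generator enforces the same convention by
resolving death before (absorbing) dropout within each interval, so the
observed-data likelihood is exactly the generating process.

### Joint likelihood and quadrature

The joint likelihood integrates, per subject, the Gaussian outcome
density times the survival probability over the latent factors.  Because
the hazard involves only two factors, the integral is two-dimensional:
conditional on those factors' deviations, the outcome stack stays
Gaussian with a node-independent covariance, and the node dependence
collapses to a quadratic form in the node coordinates.

Two Gauss-Hermite layouts are implemented:

* **Posterior-centered evaluation** (`QuadratureRule(adaptive=True)`,
  the default for `joint_loglik`): the likelihood is factored as the
  exact marginal Gaussian density times the posterior expectation of the
  survival factor, integrated with nodes centered at each subject's
  posterior of the hazard-factor deviations.  This is exactly separable
  when the hazard loadings are zero and is converged to ~1e-9 by 7
  points per dimension on realistic cohorts.
* **Recentered prior expansion** (used for fitting): the same 2D
  expansion with an analytic gradient for every parameter block.  The
  node grid is re-centered and re-scaled at each subject's Gaussian
  posterior of the deviations, computed at the starting values and
  refreshed at the solution until self-consistent; between refreshes the
  grid is a fixed constant of the objective, so the analytic gradient is
  exact and the objective is smooth and deterministic.  A purely
  prior-centered grid (`adaptive=False` without centers) is retained as a
  diagnostic but converges slowly when residual variances make the
  posterior much narrower than the prior.

Default 15 points per dimension for evaluation; fitting uses 9 (the
recentered grid is accurate to ~1e-9 already at 7).

## Estimation

* Parameters are optimized on an unconstrained scale: log variances,
  log-Cholesky `Psi`, Fisher-z of the residual cross-correlation; hazard
  parameters are unconstrained already.
* Starting values: per-subject least-squares intercepts/slopes give the
  factor means and (by regression on the covariates) the covariate
  effects; their sample covariance, shrunk toward its diagonal and
  eigenvalue-floored, starts `Psi`; pooled within-subject residuals start
  `theta`; empirical interval death fractions start `tau`; hazard
  loadings start at zero.
* The search is diagonally preconditioned by the curvature at the start
  values (finite differences of the analytic gradient); without this the
  ~10^8 spread in curvature between slope-scale parameters and hazard
  loadings stalls L-BFGS.
* Convergence requires optimizer success plus a small preconditioned
  gradient; non-convergence is flagged in the result and retried from
  perturbed starts (two retries) before being reported as failed — never
  silently returned as valid.
* Standard errors come from the observed information (finite differences
  of the analytic gradient at the optimum) mapped to the natural scale by
  the delta method; confidence intervals are Wald-type (estimate +/-
  1.96 SE), and group comparisons use the block-diagonal stacked
  covariance of independently fitted groups.  Two-sided p-values, no
  multiple-testing correction (raw pairwise p-values are reported, as is
  conventional for this design).

## Synthetic cohorts

The generator mirrors the model exactly (bivariate correlated random
intercepts/slopes, practice effect, covariate effects, informative
discrete-time mortality, absorbing MAR dropout) and returns the
generating values as a ground-truth parameter object.  The reference
scenario emulates a middle-aged-to-older arterial-disease cohort followed
up to ~12 years with up to three visits:

* planned visits at 0/4/12 years with Gaussian jitter (SD 0.5 yr,
  truncated to keep times increasing; the jitter SD is a design choice,
  not a published fact);
* memory slope mean -.085/yr, brain slope mean -.137/yr (standardized
  units), slope covariance ~.001 (slope SDs .045 and .035, correlation
  .60); intercept SDs .74 (memory) and .89 (brain); residual SDs .54 and
  .25 chosen so each outcome's baseline variance is ~1 after covariate
  effects;
* practice mean .10 standardized units per unit loading (typical retest
  gain);
* covariate effects per reference SD/unit: reading-test score (DART)
  .350 on the memory intercept and .008 on the memory slope; age, sex,
  stroke history adjustments on the intercepts;
* baseline covariates: DART ~ N(79.5, 15) clipped to [35, 100],
  correlated .50 with a latent education propensity discretized into 7
  levels whose 3-category marginal is 11.7/64.7/23.6%; 20.8% women;
  stroke prevalence 10.8%; age ~ N(58.7, 9.1) on [40, 79]; ICV drawn per
  sex (men 1490 (120), women 1350 (110) ml);
* mortality: logit hazard loadings (-0.4, -5.5) on the latent memory
  intercept and slope — about 1.5 mortality odds per SD of memory level
  and 1.3 per SD of slope, the magnitudes reported in the
  terminal-decline literature — with thresholds giving ~.20/.27 interval
  death probabilities; MAR dropout .2 per visit.  Combined, retention is
  roughly .64/.36, bracketing the motivating cohort's 57.6%/43.6%.

Two dedicated presets alter single aspects of these conditions:

* `informative_mortality_scenario` strengthens the slope-hazard link to
  -16 (~0.7 logit per slope SD) so the completer bias in naive
  longitudinal fits clearly exceeds estimator noise; this is the
  demonstration design for the informative-censoring correction.  At the
  reference loadings the hazard-slope coupling is so weakly identified at
  n ~ 1-2k that the joint and naive estimates differ by less than their
  sampling noise in a substantial fraction of replicates.
* `stratified_reserve_scenario` gives the DART slope effect .011 per SD
  in late-life and 0 in mid-life with slope-noise calibrated so the
  effect's standard error matches the published late-life z-ratio (~2.6
  at ~550 subjects); the published estimates are on a standardized scale
  whose raw-scale noise cannot be reconstructed, so the signal-to-noise
  ratio is the emulated quantity.  Age distributions are drawn so every
  subject's mid-study age falls on the intended side of the 60-year
  boundary, keeping the strata pure.

What the generator does **not** emulate: item-level test responses and
raw MRI volumes (outcomes are generated directly on the standardized
composite scale); non-monotone (intermittent) attendance; attrition that
is informative for reasons other than death; heavier-tailed or skewed
outcome distributions; practice effects that differ between persons.
Passing recovery tests therefore shows the estimator is correct *under
the stated model*, not that the model is correct for any particular
cohort.

## Preprocessing rules

* All standardizations are baseline-referenced with population SDs
  (ddof = 0) and frozen in a serializable reference object; later waves
  reuse the baseline moments.
* Memory composite: each of the three test scores z-scored against its
  baseline mean/SD, averaged (at least 2 of 3 components required, else
  missing — preserves FIML sample size), and the average re-standardized
  against its own baseline moments.
* BPF = total brain volume / intracranial volume, standardized from the
  fraction scale; ICV standardized separately within men and women.
* Age groups by the mid-study midpoint age with ties (exactly 60) going
  to late-life.
* Fixed tertile boundaries: DART 35-75 / 76-89 / 90-100; ICV z -2.66 to
  -.46 / to .40 / to 3.29; BPF z -3.65 to -.37 / to .51 / to 2.91;
  intervals are lower-open/upper-closed except the first bin.  The
  pipeline widens the outermost edges to the sample range (the fixed
  outer limits are sample extrema, not structural bounds); data-driven
  tertiles are available by config.
* Education levels 1-2 / 3-5 / 6-7 map to below-high-school / high
  school / college-university (the split points are exposed as config).

## Numerical choices and degenerate inputs

* Singular `Psi` (e.g. exactly zero random effects) is accepted for
  likelihood evaluation — the residual variance keeps the implied
  covariance positive definite — and handled with eigen-floored or
  jittered square roots where a Cholesky factor is needed.
* A non-positive-definite implied covariance is rejected with the
  offending subject named.
* A zero contrast (a parameter tested against itself) returns statistic
  0, df 0, p = 1; genuinely redundant contrast rows are rejected.
* Quadrature underflow raises with advice to increase the node count or
  use the adaptive rule.
* Observed information uses forward differences of the analytic gradient
  (step 1e-5); the delta-method Jacobian uses central differences.

## Problem sizes in the test suite

The acceptance experiments run at the sizes of the study design they
emulate: 200 recovery replicates at n = 1,000; 100 informative-censoring
replicates at n = 2,000; 1,000 null replicates at n = 500 for the Wald
calibration; 75 stratified pipeline replicates at n = 1,000 per stratum;
Monte-Carlo oracles use 10^6 draws on 3-subject toys.  Unit and property
tests use cohorts of 100-400 subjects.

## Known limitations

* Linear growth only (no quadratic/spline trajectories); two risk
  intervals by default (configurable); no continuous-time survival, no
  competing risks, no time-varying hazard covariates.
* The hazard regresses on one outcome's factors (memory by default); a
  four-factor hazard would require 4D quadrature and is out of scope.
* No Bayesian estimation, bootstrap intervals, or SEM fit indices.
* Finite-sample bias of the joint MLE is visible when the hazard
  loadings are weakly identified (few visits, small slope variance);
  the recovery experiments quantify it at the reference conditions.
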