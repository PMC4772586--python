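# Methods

## Model

### Discrete-time hazard

Time is a 1-based period index. For subject *i* with time-invariant
covariates *x* (and optionally time-varying *z*), the hazard in period *j* is

    h_ij = expit(beta_j + kappa_x' x_i + kappa_zj' z_ij),
    S_ij = prod_{k<=j} (1 - h_ik).

Each subject contributes one Bernoulli indicator `u` per at-risk period
(1 in the event period, 0 otherwise, nothing after resolution), so the joint
likelihood factorizes over person-period rows and the model is an ordinary
logistic regression on the expanded table. Fitting is Newton–Raphson with
analytic gradient/Hessian and monotone step-halving; convergence is declared
at max |gradient| < 1e-8 (the objective is smooth and concave, so this is
cheap and exact for practical purposes). Coefficients exceeding |30| or a
singular Hessian abort with a separation diagnostic; collinear design
columns are rejected by name.

Baseline options: `unstructured` (one intercept per period; with no
covariates this model is saturated and reproduces life-table hazards
exactly), `constant`, and `piecewise` (one intercept per user-specified group
of periods; groups must partition 1..J_max). Period-constant covariate
coefficients (the proportional hazard-odds model) are imposed by *sharing
design columns*, not by penalties or post-hoc restriction, so the constraint
holds exactly; freeing a covariate gives it one column per period with
events, which is also how the proportionality LR test builds its alternative
(df = number of freed coefficients).

Periods with zero events under a free baseline have their intercepts pinned
at logit = −15 (hazard ≈ 3e−7) with a warning instead of diverging; the
pinned values are reported in the fit object and used in prediction.

The default covariance is the sandwich estimator clustered by subject;
`vcov="model"` gives the inverse observed information (the LR test uses
likelihoods only and fits with model-based covariance for speed).

### Conventions for the data model

- Censored subjects are assumed observed for the whole of their final period
  (their last row is kept with u = 0); within-period censoring is not
  modelled.
- Events after the truncation horizon J_max are recoded as censored at
  J_max.
- Competing-cause deaths must be pre-coded by the caller as censoring.
- Missing covariates: complete-case by default (dropped count logged and
  returned) or modal-value imputation per column; nothing more elaborate.
- Ties within a period are exchangeable; no within-period ordering exists.

### Path system and mediation

A model is an ordered list of equations over named variables: linear
(probability) equations for the mediators, and exactly one terminal
discrete-time-logit equation for the outcome. Validation enforces
acyclicity, topological ordering of regressors, and that nothing depends on
the outcome. Linear equations are fitted by OLS with HC1
heteroskedasticity-robust standard errors; residual variance uses the
1/(n−k) convention. Linear-probability fitted values are *not* truncated to
[0, 1]; out-of-range predictions are counted and logged (the LPM is
acceptable here because the binary mediators are reasonably balanced).

Because the system is recursive with independent errors, the joint
likelihood factorizes and equation-by-equation estimation is the ML
solution; cross-equation parameter covariances are identically zero.

Indirect paths are all simple exposure→outcome chains through at least one
mediator, enumerated on the DAG and ordered shortest-first then
lexicographically. Each path effect is the product of its edge coefficients;
its variance is the first-order delta method. Successive edges of one path
always sit in different equations, so within a single path the coefficient
covariances vanish and Var = Σ_k (∏_{j≠k} c_j)² Var(c_k).

The total indirect effect is the sum of path products; its standard error is
the delta method over the *distinct* edge coefficients (the gradient of the
sum), honouring the fact that several paths can share an edge. By default
the coefficient covariance matrix is diagonal (the zero-cross-equation
convention extended to within-equation pairs, which is the only option when
the inputs are a printed coefficient table without covariances);
`within_equation_cov=True` adds covariance terms for coefficient pairs from
the same fitted equation. On the shipped worked example the two conventions
differ by about 0.001 in the total-indirect SE. The total effect is direct +
total indirect with the analogous gradient (the direct edge adds 1).

The mediation proportion is total-indirect / total-effect; when the direct
and indirect effects have opposite signs the decomposition is flagged as
"inconsistent mediation" (the proportion then falls outside [0, 1] and
should not be read as a share).

Latent-response standardization: the default "raw" view reports the outcome
equation's coefficients as estimated on the logit-latent scale, treated as
linear effects on a unit-SD latent response — this is the metric on which
the product decomposition operates. The alternative `ystar` view divides by
sqrt(Var(linear predictor) + π²/3), the classical y*-standardization for
logistic models; it is clearly labelled and never used by the decomposition
itself.

A nonparametric subject-resampling bootstrap (percentile CIs, B ≥ 100
enforced, >10% replicate failures aborts) provides an independent check on
the delta-method intervals; on simulated cohorts the two agree within ~25%
on single-path SEs.

## Synthetic cohorts

The generator emulates the structure of the colon-cancer registry cohort the
worked example comes from, with defaults chosen once:

- exposure: Beta distribution matched to mean 0.58, SD 0.13 on the 0–1
  affluence metric (uniform available);
- age at diagnosis: Normal(69, 11.5) truncated to [25, 99], scaled by 0.1;
- stage frequencies (10.8 / 35.0 / 32.4 / 21.8%) and treatment-optimality
  prevalence (80.8%) as categorical/Bernoulli draws;
- mediators: Bernoulli draws with probabilities from their linear equations,
  clipped to [0, 1] with the clip count recorded (warning above 20%). The
  LPM mechanism mirrors the analysis model so that parameter recovery is a
  pure self-consistency check; a logit mechanism is available for
  misspecification studies;
- hazard: constant baseline logit solved so that the cumulative event
  probability over J = 24 periods is 0.5 at the covariate means (the study
  does not publish its per-period baseline logits; with the default
  coefficients this gives β ≈ −5.99), then per-period Bernoulli event draws;
- censoring: administrative at J, plus an optional per-period random
  censoring probability (default 0, i.e. non-informative by construction).
  An event inside a fully observed period takes precedence over censoring at
  that period's end.

What this does *not* emulate: registry linkage artefacts, cause-of-death
misclassification, geographic clustering of deprivation, covariate
measurement error, or frailty-type unobserved heterogeneity. Passing
recovery tests therefore demonstrate internal consistency of the estimator
under its own assumptions, not robustness to those features of real data.

`recovery_experiment` runs simulate → fit → decompose over replicates and
reports bias, RMSE and 95%-CI coverage for every structural coefficient and
each path-specific indirect effect.

## Problem sizes used in the validation suite

Chosen as the package's own test design: parameter recovery uses 100
replicates at n = 5000 with the published coefficients as truth; the
proportionality test is calibrated over 200 null replicates (n = 800, J = 8,
κ = 0.3, baseline hazard ≈ 0.1) and its power checked over 100 replicates
(n = 2000, κ stepping 0.4 → 0.8 after period J/2); the Cox-convergence
property uses one continuous-time exponential cohort of n = 8000 (true log
hazard ratio 0.8) discretized at J = 4, 12 and 36 against a
partial-likelihood fit. Oracle equivalence with a pooled logistic regression
is checked at n = 1000, J = 24 with a four-group piecewise baseline.

## Numerical choices

- Gradient tolerance 1e−8; maximum 100 Newton iterations; step-halving up to
  30 times per iteration.
- Pinned intercept for event-free periods: −15 on the logit scale.
- Covariance matrices are symmetrized (0.5(V + V')) against round-off and
  checked PSD in tests.
- 95% intervals throughout (Wald for delta method, percentile for
  bootstrap); two-sided p-values from the χ²₁ reference for z².
- CSV output uses six significant digits; the CLI console table rounds to 3
  decimals for comparison with published tables.

## Known limitations

- No frailty / latent classes / random effects; all heterogeneity in hazards
  comes from observed covariates.
- No exposure–mediator interactions (no effect modification), controlled
  direct effects, or inverse-probability weighting.
- Binary mediators are modelled by linear probability equations only; logit
  or probit mediator links are not supported in combination with this
  outcome.
- Left truncation, interval censoring and calendar-date handling are out of
  scope; inputs must already be discrete period counts.
- The delta method is first-order; for very small samples or products near
  zero the bootstrap intervals are the safer choice.
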