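# Methods

`trialmed` re-implements, end to end, a Bayesian counterfactual mediation
analysis of a two-arm randomised smoking-cessation trial: linear models for
standardised mediators (importance, know-how, confidence — single-item 1–10
scores), logistic models for binary abstinence outcomes, and their
combination through the mediation formula into natural direct and indirect
effect odds ratios.  Because the original participant-level data are not
public, the package ships a synthetic-trial generator whose true causal
effects are computable by brute force, so every estimator can be validated
by parameter recovery.

## Causal estimands

Let `A` be treatment (1 = intervention), `M` the mediator vector at the
interval causally prior to the outcome (1-month mediators for 3-month
outcomes, 3-month mediators for 6-month outcomes), `Y` a binary abstinence
outcome, and `X` baseline covariates (sex, age, intervention version,
baseline FTND, baseline mediator scores).  With

    p[a, a'] = E_X [ P( Y(a, M(a')) = 1 | X ) ],

the package reports, on the odds-ratio scale with `odds(p) = p/(1-p)`:

| quantity  | definition                      | note |
|-----------|---------------------------------|------|
| pure NDE  | odds(p[1,0]) / odds(p[0,0])     | direct effect holding M at its control law |
| pure NIE  | odds(p[0,1]) / odds(p[0,0])     | mediator shift with treatment at control |
| total NDE | odds(p[1,1]) / odds(p[0,1])     | complement of pure NIE |
| total NIE | odds(p[1,1]) / odds(p[1,0])     | complement of pure NDE |
| TE        | odds(p[1,1]) / odds(p[0,0])     | total effect |

The headline pairing follows the prose definitions of natural effects
(pure NDE, pure NIE).  That pairing does not multiply to the total effect;
the complementary pairing does, exactly and per posterior draw:
`TE = total NDE x pure NIE = pure NDE x total NIE`.  All five families are
derived from the same four probabilities in every run, so the
decomposition is available (and asserted to 1e-10 in the tests) without
re-estimation.  Identifiability rests on randomisation (no A–M or A–Y
confounding) plus the untestable assumption that `X` suffices for
M–Y confounding; this mirrors the design assumptions of the trial being
emulated and is not something the package can verify.

## Estimation

**Mediator models.**  Each mediator at each interval is standardised by the
mean/sd (denominator n−1) of the available observations at that interval,
both arms pooled, and regressed on arm plus the adjustment set.  The
transform is stored with the fit and reapplied when counterfactual mediator
laws are evaluated, so mediator and outcome models always share one scale.

**Outcome models.**  Logistic regression of the outcome on arm, the
standardised mediator(s) at the causally prior interval, and the adjustment
set.  Complete-case rows only ("available data" analysis): a row enters
when arm, adjustment covariates, the mediators in the model, their
baselines and the outcome are all observed; the exact row set is recorded
with each fit.

**Priors.**  Standard normal on every effect coefficient (arm, mediator,
covariate) — continuous covariates are standardised so that scale is
meaningful.  Intercepts get Normal(0, 10); the linear-model residual sd a
half-Normal(5).  These weakly-informative choices are dominated by the
data at trial size.

**Sampling.**  The linear/logistic posteriors are smooth, unimodal and
near-Gaussian at these sample sizes, so they are sampled by independence
Metropolis–Hastings: 4 chains, multivariate-t proposal (df 8, scale 1.3)
built from a Laplace approximation at the posterior mode (numeric Hessian).
Acceptance is typically 0.4–0.6 and draws are nearly independent.  Chains
run at least 2000 kept iterations regardless of how many draws the caller
requests, so the split-Rhat and bulk-ESS diagnostics stay stable.  Any fit
with max Rhat > 1.01 (or non-finite diagnostics) is flagged; the pipeline
aborts on flagged fits unless explicitly overridden.  Divergences are
reported as 0 — the concept does not apply to these samplers — with the
acceptance rate reported instead.

**Attrition models.**  Response indicators are regressed on baseline
covariates, arm, and arm x covariate interactions, with Cauchy(0, tau)
priors on coefficients and a half-Normal(1) hyperprior on the shared scale
tau.  Two numerical choices matter here:

* tau is integrated out of the prior by quadrature on a 64-point log-spaced
  grid (tau from e^-7 to e^2), removing the funnel geometry entirely;
  posterior tau draws are reconstructed from the exact conditional
  p(tau | beta).  The resulting marginal prior has a spike-and-heavy-tails
  shape that defeats both independence proposals and ensemble moves, so
  this model is sampled with coordinate-wise slice sampling (rejection-free,
  no tuning).
* the design is centred — covariates and the arm indicator — before
  interactions are formed, because coordinate-wise sampling mixes poorly
  across the correlated intercept/sex/arm/arm:sex block on the raw coding.
  Cauchy priors therefore apply to the centred-parameterisation
  coefficients; arm-specific covariate effects are recovered exactly as
  main + (arm − arm-mean) x interaction per draw.

**Counterfactual integration.**  Per posterior draw, the conditional
mediator law under arm a' (normal on the z scale, mean from the mediator
model, residual sd from its draws) is integrated against the logistic
outcome model at arm a, then averaged over the observed covariate rows of
the analysis sample (no model is placed on the covariate distribution).
A single mediator uses Gauss–Hermite quadrature (32 nodes by default; 64
nodes agree with large Monte Carlo to 3 decimals in the tests).  The joint
three-mediator model uses Monte Carlo with mediators conditionally
independent given covariates (an optional residual-correlation parameter
exists in the generator, default 0): 20 normal deviates per row per
posterior draw, shared across the four compositions and all posterior draws
(common random numbers), i.e. 20 x n_rows integration points per marginal
probability.  Posteriors are thinned to 1000 draws for integration; the
Monte Carlo error this leaves on a posterior median is an order of
magnitude below the reporting precision.

**Summaries.**  Posterior medians with 2.5%/97.5% percentiles (linear
interpolation) and the posterior probability of direction.  Odds-ratio
summaries are direct percentiles of per-draw OR values, not exponentiated
log-scale summaries; the two agree for the median by monotonicity, which
the tests assert.

## The synthetic generator

The generator emulates the study conditions of the motivating trial:

* **Baseline** (n = 1012 by default): 81% women, age ~ truncated normal
  with *observed* mean 45.4 / sd 14 (the parent normal's parameters are
  solved so the truncated-at-18 moments match the targets), FTND rounded
  normal 5 (2.2) clipped to [0, 10], 6.2% surgery version, cigarettes/week
  lognormal matched to mean 101 / sd 46.2, baseline mediator scores
  importance 9.4 (1.3), know-how 5.5 (2.6), confidence 6.2 (2.5) with an
  exchangeable latent correlation of 0.3, clipped to [1, 10].
* **Randomisation**: permuted blocks of random length 2 or 4, stratified by
  intervention version, truncating the final block (the only source of
  imbalance, bounded by max(block)/2).
* **Mediator trajectories**: `M_t = mean + rho (M_0 − mean) + coef·x +
  a_t sd A + eps`, clipped to [1, 10]; `a_t` defaults are the trial's
  reported standardised effects (know-how 0.55/0.47/0.47, confidence
  0.30/0.23/0.32, importance −0.04/0.13/0.10), carry-over rho = 0.5, and
  the residual sd is chosen so the marginal control-arm sd stays at the
  baseline value.  Importance sits near its ceiling, so its effective arm
  effect is ~0, as observed.  Scores are continuous by default (an optional
  rounding flag exists): the analysis standardises them anyway and
  continuity keeps calibration smooth.
* **Outcomes**: separate logistic models per definition and interval
  (prolonged and point-prevalence abstinence are *not* nested and get
  independent noise), with logit = theta_0 + theta_A A + sum b_m z(M_m) +
  covariate terms.  The trial never prints arm-specific abstinence
  proportions, so control-arm rates are free parameters, defaulting to
  non-rare (~0.2–0.25) — deliberately, so the odds-ratio/risk-ratio gap is
  real and the integration machinery is genuinely exercised.
* **Attrition**: response models use exactly the predictors the trial
  reported as predictive — a positive age slope everywhere, arm-specific
  intercepts, and a negative FTND slope in the intervention arm at 1 month
  only.  Intercepts are solved (Gauss–Hermite over the covariate
  distribution) so the marginal response rates match the reported
  arm-specific rates (1 month: 40% intervention / 61% control; 3 months:
  41/47; 6 months: 36/42).  Outcome follow-up used phone-call rescue in the
  trial and its rates are unpublished; defaults of 70%/66% at 3/6 months
  are declared, not inferred.

**What the generator does not emulate**: item discreteness (scores are
continuous), serial mediator correlation beyond baseline carry-over,
non-normal mediator residuals other than clipping, time-varying direct
effects within an interval, and any dependence of missingness on
unobserved values (the mechanism is MAR by construction).  Passing recovery
tests therefore demonstrates estimator correctness under the assumed model
class, not robustness to real-data violations of it.

## The brute-force oracle and calibration

`oracle_true_effects` simulates a large synthetic population, draws both
potential mediator vectors M(0) and M(1) per participant with shared noise
(common random numbers), and averages the *true* outcome probabilities
under the four compositions — no outcome sampling noise enters.  Monte
Carlo standard errors come from 20 replicate batches.  Mediators outside
the requested mediator set follow the direct arm, i.e. they are treated as
part of the non-mediated pathway; in all calibration configurations used
for recovery checks the outside-set coefficients are zero, so nothing hangs
on this convention.

`calibrate_to_target` adjusts one coefficient — scaling the
mediator→outcome coefficients for an NIE target, searching the direct
effect theta_A for NDE/TE targets, or searching the latent arm effect for a
*realised* (post-clipping) standardised mediator-effect target — by a
monotone bracketing root find (bracket widened geometrically, then Brent's
method) evaluated on one fixed synthetic population, so the search is
deterministic and exact to the stated tolerance.  An unreachable target
raises an error reporting the bracket.

## Multiple imputation

Chained equations over the thirteen analysis variables (nine mediator
scores, four outcomes), visited in ascending-missingness order for
`n_iter` cycles: continuous mediators by type-1 predictive mean matching
(Bayesian linear draw, 5 donors), binary outcomes by approximate-Bayesian
logistic draws (ridge-stabilised IRLS + Laplace draw).  Every imputation
model conditions on all baseline covariates, arm, and all other analysis
variables, keeping imputation congenial with the analysis models.  Defaults
m = 20, n_iter = 20 are conventional choices recorded in the run manifest
(the original analysis's settings are unpublished).  Bayesian results are
pooled across imputations by concatenating posterior draws, which carries
within- plus between-imputation uncertainty into the usual summaries.

One property of the *default* study conditions is worth stating plainly:
the default attrition depends only on variables the total-effect model
adjusts for, so complete-case analysis is consistent there and imputation
cannot beat it.  The MAR-recovery test therefore drives outcome response
by the observed 3-month know-how score — still MAR, but omitted from the
total-effect model — where complete-case analysis is demonstrably biased
and the imputation recovers the full-data estimate (checked over 25 seeded
replicates of n = 4000, sized so the bias term dominates replicate noise).

## Problem sizes and reproducibility

Recovery checks run at n = 4000–5000 participants with full response, the
oracle-equivalence grid at n = 20,000, oracle populations at 200k–1M, and
attrition realism at 100 replicates of n = 1012; these sizes put estimator
noise well inside the stated tolerances while keeping any single check in
the minutes range on one CPU.  Every stage takes an explicit seed; a
pipeline run derives per-stage seeds from one master seed via hashed
labels, so reruns are byte-identical, and stage outputs are cached keyed on
a digest of the run configuration.

## Known limitations

* No exposure–mediator interaction terms and no sensitivity analysis for
  unmeasured mediator–outcome confounding (matching the scope of the
  analysis being reproduced).
* The joint mediator law is conditionally independent normals given
  covariates; a residual-correlation extension exists in the generator but
  the estimator does not model it.
* Clipping to [1, 10] makes the conditional-normal mediator model mildly
  misspecified near the scale ceiling (importance especially); recovery
  tests show the induced bias is well inside reporting tolerances, but it
  is not zero.
* The hierarchical attrition model's tau grid truncates the hyperprior at
  e^-7; coefficients smaller than ~1e-3 in magnitude are indistinguishable
  from zero by design.
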