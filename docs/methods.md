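# Methods

## The problem

In observational cohorts of recurrent events (sick-leave episodes,
recurrent infections, readmissions), many participants were already at
risk before follow-up began.  When the event exhibits *event dependence*
— the baseline hazard of the k-th episode depends on k — the number of
episodes a subject experienced before t = 0 matters for the analysis, but
it is typically unknown: the episode history is left-censored.  Fitting a
conditional (PWP-type) model on the *observed* episode index then mixes
subjects whose hazards differ, and fitting a common-baseline
(Andersen–Gill-type) model ignores event dependence altogether; both
produce biased effect estimates and distorted confidence intervals.

`recurmi` implements the specific-hazard frailty approach with multiply
imputed prior counts, plus the machinery needed to evaluate it by
simulation.

## Models

All survival models are proportional-hazards models on start–stop data
with delayed entry.  Writing ν_i for a subject-level frailty with
E[ν_i] = 1, V[ν_i] = θ, the fitted hazards are, per preset:

* `specific-cp` — h_{ikr}(t) = ν_i h_{0kr}(t) exp(X_i β): baseline
  stratified by the completed episode number k (imputed where unknown,
  capped at k_max) crossed with the prior-risk indicator r; time on the
  study clock (counting process).
* `specific-gt` — the same strata with each episode's clock restarted at
  the previous event (gap time).  For a prior-risk subject's first
  observed interval the gap clock starts at study entry: the time since
  the unobserved last episode is unknowable, which is exactly the data
  layout the method is designed around.
* `common` — λ_{ir}(t) = ν_i λ_{0r}(t) exp(X_i β): one baseline per
  prior-risk subpopulation, no event dependence (the comparator).
* `conditional-cp` / `conditional-gt` — strata from the observed episode
  index only (the naive conditional model under left censoring).
* `known-cp` / `known-gt` — strata from the true episode number; usable
  on simulated data only, as the oracle reference.
* `shared` — single stratum with frailty.

### Gamma-frailty estimation

The frailty is gamma with mean 1 and variance θ — the distribution is a
modelling choice (only the two moments are imposed by the setup); gamma
admits closed-form updates and matches common practice.  Estimation is
the standard penalized-partial-likelihood / EM scheme:

1. inner loop at fixed θ: Newton maximization of the stratified partial
   likelihood over β with log ν_i as offsets (Efron ties by default),
   alternated with the closed-form update
   ν_i = (d_i + 1/θ)/(Λ_i + 1/θ), where d_i is the subject's event count
   and Λ_i its accumulated frailty-free cumulative hazard (Breslow
   baseline);
2. outer loop: θ maximizes the observed-data marginal likelihood obtained
   by integrating the gamma frailty out analytically,
   Σ_i [log Γ(d_i + 1/θ) − log Γ(1/θ) + d_i log θ
        − (d_i + 1/θ) log(1 + θ Λ_i)] + (baseline/covariate terms),
   searched by bounded Brent on log θ over [1e-3, 8] with absolute
   tolerance 0.02 on log θ;
3. boundary: if the optimum is ≤ 2e-3 or beaten by the θ → 0 limit, the
   model collapses to the plain (no-frailty) stratified Cox fit with
   θ̂ = 0.

Standard errors of β come from the penalized information with the
frailty block absorbed through its Schur complement; the ω-block is taken
diagonal (the sparse approximation used by standard frailty software),
which is accurate for moderate θ and is replaced by the unadjusted
inverse information if it ever produces a non-positive variance (extreme
fixed θ).  Convergence tolerances: 1e-9 on the inner Newton objective,
1e-6 on the frailty updates, 50 EM iterations maximum.  Strata without
events are dropped with a logged warning — they contribute nothing to the
partial likelihood.

The engine was validated against `lifelines.CoxTimeVaryingFitter`
(no-frailty stratified fits agree to ~1e-6 in both coefficients and SEs)
and against R `survival::coxph(..., frailty.gamma(id))` (coefficients,
SEs and θ̂ agree to ~3 decimals on recurrent-event fixtures); the partial
likelihood itself is checked against brute-force risk-set enumeration.

### Imputation of the prior episode count

For subjects flagged at prior risk, the unknown number of prior episodes
k0 is multiply imputed (m = 5 by default) using a Conway–Maxwell–Poisson
(CMP) regression in a three-step Bayesian scheme: fit, perturb the
parameters with one N(β̂, V(β̂)) draw per imputation, then sample k0 from
the CMP at the perturbed parameters.  Design choices:

* Fitting data: the *observed* in-study event count of every subject,
  with log observed time at risk as offset; predictors are the analysis
  covariates plus an intercept.  This keeps the imputation model
  congenial with the analysis model without using unavailable
  information.
* Prediction: λ_i* = exp(x_i β* + log a_i), where a_i is the (known) time
  at risk before t = 0.
* The log-dispersion is part of the estimated and drawn parameter
  vector, so dispersion uncertainty propagates into the imputations.
* The imputed count enters the analysis only through the stratum label
  min(k0 + observed episode index, k_max); it is not a regressor.
  k_max = 3 by default (baseline hazards treated as constant from the
  third episode on), configurable.
* Posterior draws can land where the CMP series is unsummable (ν* → 0
  with λ ≥ 1); sampling is therefore truncated at 1000, which cannot
  affect the analysis because of the stratum cap.

The CMP likelihood itself is maximized by BFGS warm-started at the
Poisson GLM solution (statsmodels); the normalizing constant is a
truncated series with a geometric tail bound (relative tolerance 1e-10)
and a saddlepoint approximation when the series mode λ^{1/ν} exceeds 1e6.

### Pooling

Rubin's rules: β̄ = mean estimate, W = mean squared SE, B = between-
imputation variance, T = W + (1 + 1/m) B.  Degrees of freedom use the
Barnard–Rubin small-sample formula with complete-data df = events − p
(the effective sample size of a partial-likelihood analysis); CIs and
Wald tests use the t distribution with those df.  Frailty variances are
not pooled beyond reporting their mean.

## The simulator

The generator reproduces six worker populations defined by three
episode-specific distributions each (episode 1, 2, ≥3): populations 1–3
are unit-shape Weibull (exponential) with increasing event dependence
(second/third-episode hazard ratios 1.20/1.44, 1.50/2.25, 2.50/6.25);
populations 4–6 mix lognormal, loglogistic and shaped-Weibull episodes
with non-constant within-episode hazards.  Three Bernoulli(0.5)
covariates act with coefficients β = (0.25, 0.5, 0.75); for the Weibull
family the linear predictor multiplies the hazard (PH form), for the
lognormal/loglogistic it shifts the location parameter (AFT form), since
those families admit no PH representation.

Time is in days (1 year = 365): follow-up 2 or 5 years, prior-risk
windows 2 or 10 years.  No unit is inherent to the design; on the day
scale the first-episode mean e^8.109 ≈ 9.1 years is epidemiologically
plausible for long-term sick leave.  Prior-risk subjects draw their time
already at risk uniformly on (0, window] — the original dynamic-
population scheme does not pin this law down, and uniform entry over the
window is the natural stationary-recruitment assumption — and accrue
latent episodes before t = 0 from the same episode-specific
distributions; the gap in progress at t = 0 carries over, so the first
observed interval reflects the subject's true latent episode number.
Non-prior-risk subjects enter at a uniform incorporation time in
[0, follow-up) (configurable to all-enter-at-0), emulating a dynamic
cohort.  Events are instantaneous; episodes in progress at the end of
follow-up are censored there.  One root seed spawns per-subject
substreams, so cohorts are reproducible and subjects' draws do not
depend on cohort composition.

What the generator does *not* emulate: episode durations (no time spent
off-risk while sick), competing risks, covariate measurement error,
time-varying covariates, or real-world frailty heterogeneity beyond what
event dependence induces.  A green simulation test therefore establishes
internal validity of the estimator under the stated generating process,
not robustness to those violations.

## Performance criteria

Per scenario cell (population × n × follow-up × window × prior-risk
proportion × model), over R replicates and covariates j:

* mean relative bias: mean over (j, replicate) of |β̂ − β_j|/β_j × 100.
  Note this statistic is floored at ≈ 0.8·SE(β̂)/β_j even for an exactly
  unbiased estimator, i.e. ~22% at n = 250;
* relative bias of the mean: mean over j of |mean_m(β̂) − β_j|/β_j × 100
  — the conventional simulation-study bias measure, reported alongside
  and used for the headline "bias below 10%" checks (see the limitation
  note below);
* average 95% CI length 2·z_{0.975}·SE;
* coverage: percent of intervals containing β_j, with its binomial
  Monte-Carlo standard error;
* type-I error: percent of replicates with pooled Wald p < 0.05, for the
  null study (one covariate, β = 0).

Replicates whose fit fails are excluded, never retried (a retry would
bias the seed stream), and counted.  Defaults are desk-scale (100
replicates for bias/coverage, 200 for type-I error); the full published
grid (6 populations × 4 time combinations × 3 sizes × 5 proportions,
100/1000 replicates) is reachable purely through configuration.

## Known limitations

* The two bias variants above can disagree by an order of magnitude; the
  per-replicate absolute version is reported for completeness but cannot
  discriminate between methods at small n, where it mostly measures
  estimator variance.
* The frailty SE uses a diagonal approximation for the frailty block of
  the penalized information; for θ beyond ~2 (far above what these
  scenarios produce) it becomes conservative to unstable and falls back
  to the unadjusted information.
* θ is profiled to a tolerance of 0.02 on the log scale — ample against
  its sampling noise, but not a high-precision θ estimator.
* Imputation assumes the time at risk before t = 0 is known exactly and
  missingness is governed by the measured covariates (missing at
  random); neither assumption is testable from the data themselves.
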