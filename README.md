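# recurmi

Recurrent-event survival analysis when the episode history is
left-censored: some (or all) subjects in a cohort were already at risk
before follow-up started, so the number of episodes they had previously
experienced is unknown.  Ignoring that history — either by treating the
first observed episode as the first ever (naive conditional models) or
by assuming a common baseline hazard across episodes (Andersen–Gill-type
models) — biases covariate effects whenever the event shows *event
dependence*, i.e. the baseline hazard of the k-th episode depends on k.

`recurmi` implements the specific-hazard frailty approach for this
setting, aimed at biostatisticians and epidemiologists analyzing
recurrent outcomes such as sick leave, recurrent infections or
readmissions:

* the unknown prior episode count k0 is **multiply imputed** from a
  Conway–Maxwell–Poisson regression of the observed in-study counts
  (log time-at-risk offset), drawing parameters from N(β̂, V(β̂)) for
  each of m = 5 imputations;
* each completed data set is fitted with a **stratified
  proportional-hazards model with a shared gamma frailty**
  h_{ikr}(t) = ν_i h_{0kr}(t) e^{X_i β}, the baseline stratified by the
  completed episode number k crossed with the prior-risk indicator r, in
  counting-process (`specific-cp`) or gap-time (`specific-gt`) form,
  with delayed entry and E[ν_i] = 1, V[ν_i] = θ;
* the m fits are **pooled by Rubin's rules** (Barnard–Rubin degrees of
  freedom);
* a **simulator** reproduces six benchmark worker populations with
  tunable event dependence and left censoring, and a **harness**
  computes bias, CI length, coverage and type-I error over scenario
  grids.

The gamma-frailty Cox engine (start–stop data, stratified baselines,
Efron ties, penalized-likelihood frailty estimation with profile θ) is
implemented here and cross-validated in the test suite against
`lifelines` (no-frailty limit) and R `survival::coxph(frailty.gamma)`.

## Worked example

```python
import recurmi as rm
from recurmi.model import SpecificHazardFrailtyMI

pop = rm.get_population(1)                    # constant hazards, HR2=1.20, HR3=1.44
cfg = rm.CohortConfig.from_years(
    n=500, followup_years=5, prior_window_years=10,
    prior_risk_prop=0.5, seed=2026,
)
cohort = rm.simulate_cohort(pop, cfg)          # half the cohort at prior risk
res = SpecificHazardFrailtyMI(cohort, model="specific-gt", m=5, seed=2026).fit()
print(res.summary())
```

```
Rubin-pooled inference over 5 imputations
  mean frailty variance theta: 0.0000
  all fits converged: True

               coef       se       t       df        p   [0.025   0.975]
      x1     0.2929   0.0824    3.55    635.9   0.0004   0.1311   0.4547
      x2     0.4642   0.0851    5.46    631.3   0.0000   0.2971   0.6312
      x3     0.8360   0.0965    8.67    605.4   0.0000   0.6465   1.0254
```

The true log hazard ratios are (0.25, 0.5, 0.75); despite half the
cohort having an unknown episode history, the pooled estimates sit
within one to two standard errors of the truth and every 95% interval
covers it.  θ̂ = 0 is expected here: population 1 has no residual
heterogeneity beyond what the strata capture.  The per-fit results
(`CoxFrailtyModel(table, spec).fit()`) expose coefficients, SEs, θ̂ and
per-subject frailties the same way.

The same pipeline is scriptable from the shell:

```sh
recurmi simulate --population 1 --n 500 --followup-years 5 \
    --prior-window-years 10 --prior-risk-prop 0.5 --seed 2026 --out cohort.csv
recurmi impute --input cohort.csv --m 5 --seed 2026 --layout gap_time --out imputed.csv
recurmi fit --model specific-gt --input imputed.csv --out fit.csv
recurmi evaluate --population 1 --n 250 --replicates 100 --seed 1 --out grid.csv
```

Every command writes a JSON manifest (config, seed, version) next to its
output, so any artifact is reproducible from disk.

## Simulation-study replication

`scripts/acceptance.py` recomputes the headline simulation-study
quantities from scratch by running the full pipeline — no stored
results, everything simulated, imputed, fitted and pooled at run time:
the type-I error rate of `specific-cp` under a null covariate, the
coverage and systematic relative bias of `specific-gt` in the
constant-hazard scenario with 50% of subjects at prior risk, and the
recovery of the largest covariate effect when the episode history is
fully observed.

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

It finishes in a few minutes on one CPU and writes one JSON object per
quantity (`value` plus the replicate count `n`).  See `docs/methods.md`
for the estimation details, the simulator's assumptions and the known
limitations of the performance criteria.
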