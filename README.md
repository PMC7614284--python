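# illnessdeath

Bayesian multistate estimation of age-specific disease **incidence**,
**case fatality** and **remission** rates from aggregate burden data.

Multistate-lifetable health impact models need, for each disease, the
transition rates of a three-state illness–death process (disease-free →
disease → disease-specific death, with optional remission back to
disease-free). Published sources rarely report case fatality directly:
typically one has population **mortality**, **prevalence** and perhaps
**incidence** — by age, and often by area and gender. `illnessdeath`
infers all transition rates jointly from whatever subset of those
outcomes is available, with honest uncertainty.

## The model

Rates `i_a` (incidence), `f_a` (case fatality) and `r_a` (remission) are
constant within each year of age `a`. The annual transition probability
matrix `P_a` is the matrix exponential of the intensity matrix

```
        ( -i_a      i_a        0  )
  Q_a = (  r_a   -(r_a+f_a)   f_a )
        (   0        0         0  )
```

A birth cohort's state occupancy follows `S_{a+1} = S_a P_a`, giving
prevalence `π_a = S_{a,2} / (S_{a,1} + S_{a,2})` and the population
mortality probability `d_a = P_{a,2,3} π_a + P_{a,1,3} (1 − π_a)`.
Observed counts are binomial:

- `y_inc  ~ Bin(n_inc,  1 − P_{a,1,1})`
- `y_prev ~ Bin(n_prev, π_a)`
- `y_mort ~ Bin(n_mort, d_a)`
- `y_rem  ~ Bin(n_rem,  P_{a,2,1})`

Log rates are penalised thin-plate-style spline functions of age
(`log f_a = Σ_k β_k g_k(a)`, K = 10 terms), with an estimated smoothness
scale λ₀, an age `a_base` below which rates are constant, and an optional
constraint that rates increase with age. Areas can share strength through
a hierarchical model on the case-fatality intercepts (between-area SD λ₁
with a gamma prior elicited from fold-ratio beliefs), gender can enter as
an additive log-scale offset common to all areas (prior SD 0.82, i.e. a
95% prior rate-ratio interval of about 0.2–5) or interact with area, and
published age-specific calendar-time trends can be supplied as fixed
ratio matrices that the cohort recursion applies to past rates.

Two inference engines share every model: full posterior sampling
(ensemble MCMC with split-R̂/ESS diagnostics) and a fast posterior
mode + multivariate-normal approximation (Fisher-scoring Newton
optimisation with an expected-information covariance), typically two
orders of magnitude faster. Model checking includes fitted-vs-observed
tables, conflict p-values comparing each count against the synthesis of
the remaining evidence, and PSIS leave-one-out ELPD for model comparison.

## Worked example

Simulate a single-population dataset from known smooth rate curves
(IHD-like magnitudes, denominators of ~50 000 per age for incidence and
mortality and ~2 000 for prevalence, decaying above age 90), fit it with
the fast engine, and read off case fatality:

```python
from illnessdeath import assemble_model, fit_mode_laplace, summarize_rates
from illnessdeath.synthetic import ScenarioConfig, simulate_scenario, matching_config

scenario = ScenarioConfig(variant="single-area", seed=1)
truth, data = simulate_scenario(scenario)

model = assemble_model(matching_config(scenario), data)
fit = fit_mode_laplace(model, seed=1)

summary = summarize_rates(fit)
cf = summary[(summary.quantity == "f") & summary.age.isin([60, 70, 80, 90])]
print(cf[["age", "median", "lower", "upper"]].round(4).to_string(index=False))
```

```
 age  median  lower  upper
  60  0.0294 0.0268 0.0322
  70  0.0387 0.0360 0.0413
  80  0.0526 0.0499 0.0554
  90  0.0709 0.0674 0.0748
```

The posterior medians track the true case fatality (0.0306, 0.0402,
0.0502, 0.0683 at those ages — a few percent relative error) and the 95%
intervals quantify what the mortality and prevalence counts can support.
Case fatality is never observed directly: it is inferred through the
multistate model. `sample_posterior(model, seed=1)` runs full MCMC on
the same model object; on this example its intervals agree with the
approximation above to within a few percent of interval width.

## Command line

```bash
illnessdeath simulate --seed 3 --out-dir runs/sim
illnessdeath fit   --data runs/sim/simulated_counts.csv --engine mode --seed 1 --out-dir runs/fit
illnessdeath check --data runs/sim/simulated_counts.csv --engine mode --seed 1 --out-dir runs/check
illnessdeath prepare --data estimates.csv --out-dir runs/prep   # estimate+CI format -> counts
```

Every run writes plain CSV outputs plus a JSON manifest (inputs, digests,
seed, engine, version, timing) sufficient to reproduce it.

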