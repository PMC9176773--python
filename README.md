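# macrofrailty

Frailty indices of nations: construction from disease-prevalence panels,
panel-regression validation, global aging trends, and the association
between workforce physiological aging and labor productivity.

## The problem

A frailty index measures physiological (as opposed to chronological) age as
the fraction of a fixed list of *N* age-related health conditions
("deficits") that a person has:

    d_i = (1/N) Σ_d 1_i(d)

Averaged over a population cell, the double sum rearranges so the index is
simply the mean of the *N* condition prevalence rates — which makes it
computable for whole countries from burden-of-disease prevalence panels:

    d_ac = (1/N) Σ_d P_dac / P_ac

for age group *a* in country *c*. From the cell indices the package builds

* **period life-cycle deficits** — the unweighted mean over age groups 20–24
  … 90–94: the deficits a hypothetical person would accumulate facing one
  period's age-specific rates;
* **workforce frailty** — the population-share-weighted mean over ages
  20–64: a workforce ages both because workers in each age group carry more
  deficits and because population mass shifts into older groups.

Four fixed-effects panel regressions (all with standard errors clustered at
the country level) validate and exploit the index:

| specification | model |
|---|---|
| age gradient | ln d_act = μ·age_a + θ_c + θ_t + ε (μ/5 ≈ annual deficit growth) |
| mortality power law | ln m_act = β·ln d_act + λ_c + λ_t + λ_a + ϵ (m ∝ d^β) |
| period trends | ln d_act = ϕ_t + ξ (ϕ_t = % aging since the baseline period) |
| growth | ln y_ct = γ·ln d_ct + X′Γ + σ_c + σ_t + ζ (y = GDP per working-age person; X = age shares + initial-GDP × period convergence controls) |

The intended users are epidemiologists and economists who want to run this
methodology on prevalence extracts (GBD-style), mortality life tables
(HMD-style) and income panels (PWT-style) — or to study its statistical
behavior on fully synthetic panels with known ground truth, which the
built-in generator provides.

## Worked example

```python
import macrofrailty as mf

cfg = mf.GeneratorConfig(n_countries=50, sd_period=0.0, seed=1)
prevalence, pop, truth = mf.generate_prevalence_panel(cfg)
frailty = mf.build_frailty_panel(prevalence)

grad = mf.fit_age_gradient(frailty, "female")
mortality = mf.generate_mortality_panel(frailty, cfg)
power = mf.fit_mortality_elasticity(frailty, mortality, "female",
                                    with_country_fe=False, with_period_fe=False)
trend = mf.fit_period_effects(frailty, "20-24", "90-94")

econ = mf.generate_econ_panel(frailty, pop, cfg)
wf = mf.workforce_index(frailty[frailty.period.isin(cfg.econ_periods)],
                        pop[pop.period.isin(cfg.econ_periods)])
growth = mf.fit_growth_model(econ, wf, spec="benchmark")
cf = mf.counterfactual_growth(0.02, growth.params["ln_deficits"], horizon_years=29)
```

This prints (via the obvious f-strings):

```
female age slope: 0.1340 (SE 0.0001)
annual deficit growth: 2.7% per year of age
mortality elasticity: 3.067 (SE 0.001)
2019 period effect: +1.95% vs 1990
GDP elasticity of workforce frailty: -1.470 (SE 0.118, N=200)
counterfactual: -2.9% cumulative, -0.10 pp/year
```

Reading the numbers: female log deficits rise 0.134 per five-year age group
(≈ 2.7 %/year of age — deficits roughly double every 26 years of life); a 1 %
higher frailty index goes with ≈ 3.1 % higher female mortality; life-cycle
deficits in 2019 are ≈ 2 % above their 1990 level (the generator's drift);
and a 1 % more frail workforce is associated with ≈ 1.5 % lower GDP per
working-age person, so the 2 % deficit rise costs ≈ 3 % of GDP over 29
years, ≈ 0.1 percentage points of annual growth. Each estimate recovers the
generator's ground truth within sampling error.

## Command-line pipeline

```bash
macrofrailty simulate --seed 1 --out data/          # synthetic panels + truth sidecar
macrofrailty index    --config run.yaml             # frailty panel + aggregates
macrofrailty validate --config run.yaml             # age-gradient & mortality tables
macrofrailty trends   --config run.yaml             # period-effect tables by grouping
macrofrailty growth   --config run.yaml --long-difference
macrofrailty report   --delta-log-deficits 0.02 --gamma -1.5
```

`run.yaml` is a flat key-value file naming the four input CSVs (long-format
schemas documented in `macrofrailty/io.py`; a column map adapts foreign
extracts). Exit codes: 0 success, 2 validation error, 1 unexpected failure.

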