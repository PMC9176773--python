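# Methods

## The macro frailty index

For an individual, the frailty index is the fraction of a fixed list of *N*
age-related conditions present. Deficits qualify by the usual criteria:
associated with health status, prevalence rising with age, not saturating
early, spanning several organ systems, and — critically for panel use — the
item set fixed across iterations. The package therefore treats an
incomplete condition set in a cell as a hard validation error rather than
renormalizing over available items: silently changing the item set would
change the measurand between periods.

Summing the individual indices over a population cell and exchanging the
order of summation gives the cell index as the arithmetic mean of the *N*
prevalence rates, `d_ac = (1/N) Σ_d P_dac / P_ac`. Everything downstream is
built from these cell indices:

* **unweighted aggregates** over an age range (default 20–24 … 90–94):
  "period life-cycle deficits", the experience of a hypothetical person
  facing one period's age-specific rates — composition-free by design;
* **weighted aggregates** using population shares as weights: the frailty of
  the average person actually alive; over ages 20–64 this is the
  **workforce index**, which moves both with within-group deficits and with
  the age composition of the workforce.

Sexes are combined at the cell level by population-weighting the
sex-specific indices, which is algebraically identical to computing the
index from pooled both-sex prevalence (prevalence × count = affected
persons). A numerical identity checked in the tests: the weighted all-age
index decomposes exactly into the working-age share times the workforce
index plus the old-age share times the 65–94 index.

Age groups are closed five-year bins, serialized `"20-24"` … `"90-94"`; the
internal age coordinate is the 0-based bin index, so the age-gradient slope
is per five-year step and dividing by 5 annualizes it (that convention is
why the regression uses the index, not the midpoint age). Periods are
categorical calendar-year labels (1990, 1995, …, 2015, 2019 by default);
the 4-year step to 2019 is deliberately not rescaled or interpolated —
period effects are contrasts between labeled cross-sections, not rates.

## Fixed-effects engine

All four specifications run on one least-squares engine. Absorbed factors
(country, period, age group) are removed by alternating projections:
repeatedly subtracting within-group means of all variables until every
factor's residual group means fall below 1e-10 in absolute value (cap
10,000 sweeps; a single factor converges in one). The demeaned solution
equals the explicit dummy-variable regression — the test suite verifies
coefficient agreement with statsmodels dummy OLS to 1e-8 and better.

Variance is the cluster-robust sandwich with the CR1 small-sample factor
`G/(G-1) · (n-1)/(n-k)`, clustering at the country level; `k` counts the
explicit regressors plus the absorbed degrees of freedom (one grand
intercept plus levels−1 per factor, assuming a connected panel), so the
standard errors coincide with a dummy-variable regression under
`cov_type="cluster"`. With every observation its own cluster the estimator
degenerates to HC1, also verified in tests. p-values use a t reference
distribution with G−1 degrees of freedom. Rank deficiency after absorption
is detected with a pivoted QR and reported with the names of the collinear
columns. Both a within-R² (demeaned regression) and an overall R²
(including absorbed effects) are reported; published tables of this kind
show the overall version.

Specification details:

* **Age gradient**: ln cell frailty on the age-group index, absorbing
  country and period, per sex.
* **Mortality elasticity**: ln mortality on ln frailty with any subset of
  country/period/age fixed effects. Without age effects the slope is the
  power-law exponent (the natural consequence of Gompertz mortality plus
  constant-rate deficit accumulation); with age effects it is the
  conditional elasticity of mortality with respect to deficits at given
  chronological age.
* **Period effects**: ln cell frailty on period dummies, both sexes pooled,
  earliest period omitted; on a balanced panel each coefficient is exactly
  the difference of period means of log deficits (a group-mean identity the
  tests assert). Country-group splits rerun the regression on subsets.
* **Growth**: ln GDP per working-age person on ln workforce frailty,
  absorbing country and period, with column selectors: no controls;
  + initial log GDP × period interactions (convergence — the first period's
  interaction is omitted, being collinear with the country effects);
  + working-age composition shares in ten-year bins (20–24 the omitted
  reference). A long-difference variant first-differences the earliest and
  latest periods and runs the cross-section with the analogous controls.
  Dummy levels sort lexicographically; omitted baselines are always the
  explicitly configured ones (earliest period; the 20–24 share).

## Synthetic data generator

The generator produces panels with exactly the statistical structure the
estimators assume, plus the realized ground truth, so every estimator can
be tested for parameter recovery. It emulates the *shape* of real
prevalence/population/mortality/income sources, not their content.

**Prevalence.** Cell target frailty is
`d = exp(b0_g + mu5_g·a + θ_c + θ_t + drift_t + cp_ct + ε)`, with per-sex
intercepts and slopes (female intercept higher, male slope steeper — the
compensation effect of morbidity), country effects (SD 0.2), period effects
(SD 0.05), a deterministic period drift (default rising linearly to 0.02
log points in the final period), a country–period shock shared across age
groups and sexes (SD 0.05), and cell noise (SD 0.02). Condition prevalences
are `d·w_j` for positive log-normal loadings `w_j` frozen per run and
normalized to mean exactly 1 — only the mean across conditions matters for
the index, so condition-level heterogeneity is a free texture choice.
Values are clipped into (1e-6, 0.99) and clip events counted (the defaults
sit far from the bounds; the counter exists so stress configurations are
honest). Defaults are the published point estimates: slopes 0.134/0.141,
intercepts −3.484/−3.581.

The country–period shock deserves a note: real national prevalence panels
move together across age groups within a country-year (epidemics,
surveillance revisions, policy shifts). Without such a component the
workforce index — an average over ~18 cells — would have essentially no
within-(country, period) variation left after fixed effects, and the growth
elasticity would be identified off nothing. The shock is mean-zero,
independent of age and of the GDP disturbance, so it biases neither the age
gradient nor the period effects; it only (correctly) widens clustered
standard errors.

**Population.** Per-country exponential pyramids `counts ∝ exp(−s_c·a)`
with slopes scattered around 0.10 (SD 0.05) and a per-country aging drift
(mean 0.01/period, SD 0.005) tilting mass toward older groups. The
cross-country scatter is what identifies the age-share controls in the
growth regression — with a common pyramid the shares would be collinear
with period effects. Country totals are flat at 10⁶ persons, split equally
by sex; levels are arbitrary because every consumer uses shares or rates.

**Mortality.** `ln m = const_g + β_g·ln d (+ age effects) + noise` (defaults
β 3.067/2.823, constants 2.762/2.310, noise SD 0.05). The optional additive
age-group effects generate worlds in which chronological age affects
mortality beyond frailty, so the age-FE specification estimates something
genuinely smaller than the raw power law.

**Income.** `ln y = 10 + γ·ln d_workforce + Γ′·shares + σ_c + σ_t +
conv_t·ln y_initial + noise` on the four-period subset 1990/2000/2010/2019
(γ = −1.53, Γ = (2.39, 1.05, 3.79, 7.36), noise SD 0.05, convergence
coefficients (0, −0.05, −0.10, −0.15)). The initial period is generated
first (its convergence coefficient is pinned to 0) so later periods load on
the *realized* initial log GDP, exactly as the estimator's interaction
terms assume.

All draws flow from `numpy.random.default_rng` seeded with
`[config.seed, stage]`, one independent stream per generation stage, so
identical configs give bit-identical panels and adding a stage never
perturbs earlier ones.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: disease-level epidemiology (incidence,
remission, comorbidity correlations), survivor effects at advanced ages,
measurement error correlated with income or with mortality registration,
unbalanced country coverage, and any feedback from income to health. The
generator realizes the maintained model; recovery tests demonstrate that
the estimators are correct under that model, not that the model is true.

## Post-estimation conventions

* Annualization of five-year-group slopes divides by 5.
* The counterfactual GDP effect of a deficit change is
  `100·γ·Δln d` percent cumulatively; annualized by simple division by the
  horizon (default 29 years, 1990→2019), which matches the usual printed
  rounding (3 % / 29 ≈ 0.1 pp). A compound (log-ratio) annualization is
  available but non-default.
* Life-year equivalence divides the percent change in deficits by the
  annual percent growth of deficits in age (2 / 2.5 = 0.8 years).
* Confidence bands use 1.96 × clustered SE (95 %).
* Significance stars in written tables: 10 / 5 / 1 percent.

## Problem sizes and numerical choices

Recovery tests and the acceptance script use 50 countries × 7 periods × 15
age groups × 2 sexes (the growth regression: 168 countries × 4 periods,
n = 672, matching the published sample size); Monte-Carlo calibration runs
200 replicates at 12–25 countries with 4 conditions — sizes chosen so the
whole suite runs in a few minutes while keeping clustered-SE asymptotics
reasonable (G ≥ 12). The Monte-Carlo checks assert unbiasedness of the
three elasticities within 3 Monte-Carlo standard errors and agreement of
the mean reported clustered SE with the empirical dispersion within 25 %.

Degenerate inputs are errors, not warnings: empty deficit vectors,
prevalence outside [0, 1], non-positive frailty or mortality under a log,
missing age groups in a requested range, unbalanced growth panels, single
clusters, and rank-deficient designs (reported with column names). Missing
conditions never renormalize. Ties in dummy ordering cannot arise: levels
are sorted and baselines configured.

## Known limitations

* The engine is dense and in-memory; it is comfortable to ~10⁷ cells but is
  not a high-dimensional-FE solver for millions of singleton groups.
* Only one clustering dimension (country) is implemented; two-way
  clustering is out of scope.
* The long-difference estimator clusters by country, which with one
  difference per country reduces to heteroskedasticity-robust errors.
* Period spacing is ignored everywhere by design; users who want per-year
  trend rates must divide period contrasts by the relevant year gaps
  themselves.
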