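"""Synthetic panel generator with the statistical structure the estimators assume.

Emulates the joint shape of the real inputs — disease-prevalence panels,
population pyramids, age-specific mortality and income panels — without any
epidemiological detail.  The data-generating processes mirror the four
regression specifications exactly:

* cell log frailty is linear in the age-group index with country, period and
  country-period effects plus idiosyncratic noise (exponential-in-age
  deficits, the macro analogue of constant-rate deficit accumulation);
* log mortality is a power law in cell frailty, optionally with additive
  age-group effects;
* log GDP per working-age person is linear in log workforce frailty, the
  working-age composition shares, country/period effects and
  convergence terms on initial log GDP.

Ground-truth parameters and realized effects are returned in a
:class:`GeneratorTruth` so estimators can be tested for parameter recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import frailty as fr
from .exceptions import BalancedPanelError, ConfigurationError, DomainError

DEFAULT_PERIODS = (1990, 1995, 2000, 2005, 2010, 2015, 2019)
ECON_PERIODS = (1990, 2000, 2010, 2019)

# Ten-year composition bins controlled for in the growth regression;
# "25-34" pools the five-year groups 25-29 and 30-34, etc.  The 20-24
# share is the omitted reference group.
SHARE_BINS: dict[str, tuple[str, ...]] = {
    "share_20_24": ("20-24",),
    "share_25_34": ("25-29", "30-34"),
    "share_35_44": ("35-39", "40-44"),
    "share_45_54": ("45-49", "50-54"),
    "share_55_64": ("55-59", "60-64"),
}
SHARE_CONTROLS = ("share_25_34", "share_35_44", "share_45_54", "share_55_64")

PREVALENCE_CLIP = (1e-6, 0.99)


def _default_drift() -> tuple[float, ...]:
    """Linear upward drift reaching 0.02 log points in the final period."""
    n = len(DEFAULT_PERIODS)
    return tuple(0.02 * i / (n - 1) for i in range(n))


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic world, with defaults set to the study
    conditions the estimators are validated against.

    Per-sex parameters are mappings ``{"female": .., "male": ..}``.  The
    female intercept is higher and the male age slope steeper, reproducing
    the compensation effect of morbidity.  Frailty defaults: slope 0.134/0.141
    log deficits per five-year group, intercepts -3.484/-3.581 at ages 20-24.
    Mortality defaults follow the power law ln m = const + beta ln d with
    beta 3.067/2.823 and constants 2.762/2.310.  The GDP elasticity gamma
    defaults to -1.53 with age-share effects (2.39, 1.05, 3.79, 7.36).
    """

    n_countries: int = 50
    periods: tuple[int, ...] = DEFAULT_PERIODS
    age_groups: tuple[str, ...] = fr.AGE_GROUPS
    n_conditions: int = 32
    mu5: Mapping[str, float] = field(
        default_factory=lambda: {"female": 0.134, "male": 0.141})
    b0: Mapping[str, float] = field(
        default_factory=lambda: {"female": -3.484, "male": -3.581})
    sd_country: float = 0.2
    sd_period: float = 0.05
    #: Country-period log-frailty shock shared across age groups and sexes;
    #: emulates country-level health shocks and is the within variation that
    #: identifies the growth elasticity once cell noise averages out.
    sd_country_period: float = 0.05
    sd_noise: float = 0.02
    period_drift: tuple[float, ...] = field(default_factory=_default_drift)
    loading_sigma: float = 0.3
    mortality_const: Mapping[str, float] = field(
        default_factory=lambda: {"female": 2.762, "male": 2.310})
    mortality_beta: Mapping[str, float] = field(
        default_factory=lambda: {"female": 3.067, "male": 2.823})
    #: Optional additive age-group effects in log mortality (length = number
    #: of age groups); None means none.  Used to generate worlds where
    #: chronological age affects mortality beyond frailty.
    mortality_age_effects: tuple[float, ...] | None = None
    sd_mort_noise: float = 0.05
    gamma: float = -1.53
    age_share_effects: tuple[float, ...] = (2.39, 1.05, 3.79, 7.36)
    sd_country_gdp: float = 0.3
    sd_period_gdp: float = 0.1
    sd_gdp_noise: float = 0.05
    #: Period-specific coefficients on initial (first econ period) log GDP;
    #: first element must be 0 — the initial period defines the level.
    convergence_coefs: tuple[float, ...] = (0.0, -0.05, -0.10, -0.15)
    econ_periods: tuple[int, ...] = ECON_PERIODS
    gdp_const: float = 10.0
    #: Population pyramid: baseline counts fall like exp(-slope * a) in the
    #: age-group index; per-country slopes scatter around the mean, and a
    #: per-country aging drift tilts mass toward older groups each period.
    pyramid_slope: float = 0.10
    sd_pyramid_slope: float = 0.05
    aging_drift: float = 0.01
    sd_aging_drift: float = 0.005
    country_population: float = 1e6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conditions < 1:
            raise ConfigurationError("n_conditions must be >= 1")
        if self.n_countries < 1:
            raise ConfigurationError("n_countries must be >= 1")
        if len(self.periods) == 0:
            raise ConfigurationError("periods must be non-empty")
        if any(b >= a for a, b in zip(self.periods[1:], self.periods)):
            raise ConfigurationError("periods must be strictly increasing")
        for lbl, nxt in zip(self.age_groups, self.age_groups[1:]):
            lo, hi = map(int, lbl.split("-"))
            nlo = int(nxt.split("-")[0])
            if hi - lo != 4 or nlo != lo + 5:
                raise ConfigurationError(
                    f"age_groups must be contiguous five-year bins; got {lbl} then {nxt}")
        for name in ("sd_country", "sd_period", "sd_country_period", "sd_noise",
                     "sd_mort_noise", "sd_country_gdp", "sd_period_gdp",
                     "sd_gdp_noise", "sd_pyramid_slope", "sd_aging_drift"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if len(self.period_drift) != len(self.periods):
            raise ConfigurationError("period_drift must have one entry per period")
        if self.period_drift[0] != 0.0:
            raise ConfigurationError("period_drift must start at 0 (baseline period)")
        if len(self.convergence_coefs) != len(self.econ_periods):
            raise ConfigurationError("convergence_coefs must have one entry per econ period")
        if self.convergence_coefs[0] != 0.0:
            raise ConfigurationError("convergence_coefs must start at 0 (initial period)")
        if not set(self.econ_periods).issubset(self.periods):
            raise ConfigurationError("econ_periods must be a subset of periods")
        if self.mortality_age_effects is not None and len(
                self.mortality_age_effects) != len(self.age_groups):
            raise ConfigurationError(
                "mortality_age_effects must have one entry per age group")

    def countries(self) -> list[str]:
        width = len(str(self.n_countries - 1))
        return [f"C{i:0{width}d}" for i in range(self.n_countries)]

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GeneratorTruth:
    """Realized effects and echoed parameters of one generator run."""

    config: GeneratorConfig
    country_effects: pd.Series        # theta_c, by country
    period_effects: pd.Series         # theta_t, by period
    country_period_effects: pd.DataFrame  # shared shocks, country x period
    condition_loadings: np.ndarray    # w_j, mean exactly 1
    clip_events: int                  # prevalence/frailty values clipped


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per generation stage
    return np.random.default_rng([config.seed, stream])


def generate_population_panel(config: GeneratorConfig) -> pd.DataFrame:
    """Population counts by country, period, sex and age group.

    Per-country exponential pyramids with an optional per-period aging drift
    that tilts mass toward older groups.  Sexes split the country total
    equally.  Counts are strictly positive and per-(country, period, sex)
    shares sum to 1 by construction.
    """
    rng = _rng(config, 1)
    countries = config.countries()
    n_age = len(config.age_groups)
    a = np.arange(n_age)
    slopes = config.pyramid_slope + rng.normal(0.0, config.sd_pyramid_slope, config.n_countries)
    drifts = config.aging_drift + rng.normal(0.0, config.sd_aging_drift, config.n_countries)

    rows = []
    for ci, c in enumerate(countries):
        for pi, t in enumerate(config.periods):
            w = np.exp(-(slopes[ci] - drifts[ci] * pi) * a)
            shares = w / w.sum()
            counts = config.country_population * shares / 2.0
            for sex in fr.SEXES:
                for ai, g in enumerate(config.age_groups):
                    rows.append((c, t, sex, g, counts[ai]))
    return pd.DataFrame(rows, columns=["country", "period", "sex", "age_group", "count"])


def generate_prevalence_panel(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GeneratorTruth]:
    """Prevalence and population panels plus the realized ground truth.

    Cell target frailty is
    ``d = exp(b0_g + mu5_g * a + theta_c + theta_t + drift_t + cp_ct + eps)``
    with ``a`` the 0-based age-group index, clipped into the prevalence
    bounds.  Condition prevalences are ``d * w_j`` for fixed positive
    loadings ``w_j`` averaging exactly 1, so the cell mean prevalence equals
    the target frailty wherever nothing clips.
    """
    rng = _rng(config, 0)
    countries = config.countries()
    periods = list(config.periods)
    n_age = len(config.age_groups)
    nC, nT = len(countries), len(periods)

    theta_c = rng.normal(0.0, config.sd_country, nC)
    theta_t = rng.normal(0.0, config.sd_period, nT)
    cp = rng.normal(0.0, config.sd_country_period, (nC, nT))

    loadings = np.exp(rng.normal(0.0, config.loading_sigma, config.n_conditions))
    loadings = loadings / loadings.mean()  # mean exactly 1

    a = np.arange(n_age)
    drift = np.asarray(config.period_drift)
    clip_events = 0
    frames = []
    lo, hi = PREVALENCE_CLIP
    for si, sex in enumerate(fr.SEXES):
        mu5, b0 = config.mu5[sex], config.b0[sex]
        eps = rng.normal(0.0, config.sd_noise, (nC, nT, n_age))
        logd = (
            b0
            + mu5 * a[None, None, :]
            + theta_c[:, None, None]
            + (theta_t + drift)[None, :, None]
            + cp[:, :, None]
            + eps
        )
        d = np.exp(logd)
        clip_events += int(((d < lo) | (d > hi)).sum())
        d = np.clip(d, lo, hi)
        prev = d[..., None] * loadings[None, None, None, :]
        clip_events += int(((prev < lo) | (prev > hi)).sum())
        prev = np.clip(prev, lo, hi)

        idx = pd.MultiIndex.from_product(
            [countries, periods, [sex], config.age_groups,
             [f"cond{j:02d}" for j in range(config.n_conditions)]],
            names=fr.CELL_KEYS + ["condition"],
        )
        frames.append(pd.DataFrame({"prevalence": prev.ravel()}, index=idx).reset_index())

    prevalence = pd.concat(frames, ignore_index=True)
    pop = generate_population_panel(config)
    truth = GeneratorTruth(
        config=config,
        country_effects=pd.Series(theta_c, index=countries, name="theta_c"),
        period_effects=pd.Series(theta_t, index=periods, name="theta_t"),
        country_period_effects=pd.DataFrame(cp, index=countries, columns=periods),
        condition_loadings=loadings,
        clip_events=clip_events,
    )
    return prevalence, pop, truth


def generate_mortality_panel(frailty_panel: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Age-specific mortality rates from the power law in cell frailty.

    ``ln m = const_g + beta_g * ln d [+ age_effect_a] + Normal(0, sd)``.
    With zero noise and no age effects the power law holds exactly cell by
    cell.
    """
    d = frailty_panel["frailty"].to_numpy(dtype=float)
    if (d <= 0).any() or (d >= 1).any():
        raise DomainError("frailty values must lie strictly in (0, 1)")
    rng = _rng(config, 2)
    out = frailty_panel[fr.CELL_KEYS].copy()
    const = frailty_panel["sex"].map(config.mortality_const).to_numpy(dtype=float)
    beta = frailty_panel["sex"].map(config.mortality_beta).to_numpy(dtype=float)
    lnm = const + beta * np.log(d)
    if config.mortality_age_effects is not None:
        eff = dict(zip(config.age_groups, config.mortality_age_effects))
        lnm = lnm + frailty_panel["age_group"].map(eff).to_numpy(dtype=float)
    if config.sd_mort_noise > 0:
        lnm = lnm + rng.normal(0.0, config.sd_mort_noise, lnm.shape)
    out["mortality"] = np.exp(lnm)
    return out


def generate_econ_panel(
    frailty_panel: pd.DataFrame,
    pop: pd.DataFrame,
    config: GeneratorConfig,
) -> pd.DataFrame:
    """Income panel linked to workforce frailty by the elasticity ``gamma``.

    ``ln y = const + gamma * ln d_workforce + Gamma' shares + sigma_c +
    sigma_t + conv_t * ln y_{c,initial} + Normal(0, sd)``; the initial
    period is generated first (its convergence coefficient is 0) so the
    realized initial log GDP feeds the later periods.

    Returns columns ``country, period, gdp_pw, ln_gdp_initial`` plus the
    five working-age composition shares (summing to 1).
    """
    wf = fr.workforce_index(frailty_panel, pop).set_index(["country", "period"])["frailty"]
    countries = sorted(frailty_panel["country"].unique())
    periods = list(config.econ_periods)
    missing = [
        (c, t) for c in countries for t in periods if (c, t) not in wf.index
    ]
    if missing:
        raise BalancedPanelError(
            f"workforce frailty missing for {len(missing)} country-period "
            f"cells, e.g. {missing[:3]}"
        )

    # working-age composition shares from both-sex counts
    wa = pop[pop["age_group"].isin(fr.WORKING_AGE_GROUPS)]
    tot = wa.groupby(["country", "period"], observed=True)["count"].sum()
    shares = {}
    for col, groups in SHARE_BINS.items():
        s = (
            wa[wa["age_group"].isin(groups)]
            .groupby(["country", "period"], observed=True)["count"].sum()
        )
        shares[col] = s / tot

    rng = _rng(config, 3)
    nC = len(countries)
    sigma_c = pd.Series(rng.normal(0.0, config.sd_country_gdp, nC), index=countries)
    sigma_t = pd.Series(rng.normal(0.0, config.sd_period_gdp, len(periods)), index=periods)
    gamma_vec = np.asarray(config.age_share_effects, dtype=float)

    rows: list[dict] = []
    lny0 = {}
    for pi, t in enumerate(periods):
        for c in countries:
            x = np.array([shares[col][(c, t)] for col in SHARE_CONTROLS])
            lny = (
                config.gdp_const
                + config.gamma * np.log(wf[(c, t)])
                + float(gamma_vec @ x)
                + sigma_c[c]
                + sigma_t[t]
                + rng.normal(0.0, config.sd_gdp_noise)
            )
            if pi == 0:
                lny0[c] = lny
            else:
                lny += config.convergence_coefs[pi] * lny0[c]
            row = {
                "country": c, "period": t, "gdp_pw": float(np.exp(lny)),
                "ln_gdp_initial": None,
            }
            for col in SHARE_BINS:
                row[col] = float(shares[col][(c, t)])
            rows.append(row)
    econ = pd.DataFrame(rows)
    econ["ln_gdp_initial"] = econ["country"].map(lny0)
    return econ
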