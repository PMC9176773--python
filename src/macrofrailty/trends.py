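"""Post-estimation: annualization, trend tables, counterfactual decomposition.

These operations turn fitted period effects and the growth elasticity into
the quantities usually discussed: percent aging since the baseline period by
country group and age range, the implied cumulative and annualized drag on
GDP per working-age person, and the conversion of a deficit change into
life-years of physiological aging.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import frailty as fr
from .exceptions import DomainError, ValidationError
from .panels import FEFit, fit_period_effects

#: 95 percent confidence bands throughout.
CI_MULTIPLIER = 1.96


def annualize(coef5: float) -> float:
    """Per-year rate from a per-five-year-age-group coefficient (coef5 / 5)."""
    return float(coef5) / 5.0


def format_percent(rate: float, decimals: int = 1) -> str:
    """Render a rate as a percent string, e.g. 0.0268 -> ``'2.7%'``."""
    return f"{100 * rate:.{decimals}f}%"


@dataclass
class CounterfactualResult:
    """Association of a cumulative deficit change with GDP per worker."""

    cumulative_pct: float      # cumulative effect on log GDP, in percent
    annual_pp: float           # annualized difference, percentage points/year
    horizon_years: int
    delta_log_deficits: float  # input echoed
    gamma: float               # input echoed
    compound: bool = False


def counterfactual_growth(
    delta_log_deficits: float,
    gamma: float,
    horizon_years: int = 29,
    compound: bool = False,
) -> CounterfactualResult:
    """Cumulative and annualized growth effect of a deficit change.

    The cumulative effect on log GDP per working-age person is
    ``gamma * delta_log_deficits`` (in percent: × 100); e.g. a 2 percent
    deficit increase with elasticity −1.5 is a 3 percent GDP reduction.
    The default annualization divides by the horizon (simple form); the
    compound alternative converts the cumulative log effect to a constant
    annual rate.
    """
    if horizon_years < 1:
        raise ValidationError("horizon must be at least 1 year")
    cumulative_pct = 100.0 * gamma * delta_log_deficits
    if compound:
        import math
        annual_pp = 100.0 * (math.exp(cumulative_pct / 100.0) ** (1.0 / horizon_years) - 1.0)
    else:
        annual_pp = cumulative_pct / horizon_years
    return CounterfactualResult(
        cumulative_pct=cumulative_pct,
        annual_pp=annual_pp,
        horizon_years=horizon_years,
        delta_log_deficits=delta_log_deficits,
        gamma=gamma,
        compound=compound,
    )


def physiological_life_years(delta_deficits_pct: float, annual_growth_pct: float) -> float:
    """Life-years of physiological aging equivalent to a deficit change.

    Divides the cumulative percent change in deficits by the percent growth
    of deficits per year of age (e.g. 2 / 2.5 = 0.8 life-years).
    """
    if annual_growth_pct <= 0:
        raise DomainError("annual deficit growth rate must be positive")
    return float(delta_deficits_pct) / float(annual_growth_pct)


def trend_table(
    frailty: pd.DataFrame,
    grouping: dict[str, str] | None = None,
    age_ranges: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Period-effect estimates by country group and age range.

    One period-dummy regression per (group, age range); estimates and 95%
    confidence bounds are reported in percent relative to the baseline
    period.  Groups whose regression cannot run (e.g. empty after filtering)
    are flagged rather than dropped.

    Columns: ``sample, age_lo, age_hi, period, estimate_pct, ci_low_pct,
    ci_high_pct, flag``.
    """
    if age_ranges is None:
        age_ranges = [(fr.AGE_GROUPS[0], fr.AGE_GROUPS[-1])]
    samples: list[str | None]
    if grouping is None:
        samples = [None]
    else:
        samples = sorted(set(grouping.values()))

    rows = []
    for sample in samples:
        for age_lo, age_hi in age_ranges:
            label = sample if sample is not None else "all"
            try:
                fit = fit_period_effects(
                    frailty, age_lo, age_hi,
                    grouping=grouping if sample is not None else None,
                    group=sample,
                )
            except ValidationError as exc:
                rows.append({
                    "sample": label, "age_lo": age_lo, "age_hi": age_hi,
                    "period": pd.NA, "estimate_pct": float("nan"),
                    "ci_low_pct": float("nan"), "ci_high_pct": float("nan"),
                    "flag": str(exc),
                })
                continue
            for name, est in fit.params.items():
                if not name.startswith("period_"):
                    continue
                se = fit.se[name]
                rows.append({
                    "sample": label, "age_lo": age_lo, "age_hi": age_hi,
                    "period": int(name.split("_")[1]),
                    "estimate_pct": 100.0 * est,
                    "ci_low_pct": 100.0 * (est - CI_MULTIPLIER * se),
                    "ci_high_pct": 100.0 * (est + CI_MULTIPLIER * se),
                    "flag": "",
                })
    return pd.DataFrame(rows)
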