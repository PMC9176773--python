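"""Multi-way fixed-effects panel regressions with country-clustered errors.

One least-squares engine (:func:`fit_fe_ols`) absorbs arbitrary categorical
factors by alternating-projection demeaning and reports cluster-robust (CR1)
standard errors.  On top of it sit the four study specifications:

1. age gradient — log cell frailty on the linear age-group index, country
   and period fixed effects (the slope is the five-year growth rate of
   deficits; /5 annualizes it);
2. frailty–mortality elasticity — log mortality on log frailty, with any
   subset of country / period / age fixed effects (the power law m ∝ d^β);
3. period effects — log frailty on period dummies with the first period
   omitted (percent change in period life-cycle deficits from baseline);
4. growth — log GDP per working-age person on log workforce frailty, with
   convergence (initial GDP × period) and age-composition controls, plus a
   long-difference variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from . import frailty as fr
from .exceptions import (
    BalancedPanelError,
    DomainError,
    RankDeficientError,
    ValidationError,
)

DEMEAN_TOL = 1e-10
DEMEAN_MAX_SWEEPS = 10_000


@dataclass
class FEFit:
    """Result of a fixed-effects least-squares fit."""

    params: pd.Series
    se: pd.Series
    nobs: int
    n_clusters: int
    r2_within: float
    r2_overall: float
    absorbed: tuple[str, ...]
    residuals: np.ndarray
    demean_iterations: int
    df_model_total: int
    cluster: str | None = None
    name: str = ""
    extras: dict = field(default_factory=dict)

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.se

    @property
    def pvalues(self) -> pd.Series:
        # t reference distribution with G-1 degrees of freedom
        df = max(self.n_clusters - 1, 1)
        return pd.Series(
            2 * stats.t.sf(np.abs(self.tvalues), df), index=self.params.index
        )

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + level / 2)
        return pd.DataFrame(
            {"lower": self.params - z * self.se, "upper": self.params + z * self.se}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.params, "se": self.se, "pvalue": self.pvalues}
        )


def _demean(arr: np.ndarray, codes: list[np.ndarray], n_levels: list[int]) -> tuple[np.ndarray, int]:
    """Alternating projections onto the orthocomplement of each factor.

    Sweeps until every factor's within-group means are below DEMEAN_TOL in
    absolute value; one factor converges in a single sweep.
    """
    x = arr.astype(float, copy=True)
    if not codes:
        return x - x.mean(axis=0), 0
    for sweep in range(1, DEMEAN_MAX_SWEEPS + 1):
        max_dev = 0.0
        for code, L in zip(codes, n_levels):
            counts = np.bincount(code, minlength=L).astype(float)
            for j in range(x.shape[1]):
                means = np.bincount(code, weights=x[:, j], minlength=L) / counts
                dev = np.abs(means).max()
                if dev > max_dev:
                    max_dev = dev
                x[:, j] -= means[code]
        if max_dev < DEMEAN_TOL:
            return x, sweep
    raise RuntimeError(
        f"demeaning did not converge in {DEMEAN_MAX_SWEEPS} sweeps "
        f"(last deviation {max_dev:.3e})"
    )


def fit_fe_ols(
    data: pd.DataFrame,
    outcome: str,
    regressors: Sequence[str],
    absorb: Sequence[str] = (),
    cluster: str | None = None,
    name: str = "",
) -> FEFit:
    """Least squares of ``outcome`` on ``regressors``, absorbing factors.

    Equivalent to the dummy-variable regression on all absorbed factor
    levels; the absorbed intercepts are projected out by iterative
    demeaning rather than estimated.  When nothing is absorbed a constant
    is included (named ``const``).

    Clustered variance is the CR1 sandwich
    ``G/(G-1) * (n-1)/(n-k) * (X'X)^-1 (Σ_g X_g'u_g u_g'X_g) (X'X)^-1``
    where ``k`` counts explicit regressors plus absorbed degrees of freedom.
    """
    regressors = list(regressors)
    cols = [outcome] + regressors + list(absorb) + ([cluster] if cluster else [])
    df = data[list(dict.fromkeys(cols))].copy()
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValidationError(f"missing values in columns {bad}")
    n = len(df)
    if n <= len(regressors):
        raise ValidationError("more regressors than observations")

    codes, n_levels = [], []
    for f in absorb:
        code, levels = pd.factorize(df[f], sort=True)
        codes.append(code)
        n_levels.append(len(levels))

    y = df[outcome].to_numpy(dtype=float)
    X = df[regressors].to_numpy(dtype=float) if regressors else np.empty((n, 0))

    add_const = not absorb
    if add_const:
        X = np.column_stack([np.ones(n), X])
        names = ["const"] + regressors
    else:
        names = list(regressors)

    stacked = np.column_stack([y, X])
    if absorb:
        stacked, sweeps = _demean(stacked, codes, n_levels)
    else:
        sweeps = 0
    yt, Xt = stacked[:, 0], stacked[:, 1:]
    if add_const:
        # the constant column must survive demeaning-free path
        Xt[:, 0] = 1.0

    k = Xt.shape[1]
    if k == 0:
        raise ValidationError("no regressors to estimate")
    # rank check with pivoted QR so collinear columns can be named
    _, R, piv = linalg.qr(Xt, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Xt.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < k:
        bad = [names[j] for j in piv[rank:]]
        raise RankDeficientError(bad)

    XtX = Xt.T @ Xt
    beta = np.linalg.solve(XtX, Xt.T @ yt)
    resid = yt - Xt @ beta

    df_absorbed = (1 + sum(L - 1 for L in n_levels)) if absorb else 0
    k_total = len(regressors) + (1 if add_const else 0) + df_absorbed

    if cluster is None:
        # HC1-style fallback (no clustering requested)
        meat = (Xt * resid[:, None] ** 2).T @ Xt
        corr = n / max(n - k_total, 1)
        G = n
    else:
        gcodes, glevels = pd.factorize(df[cluster], sort=True)
        G = len(glevels)
        if G < 2:
            raise ValidationError("clustered errors need at least 2 clusters")
        Xu = Xt * resid[:, None]
        sums = np.zeros((G, k))
        np.add.at(sums, gcodes, Xu)
        meat = sums.T @ sums
        corr = (G / (G - 1)) * ((n - 1) / max(n - k_total, 1))

    XtX_inv = np.linalg.inv(XtX)
    V = corr * XtX_inv @ meat @ XtX_inv
    se = np.sqrt(np.diag(V))

    ssr = float(resid @ resid)
    yd = yt - yt.mean()
    tss_within = float(yd @ yd)
    y0 = y - y.mean()
    tss_overall = float(y0 @ y0)
    r2_within = 1.0 - ssr / tss_within if tss_within > 0 else np.nan
    r2_overall = 1.0 - ssr / tss_overall if tss_overall > 0 else np.nan

    return FEFit(
        params=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        nobs=n,
        n_clusters=G,
        r2_within=r2_within,
        r2_overall=r2_overall,
        absorbed=tuple(absorb),
        residuals=resid,
        demean_iterations=sweeps,
        df_model_total=k_total,
        cluster=cluster,
        name=name,
    )


# ---------------------------------------------------------------------------
# study specifications
# ---------------------------------------------------------------------------

def _ln_frailty(frailty: pd.DataFrame) -> pd.DataFrame:
    d = frailty["frailty"].to_numpy(dtype=float)
    if (d <= 0).any():
        raise DomainError("frailty must be strictly positive to take logs")
    out = frailty.copy()
    out["ln_deficits"] = np.log(d)
    return out


def fit_age_gradient(frailty: pd.DataFrame, sex: str) -> FEFit:
    """Growth rate of deficits in age: ln d on the age-group index.

    Absorbs country and period fixed effects; clusters by country.  The
    coefficient ``age`` is the log-deficit increase per five-year age group;
    ``extras["annual_rate"]`` divides it by 5.
    """
    sub = frailty[frailty["sex"] == sex]
    if sub.empty:
        raise ValidationError(f"no rows for sex {sex!r}")
    sub = _ln_frailty(sub)
    sub["age"] = sub["age_group"].map(fr.age_group_position).astype(float)
    fit = fit_fe_ols(
        sub, "ln_deficits", ["age"], absorb=["country", "period"],
        cluster="country", name=f"age_gradient[{sex}]",
    )
    fit.extras["annual_rate"] = float(fit.params["age"]) / 5.0
    return fit


def fit_mortality_elasticity(
    frailty: pd.DataFrame,
    mortality: pd.DataFrame,
    sex: str,
    with_country_fe: bool = True,
    with_period_fe: bool = True,
    with_age_fe: bool = False,
) -> FEFit:
    """Elasticity of mortality w.r.t. the frailty index (log-log power law).

    With age fixed effects the slope is the effect of deficits on mortality
    at given chronological age.  Clusters by country.
    """
    fsub = frailty[frailty["sex"] == sex]
    msub = mortality[mortality["sex"] == sex]
    merged = fsub.merge(msub, on=fr.CELL_KEYS, how="inner", validate="one_to_one")
    n_expect = max(len(fsub), len(msub))
    if len(merged) < n_expect:
        probe = fsub.merge(msub, on=fr.CELL_KEYS, how="outer", indicator=True)
        odd = probe[probe["_merge"] != "both"]
        examples = [tuple(r) for r in odd[fr.CELL_KEYS].head(3).itertuples(index=False)]
        raise ValidationError(f"unmatched frailty/mortality cells, e.g. {examples}")
    if merged.empty:
        raise ValidationError(f"no matched cells for sex {sex!r}")
    m = merged["mortality"].to_numpy(dtype=float)
    if (m <= 0).any():
        raise DomainError("mortality rates must be strictly positive")
    merged = _ln_frailty(merged)
    merged["ln_mortality"] = np.log(m)
    absorb = []
    if with_country_fe:
        absorb.append("country")
    if with_period_fe:
        absorb.append("period")
    if with_age_fe:
        absorb.append("age_group")
    return fit_fe_ols(
        merged, "ln_mortality", ["ln_deficits"], absorb=absorb,
        cluster="country", name=f"mortality_elasticity[{sex}]",
    )


def fit_period_effects(
    frailty: pd.DataFrame,
    age_lo: str = "20-24",
    age_hi: str = "90-94",
    grouping: dict[str, str] | None = None,
    group: str | None = None,
    base_period: int | None = None,
) -> FEFit:
    """Percent change in period life-cycle deficits relative to the baseline.

    Regresses ln cell frailty (both sexes pooled) on period dummies with
    the earliest period omitted, over the requested age range; coefficients
    are log-point (≈ percent/100) increases from the baseline.  Clusters by
    country.  ``grouping``/``group`` restrict the sample to one country
    group.
    """
    groups = fr.age_range(age_lo, age_hi)
    sub = frailty[frailty["age_group"].isin(groups)].copy()
    if grouping is not None:
        if group is None:
            raise ValidationError("group label required when grouping is supplied")
        members = {c for c, g in grouping.items() if g == group}
        if not members:
            raise ValidationError(f"group {group!r} not present in grouping")
        sub = sub[sub["country"].isin(members)]
        if sub.empty:
            raise ValidationError(f"group {group!r} matches no countries in the panel")
    periods = sorted(sub["period"].unique())
    base = base_period if base_period is not None else (min(periods) if periods else None)
    if base not in periods:
        raise ValidationError(f"baseline period {base} not present in the panel")
    sub = _ln_frailty(sub)
    dummy_cols = []
    for t in periods:
        if t == base:
            continue
        col = f"period_{t}"
        sub[col] = (sub["period"] == t).astype(float)
        dummy_cols.append(col)
    fit = fit_fe_ols(
        sub, "ln_deficits", dummy_cols, absorb=(), cluster="country",
        name=f"period_effects[{age_lo}..{age_hi}" + (f",{group}" if group else "") + "]",
    )
    fit.extras["base_period"] = base
    fit.extras["age_range"] = (age_lo, age_hi)
    return fit


GROWTH_SPECS = ("none", "convergence", "benchmark")


def fit_growth_model(
    econ: pd.DataFrame,
    frailty_workforce: pd.DataFrame,
    spec: str = "benchmark",
    countries: Iterable[str] | None = None,
    long_difference: bool = False,
) -> FEFit:
    """GDP-per-worker elasticity of workforce frailty.

    ``spec`` selects the control set: ``"none"`` (country and period FE
    only), ``"convergence"`` (+ initial log GDP × period dummies),
    ``"benchmark"`` (+ working-age composition shares, 20–24 omitted).
    ``countries`` restricts the sample; ``long_difference`` first-differences
    the earliest and latest periods instead of absorbing fixed effects.
    """
    if spec not in GROWTH_SPECS:
        raise ValidationError(f"unknown spec {spec!r}; choose from {GROWTH_SPECS}")
    from .synthetic import SHARE_BINS, SHARE_CONTROLS  # schema constants

    wf = frailty_workforce.rename(columns={"frailty": "wf_frailty"})
    df = econ.merge(wf[["country", "period", "wf_frailty"]],
                    on=["country", "period"], how="left", validate="one_to_one")
    if df["wf_frailty"].isna().any():
        miss = df[df["wf_frailty"].isna()].iloc[0]
        raise ValidationError(
            f"workforce frailty missing for ({miss['country']}, {miss['period']})")
    if countries is not None:
        keep = set(countries)
        df = df[df["country"].isin(keep)]
        if df.empty:
            raise ValidationError("country filter removed every observation")

    periods = sorted(df["period"].unique())
    per_country = df.groupby("country")["period"].nunique()
    if per_country.nunique() != 1 or per_country.iloc[0] != len(periods):
        bad = per_country[per_country != len(periods)].index.tolist()[:3]
        raise BalancedPanelError(f"unbalanced panel; e.g. countries {bad}")

    share_cols = list(SHARE_BINS)
    ssum = df[share_cols].sum(axis=1)
    if (np.abs(ssum - 1.0) > 1e-6).any():
        i = int(np.abs(ssum - 1.0).idxmax())
        raise ValidationError(
            f"age shares must sum to 1 (±1e-6); row {i} sums to {ssum[i]:.8f}")

    df["ln_gdp"] = np.log(df["gdp_pw"].to_numpy(dtype=float))
    df["ln_deficits"] = np.log(df["wf_frailty"].to_numpy(dtype=float))

    if long_difference:
        t0, t1 = periods[0], periods[-1]
        a = df[df["period"] == t0].set_index("country")
        b = df[df["period"] == t1].set_index("country").loc[a.index]
        ld = pd.DataFrame({
            "country": a.index,
            "d_ln_gdp": b["ln_gdp"].to_numpy() - a["ln_gdp"].to_numpy(),
            "d_ln_deficits": b["ln_deficits"].to_numpy() - a["ln_deficits"].to_numpy(),
            "ln_gdp_initial": a["ln_gdp_initial"].to_numpy(),
        })
        regs = ["d_ln_deficits"]
        if spec in ("convergence", "benchmark"):
            regs.append("ln_gdp_initial")
        if spec == "benchmark":
            for col in SHARE_CONTROLS:
                ld[f"d_{col}"] = b[col].to_numpy() - a[col].to_numpy()
                regs.append(f"d_{col}")
        fit = fit_fe_ols(ld, "d_ln_gdp", regs, absorb=(), cluster="country",
                         name=f"growth_long_difference[{spec}]")
        fit.params = fit.params.rename({"d_ln_deficits": "ln_deficits"})
        fit.se = fit.se.rename({"d_ln_deficits": "ln_deficits"})
        fit.extras["long_difference"] = (t0, t1)
        return fit

    regs = ["ln_deficits"]
    if spec in ("convergence", "benchmark"):
        for t in periods[1:]:
            col = f"lny0_x_{t}"
            df[col] = df["ln_gdp_initial"] * (df["period"] == t).astype(float)
            regs.append(col)
    if spec == "benchmark":
        regs.extend(SHARE_CONTROLS)
    fit = fit_fe_ols(
        df, "ln_gdp", regs, absorb=["country", "period"], cluster="country",
        name=f"growth[{spec}]",
    )
    fit.extras["spec"] = spec
    return fit
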