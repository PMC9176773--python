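"""Fixed-effects engine and the four study regressions.

The engine is cross-checked against explicit dummy-variable OLS fitted by
statsmodels (an independent route to the same least-squares solution),
including the cluster-robust covariance.
"""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import macrofrailty as mf
from macrofrailty.exceptions import (
    BalancedPanelError,
    DomainError,
    RankDeficientError,
    ValidationError,
)


def _dummy_ols(df, outcome, regressors, factors, cluster=None, cov="cluster"):
    """Oracle: the same regression with explicit factor dummies."""
    X = df[regressors].copy()
    for f in factors:
        X = pd.concat([X, pd.get_dummies(df[f], prefix=f, drop_first=True,
                                         dtype=float)], axis=1)
    X = sm.add_constant(X)
    model = sm.OLS(df[outcome].to_numpy(dtype=float), X.to_numpy(dtype=float))
    if cluster is not None and cov == "cluster":
        res = model.fit(cov_type="cluster",
                        cov_kwds={"groups": df[cluster].to_numpy()})
    elif cov == "HC1":
        res = model.fit(cov_type="HC1")
    else:
        res = model.fit()
    params = pd.Series(res.params[1:1 + len(regressors)], index=regressors)
    ses = pd.Series(res.bse[1:1 + len(regressors)], index=regressors)
    return params, ses


def _random_panel(seed, n_units=3, n_periods=3, n_x=2):
    rng = np.random.default_rng(seed)
    rows = []
    for u in range(n_units):
        for t in range(n_periods):
            x = rng.normal(size=n_x)
            y = 1.0 + x @ np.arange(1, n_x + 1) + 0.5 * u - 0.3 * t + rng.normal()
            rows.append({"unit": f"u{u}", "time": t, "y": y,
                         **{f"x{j}": x[j] for j in range(n_x)}})
    return pd.DataFrame(rows)


class TestFEEngine:
    def test_noiseless_unit_shifts_recover_slope_exactly(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "unit": np.repeat(list("abcd"), 10),
            "x": rng.normal(size=40),
        })
        df["y"] = 1.0 + 2.0 * df["x"] + df["unit"].map(
            {"a": 0.0, "b": 1.0, "c": -2.0, "d": 5.0})
        fit = mf.fit_fe_ols(df, "y", ["x"], absorb=["unit"], cluster="unit")
        assert fit.params["x"] == pytest.approx(2.0, abs=1e-12)
        assert np.allclose(fit.residuals, 0.0, atol=1e-10)

    @pytest.mark.parametrize("absorb", [["unit"], ["unit", "time"]])
    def test_matches_dummy_variable_oracle(self, absorb):
        """Alternating-projection demeaning equals explicit dummy OLS:
        identical coefficients (1e-10) and identical CR1 clustered SEs."""
        df = _random_panel(seed=42, n_units=5, n_periods=4)
        fit = mf.fit_fe_ols(df, "y", ["x0", "x1"], absorb=absorb, cluster="unit")
        params, ses = _dummy_ols(df, "y", ["x0", "x1"], absorb, cluster="unit")
        assert np.allclose(fit.params[["x0", "x1"]], params, atol=1e-10)
        assert np.allclose(fit.se[["x0", "x1"]], ses, rtol=1e-8)

    def test_singleton_clusters_degenerate_to_hc1(self):
        """With every observation its own cluster, the CR1 sandwich equals
        the HC1 heteroskedasticity-robust covariance."""
        df = _random_panel(seed=3, n_units=6, n_periods=4)
        df["obs"] = np.arange(len(df))
        fit = mf.fit_fe_ols(df, "y", ["x0", "x1"], absorb=(), cluster="obs")
        _, ses = _dummy_ols(df, "y", ["x0", "x1"], [], cov="HC1")
        # statsmodels HC1 uses n/(n-k); CR1 with G=n gives the same factor
        assert np.allclose(fit.se[["x0", "x1"]], ses, rtol=1e-8)

    def test_collinear_columns_are_named(self):
        df = _random_panel(seed=1)
        df["x_dup"] = df["x0"] * 2.0
        with pytest.raises(RankDeficientError) as err:
            mf.fit_fe_ols(df, "y", ["x0", "x1", "x_dup"], absorb=["unit"],
                          cluster="unit")
        assert set(err.value.columns) & {"x0", "x_dup"}

    def test_single_cluster_rejected(self):
        df = _random_panel(seed=1)
        df["one"] = "all"
        with pytest.raises(ValidationError, match="cluster"):
            mf.fit_fe_ols(df, "y", ["x0"], absorb=["time"], cluster="one")

    def test_r2_within_unit_interval_and_nobs(self):
        df = _random_panel(seed=9, n_units=6, n_periods=5)
        fit = mf.fit_fe_ols(df, "y", ["x0", "x1"], absorb=["unit", "time"],
                            cluster="unit")
        assert fit.nobs == len(df)
        assert 0.0 <= fit.r2_within <= 1.0
        assert 0.0 <= fit.r2_overall <= 1.0
        assert (fit.se >= 0).all()


class TestAgeGradient:
    def test_noiseless_recovery_is_exact(self, noiseless_world):
        for sex in mf.SEXES:
            fit = mf.fit_age_gradient(noiseless_world["frailty"], sex)
            truth = noiseless_world["config"].mu5[sex]
            assert fit.params["age"] == pytest.approx(truth, abs=1e-10)
            assert fit.extras["annual_rate"] == pytest.approx(truth / 5, abs=1e-10)

    def test_age_invariant_frailty_gives_zero_slope(self):
        rows = [("A", 1990, "female", g, 0.1) for g in mf.AGE_GROUPS]
        rows += [("B", 1990, "female", g, 0.2) for g in mf.AGE_GROUPS]
        fp = pd.DataFrame(rows, columns=mf.frailty.CELL_KEYS + ["frailty"])
        fit = mf.fit_age_gradient(fp, "female")
        assert fit.params["age"] == pytest.approx(0.0, abs=1e-12)

    def test_stochastic_recovery_within_three_se(self, small_world):
        fit = mf.fit_age_gradient(small_world["frailty"], "female")
        truth = small_world["config"].mu5["female"]
        assert abs(fit.params["age"] - truth) < 3 * fit.se["age"]

    def test_nonpositive_frailty_rejected(self, small_world):
        bad = small_world["frailty"].copy()
        bad.loc[bad.index[0], "frailty"] = 0.0
        with pytest.raises(DomainError):
            mf.fit_age_gradient(bad, bad.loc[bad.index[0], "sex"])


class TestMortalityElasticity:
    def test_noiseless_no_fe_recovers_power_law_exactly(self, noiseless_world):
        cfg = noiseless_world["config"]
        mort = mf.generate_mortality_panel(noiseless_world["frailty"], cfg)
        fit = mf.fit_mortality_elasticity(
            noiseless_world["frailty"], mort, "female",
            with_country_fe=False, with_period_fe=False, with_age_fe=False)
        assert fit.params["ln_deficits"] == pytest.approx(
            cfg.mortality_beta["female"], abs=1e-9)
        assert fit.params["const"] == pytest.approx(
            cfg.mortality_const["female"], abs=1e-8)

    def test_elasticity_given_age_recovered_with_all_fe(self):
        """With additive age effects in the mortality law, the slope under
        country+period+age FE is the conditional elasticity, not the raw
        power-law exponent."""
        cfg = mf.GeneratorConfig(
            n_countries=30, seed=12,
            mortality_beta={"female": 1.551, "male": 0.999},
            mortality_const={"female": -0.801, "male": -2.056},
            mortality_age_effects=tuple(0.2 * i for i in range(15)),
        )
        prev, _, _ = mf.generate_prevalence_panel(cfg)
        fp = mf.build_frailty_panel(prev)
        mort = mf.generate_mortality_panel(fp, cfg)
        fit = mf.fit_mortality_elasticity(fp, mort, "female", True, True, True)
        assert abs(fit.params["ln_deficits"] - 1.551) < 3 * fit.se["ln_deficits"]

    def test_zero_elasticity_not_rejected(self, small_config):
        cfg = small_config.replace(mortality_beta={"female": 0.0, "male": 0.0})
        prev, _, _ = mf.generate_prevalence_panel(cfg)
        fp = mf.build_frailty_panel(prev)
        mort = mf.generate_mortality_panel(fp, cfg)
        fit = mf.fit_mortality_elasticity(fp, mort, "female", True, True, False)
        assert abs(fit.params["ln_deficits"]) < 3 * fit.se["ln_deficits"]

    def test_unmatched_cells_reported(self, small_world):
        cfg = small_world["config"]
        mort = mf.generate_mortality_panel(small_world["frailty"], cfg)
        with pytest.raises(ValidationError, match="unmatched"):
            mf.fit_mortality_elasticity(
                small_world["frailty"], mort.iloc[5:], "female")

    def test_scale_equivariance_of_elasticity(self, small_world):
        """Rescaling all frailty values moves intercepts only; the log-log
        elasticity is unchanged."""
        cfg = small_world["config"]
        mort = mf.generate_mortality_panel(small_world["frailty"], cfg)
        base = mf.fit_mortality_elasticity(small_world["frailty"], mort, "male")
        scaled = small_world["frailty"].copy()
        scaled["frailty"] = scaled["frailty"] * 1.7
        refit = mf.fit_mortality_elasticity(scaled, mort, "male")
        assert refit.params["ln_deficits"] == pytest.approx(
            base.params["ln_deficits"], abs=1e-9)


class TestPeriodEffects:
    def test_group_mean_oracle(self, small_world):
        """Each period coefficient equals mean(ln d | t) - mean(ln d | base)
        exactly — the dummy regression is the difference of group means."""
        fp = small_world["frailty"]
        fit = mf.fit_period_effects(fp, "20-24", "90-94")
        lnd = np.log(fp["frailty"])
        base = lnd[fp["period"] == 1990].mean()
        for t in (1995, 2005, 2019):
            expect = lnd[fp["period"] == t].mean() - base
            assert fit.params[f"period_{t}"] == pytest.approx(expect, abs=1e-12)

    def test_zero_drift_noiseless_effects_vanish(self, noiseless_world):
        fit = mf.fit_period_effects(noiseless_world["frailty"])
        dummies = [p for p in fit.params.index if p.startswith("period_")]
        assert np.allclose(fit.params[dummies], 0.0, atol=1e-12)

    def test_configured_drift_recovered(self):
        cfg = mf.GeneratorConfig(n_countries=40, sd_period=0.0,
                                 sd_country_period=0.0, seed=21)
        prev, _, _ = mf.generate_prevalence_panel(cfg)
        fp = mf.build_frailty_panel(prev)
        fit = mf.fit_period_effects(fp, "20-24", "90-94")
        assert abs(fit.params["period_2019"] - 0.02) < 3 * fit.se["period_2019"]

    def test_missing_group_label_rejected(self, small_world):
        with pytest.raises(ValidationError, match="nowhere"):
            mf.fit_period_effects(small_world["frailty"],
                                  grouping={"C00": "somewhere"}, group="nowhere")


@pytest.fixture(scope="module")
def growth_world():
    cfg = mf.GeneratorConfig(n_countries=60, seed=31)
    prev, pop, truth = mf.generate_prevalence_panel(cfg)
    fp = mf.build_frailty_panel(prev)
    econ = mf.generate_econ_panel(fp, pop, cfg)
    keep = list(cfg.econ_periods)
    wf = mf.workforce_index(fp[fp.period.isin(keep)], pop[pop.period.isin(keep)])
    return {"config": cfg, "econ": econ, "wf": wf}


class TestGrowthModel:
    def test_benchmark_recovers_elasticity(self, growth_world):
        fit = mf.fit_growth_model(growth_world["econ"], growth_world["wf"],
                                  spec="benchmark")
        truth = growth_world["config"].gamma
        assert abs(fit.params["ln_deficits"] - truth) < 3 * fit.se["ln_deficits"]

    def test_zero_elasticity_not_rejected(self):
        cfg = mf.GeneratorConfig(n_countries=40, gamma=0.0, seed=17)
        prev, pop, _ = mf.generate_prevalence_panel(cfg)
        fp = mf.build_frailty_panel(prev)
        econ = mf.generate_econ_panel(fp, pop, cfg)
        keep = list(cfg.econ_periods)
        wf = mf.workforce_index(fp[fp.period.isin(keep)], pop[pop.period.isin(keep)])
        fit = mf.fit_growth_model(econ, wf, spec="benchmark")
        assert abs(fit.params["ln_deficits"]) < 3 * fit.se["ln_deficits"]

    def test_matches_dummy_variable_oracle(self, growth_world):
        econ, wf = growth_world["econ"], growth_world["wf"]
        sub_countries = sorted(econ["country"].unique())[:5]
        fit = mf.fit_growth_model(econ, wf, spec="benchmark",
                                  countries=sub_countries)
        df = econ[econ["country"].isin(sub_countries)].merge(
            wf.rename(columns={"frailty": "wf"}), on=["country", "period"])
        df["ln_gdp"] = np.log(df["gdp_pw"])
        df["ln_deficits"] = np.log(df["wf"])
        regs = ["ln_deficits"]
        for t in sorted(df["period"].unique())[1:]:
            df[f"lny0_x_{t}"] = df["ln_gdp_initial"] * (df["period"] == t)
            regs.append(f"lny0_x_{t}")
        regs += list(mf.synthetic.SHARE_CONTROLS)
        params, _ = _dummy_ols(df, "ln_gdp", regs, ["country", "period"],
                               cluster="country")
        assert np.allclose(fit.params[regs], params, atol=1e-8)

    def test_long_difference_recovers_elasticity(self, growth_world):
        fit = mf.fit_growth_model(growth_world["econ"], growth_world["wf"],
                                  spec="benchmark", long_difference=True)
        truth = growth_world["config"].gamma
        assert abs(fit.params["ln_deficits"] - truth) < 3 * fit.se["ln_deficits"]
        assert fit.extras["long_difference"] == (1990, 2019)

    def test_unbalanced_panel_rejected(self, growth_world):
        econ = growth_world["econ"]
        with pytest.raises(BalancedPanelError):
            mf.fit_growth_model(econ.iloc[1:], growth_world["wf"])

    def test_bad_share_sum_rejected(self, growth_world):
        econ = growth_world["econ"].copy()
        econ.loc[econ.index[0], "share_25_34"] += 0.01
        with pytest.raises(ValidationError, match="sum to 1"):
            mf.fit_growth_model(econ, growth_world["wf"])


class TestMonteCarloCalibration:
    """Unbiasedness and SE calibration over repeated synthetic worlds."""

    N_REPS = 200

    def test_age_slope_unbiased_and_se_calibrated(self):
        cfg0 = mf.GeneratorConfig(n_countries=12, n_conditions=4)
        est, ses = [], []
        for r in range(self.N_REPS):
            cfg = cfg0.replace(seed=50_000 + r)
            prev, _, _ = mf.generate_prevalence_panel(cfg)
            fit = mf.fit_age_gradient(mf.build_frailty_panel(prev), "female")
            est.append(fit.params["age"])
            ses.append(fit.se["age"])
        est = np.asarray(est)
        bias = est.mean() - cfg0.mu5["female"]
        mc_se = est.std(ddof=1) / np.sqrt(self.N_REPS)
        assert abs(bias) < 3 * mc_se
        # empirical dispersion of the estimator vs mean reported clustered SE
        assert abs(est.std(ddof=1) - np.mean(ses)) / est.std(ddof=1) < 0.25

    def test_mortality_elasticity_unbiased(self):
        cfg0 = mf.GeneratorConfig(n_countries=12, n_conditions=4)
        est = []
        for r in range(self.N_REPS):
            cfg = cfg0.replace(seed=60_000 + r)
            prev, _, _ = mf.generate_prevalence_panel(cfg)
            fp = mf.build_frailty_panel(prev)
            mort = mf.generate_mortality_panel(fp, cfg)
            fit = mf.fit_mortality_elasticity(fp, mort, "female")
            est.append(fit.params["ln_deficits"])
        est = np.asarray(est)
        bias = est.mean() - cfg0.mortality_beta["female"]
        assert abs(bias) < 3 * est.std(ddof=1) / np.sqrt(self.N_REPS)

    def test_growth_elasticity_unbiased(self):
        cfg0 = mf.GeneratorConfig(n_countries=25, n_conditions=4)
        est = []
        for r in range(self.N_REPS):
            cfg = cfg0.replace(seed=70_000 + r)
            prev, pop, _ = mf.generate_prevalence_panel(cfg)
            fp = mf.build_frailty_panel(prev)
            econ = mf.generate_econ_panel(fp, pop, cfg)
            keep = list(cfg.econ_periods)
            wf = mf.workforce_index(fp[fp.period.isin(keep)],
                                    pop[pop.period.isin(keep)])
            fit = mf.fit_growth_model(econ, wf, spec="benchmark")
            est.append(fit.params["ln_deficits"])
        est = np.asarray(est)
        bias = est.mean() - cfg0.gamma
        assert abs(bias) < 3 * est.std(ddof=1) / np.sqrt(self.N_REPS)
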