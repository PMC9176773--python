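import pytest
from hypothesis import settings

import macrofrailty as mf

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config() -> mf.GeneratorConfig:
    """A small but fully stochastic world: 12 countries, default parameters."""
    return mf.GeneratorConfig(n_countries=12, seed=20240101)


@pytest.fixture(scope="session")
def noiseless_config() -> mf.GeneratorConfig:
    """Every random component switched off; closed forms hold exactly."""
    return mf.GeneratorConfig(
        n_countries=4,
        sd_country=0.0,
        sd_period=0.0,
        sd_country_period=0.0,
        sd_noise=0.0,
        period_drift=(0.0,) * 7,
        loading_sigma=0.0,
        sd_mort_noise=0.0,
        sd_country_gdp=0.0,
        sd_period_gdp=0.0,
        sd_gdp_noise=0.0,
        convergence_coefs=(0.0, 0.0, 0.0, 0.0),
        sd_pyramid_slope=0.0,
        sd_aging_drift=0.0,
        aging_drift=0.0,
        seed=1,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    """Generated panels for the small stochastic world."""
    prevalence, pop, truth = mf.generate_prevalence_panel(small_config)
    frailty = mf.build_frailty_panel(prevalence)
    return {
        "config": small_config,
        "prevalence": prevalence,
        "pop": pop,
        "truth": truth,
        "frailty": frailty,
    }


@pytest.fixture(scope="session")
def noiseless_world(noiseless_config):
    prevalence, pop, truth = mf.generate_prevalence_panel(noiseless_config)
    frailty = mf.build_frailty_panel(prevalence)
    return {
        "config": noiseless_config,
        "prevalence": prevalence,
        "pop": pop,
        "truth": truth,
        "frailty": frailty,
    }
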