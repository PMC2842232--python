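import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rickernoise as rn

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def m1_series():
    """A low-noise growth-rate-noise series in the stable regime (T=60)."""
    cfg = rn.SimulationConfig(
        model=rn.Model.M1,
        params=rn.RickerParams(r=0.5, k=1.0, sigma_r=0.0625, sigma_k=0.125),
        T=60,
        seed=42,
    )
    series, _ = rn.simulate_series(cfg)
    return series


@pytest.fixture(scope="session")
def small_mcmc():
    """Short chains for unit tests where only basic sanity is needed."""
    return rn.McmcConfig(n_chains=2, burn_in=600, n_iter=1200, thin=2, seed=5)


@pytest.fixture(scope="session")
def m1_train(m1_series):
    """The first 55 points: the training window for cached fits."""
    return m1_series.head(55)


@pytest.fixture(scope="session")
def m1_chains(m1_train, small_mcmc):
    """One cached M1 fit (training window) shared across tests."""
    return rn.sample_posterior(m1_train, rn.Model.M1, mcmc=small_mcmc)
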