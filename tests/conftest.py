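import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from seasonfit.model_core import ModelParams, SamplerConfig, gibbs_fit
from seasonfit.synthetic_data import GeneratorSpec, generate_series

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

# Posterior means reported for the two sexes over the 2008-2017 window;
# used as generating values throughout the synthetic studies.
MEN = ModelParams(beta0=28.98, beta1=0.029, eta1=-1.540, eta2=-1.655, rho=0.356, sigma_eps=1.0)
WOMEN = ModelParams(beta0=24.07, beta1=0.073, eta1=-1.502, eta2=-2.463, rho=0.415, sigma_eps=1.0)


@pytest.fixture(scope="session")
def men_params() -> ModelParams:
    return MEN


@pytest.fixture(scope="session")
def women_params() -> ModelParams:
    return WOMEN


@pytest.fixture(scope="session")
def men_series():
    """One 120-month synthetic series at the men's parameter values."""
    return generate_series(GeneratorSpec(MEN, n_months=120, seed=20080101))


@pytest.fixture(scope="session")
def men_draws(men_series):
    """A moderate-length posterior sample shared across summary tests."""
    config = SamplerConfig(n_iterations=4000, burn_in=500, seed=11)
    return gibbs_fit(men_series, config)
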