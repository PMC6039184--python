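import numpy as np
import pytest

from adaptcode import EnvironmentConfig, build_bank


@pytest.fixture(scope="session")
def mean_config() -> EnvironmentConfig:
    """Mean-switching environment: mu in {-1, 1}, sigma = 1, h = 0.01."""
    return EnvironmentConfig()


@pytest.fixture(scope="session")
def var_config() -> EnvironmentConfig:
    """Variance-switching environment: sigma in {1, 2}, mu = 0, h = 0.01."""
    return EnvironmentConfig(mode="variance", theta_low=1.0, theta_high=2.0,
                             fixed_mu=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


# Level banks are the expensive shared objects; fit once per session.

@pytest.fixture(scope="session")
def bank_inference_n4(mean_config):
    return build_bank(mean_config, "inference", 4, np.random.default_rng(101))


@pytest.fixture(scope="session")
def bank_reconstruction_n4(mean_config):
    return build_bank(mean_config, "reconstruction", 4, np.random.default_rng(102))


@pytest.fixture(scope="session")
def bank_inference_n3(mean_config):
    return build_bank(mean_config, "inference", 3, np.random.default_rng(103))


@pytest.fixture(scope="session")
def bank_reconstruction_n3(mean_config):
    return build_bank(mean_config, "reconstruction", 3, np.random.default_rng(104))
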