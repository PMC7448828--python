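import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from strokecea.params import load_parameters
from strokecea.synthetic import base_case_config_path, fixture_base_case, synth_life_table


@pytest.fixture(scope="session")
def base_bundle():
    """(ParameterSet, ModelSettings) from the bundled base-case config."""
    return load_parameters(base_case_config_path())


@pytest.fixture(scope="session")
def base_params(base_bundle):
    return base_bundle[0]


@pytest.fixture(scope="session")
def base_settings(base_bundle):
    return base_bundle[1]


@pytest.fixture(scope="session")
def study():
    """Complete synthetic study: base-case inputs + 4 synthetic subgroups."""
    return fixture_base_case(seed=777)


@pytest.fixture(scope="session")
def life_table():
    return synth_life_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20200825)
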