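import numpy as np
import pytest

from bsgm_popmap.scenario import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def small_config() -> ScenarioConfig:
    """A fast 32x32, 4-unit, 5-year scenario used by several suites."""
    return ScenarioConfig(rows=32, cols=32, n_units=4, years=tuple(range(2000, 2005)), seed=7)


@pytest.fixture(scope="session")
def small_scenario(small_config):
    return generate_scenario(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
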