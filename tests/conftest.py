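import numpy as np
import pytest

from nitroscape import (
    ScenarioConfig,
    default_coefficients,
    generate_grid,
)


@pytest.fixture(scope="session")
def small_grid():
    """10×10 one-degree grid in mid-latitudes."""
    return generate_grid((45.0, 55.0, 0.0, 10.0), 1.0)


@pytest.fixture(scope="session")
def abandonment_config():
    return ScenarioConfig(archetype="abandonment", seed=7)


@pytest.fixture(scope="session")
def extensification_config():
    return ScenarioConfig(archetype="extensification", seed=7)


@pytest.fixture(scope="session")
def coefficients():
    return default_coefficients()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
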