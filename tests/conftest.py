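import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from spikenav import Arena, PlaceCellPopulation, load_config

# deterministic hypothesis runs, no deadline (some properties step simulations)
settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def arena() -> Arena:
    return Arena(2.4)


@pytest.fixture(scope="session")
def baseline_cfg():
    """The baseline study conditions (21x21 cells, sigma 0.2 m, r 0.2 m)."""
    return load_config()


@pytest.fixture(scope="session")
def baseline_pop(arena) -> PlaceCellPopulation:
    return PlaceCellPopulation.from_grid(21, arena, sigma=0.2)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20230408)
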