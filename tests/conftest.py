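"""Shared fixtures: small synthetic worlds reused across test modules."""

import numpy as np
import pytest

from cranesel.simulate import (
    LandscapeConfig,
    RiverConfig,
    generate_landscape,
    generate_river,
    simulate_tracks,
)


@pytest.fixture(scope="session")
def landscape():
    """A 15 x 15 km floodplain at 100 m cells (the default conditions)."""
    return generate_landscape(LandscapeConfig(seed=11))


@pytest.fixture(scope="session")
def small_landscape():
    """A 6 x 6 km landscape the 6.7 km radius covers entirely."""
    return generate_landscape(
        LandscapeConfig(width_m=6000, height_m=6000, cell_m=100, seed=12)
    )


@pytest.fixture(scope="session")
def river():
    return generate_river(RiverConfig(seed=13))


@pytest.fixture(scope="session")
def small_river():
    return generate_river(
        RiverConfig(length_m=4000, y_start_m=500, x_center_m=3000, seed=14)
    )


@pytest.fixture(scope="session")
def track_sim(landscape, river):
    """A moderate track simulation shared by telemetry/design tests."""
    return simulate_tracks(landscape, river, n_individuals=8, n_days=12, seed=21)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
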