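import numpy as np
import pytest

from hexfire import GridSpec, LandscapeMaps, SimParams
from hexfire.landscape import gen_uniform_wind
from hexfire.windfield import build_gradient


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def baseline_params():
    return SimParams()


def south_wind_maps(rows, cols, flammability=1.0, speed=1.0):
    """Uniform landscape with the wind gradient pointing due south."""
    s, d = gen_uniform_wind(rows, cols, speed, 180.0)
    grad = build_gradient(d)
    grid = GridSpec(rows, cols)
    return LandscapeMaps(
        grid,
        np.full(grid.shape, float(flammability)),
        s.values,
        grad.values,
        np.zeros(grid.shape, dtype=bool),
    )


@pytest.fixture
def south_maps_30x30():
    return south_wind_maps(30, 30)
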