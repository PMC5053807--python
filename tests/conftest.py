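import numpy as np
import pytest

from eventmap.design import RouteConfig, RouteDesign, generate_route
from eventmap.pipeline import simulate_cohort
from eventmap.recipe import generate_pvt_recipe


@pytest.fixture(scope="session")
def route():
    return generate_route(RouteConfig(), seed=11)


@pytest.fixture(scope="session")
def toy_route():
    """4 objects on a 3-4-5 rectangle, route order 0-1-2-3, unit speed."""
    coords = np.array([[0.0, 0.0], [3.0, 0.0], [3.0, 4.0], [0.0, 4.0]])
    return RouteDesign(
        coords=coords,
        order=np.array([0, 1, 2, 3]),
        segment_durations=np.array([3.0, 4.0, 3.0]),
        teleporter_after=frozenset(),
        map_side=10.0,
    )


@pytest.fixture(scope="session")
def recipe():
    return generate_pvt_recipe(seed=7)


@pytest.fixture(scope="session")
def tiny_cohort():
    """3 subjects on an 8^3 grid with a strong implanted effect."""
    return simulate_cohort(n_subjects=3, seed=21, effect_size=-0.6, noise_sd=0.3, grid_shape=(8, 8, 8))
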