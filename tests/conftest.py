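import warnings

import numpy as np
import pytest

import streampop as sp


@pytest.fixture(autouse=True)
def _quiet_known_warnings():
    # domain-adequacy and plateau-heuristic warnings are expected noise in
    # small-grid tests; individual tests re-enable what they assert on
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def small_grid():
    return sp.SpatialGrid(50.0, 1001)


@pytest.fixture(scope="session")
def baseline_model():
    """Plateau habitat baseline: favorable core for survival (m=5) and
    reproduction (l=10), weak drift."""
    return sp.ModelSpec(
        1.0, 0.1, 1.0,
        sp.logistic_mortality(sp.plateau_profile("mortality", 5.0)),
        sp.beverton_holt(sp.plateau_profile("reproduction", 10.0)),
        sp.KernelSpec("gaussian", 0.0, 2.0),
    )


@pytest.fixture(scope="session")
def seeded_payload(small_grid):
    return sp.generate_fixtures(7, small_grid).payload


@pytest.fixture(scope="session")
def homogeneous_model():
    """Spatially homogeneous surrogate: f = -u^2 (no location-dependent
    mortality), g = 2u/(1+u), no drift."""
    return sp.ModelSpec(
        1.0, 0.0, 1.0,
        sp.logistic_mortality(sp.constant_profile(0.0)),
        sp.beverton_holt(sp.constant_profile(2.0)),
        sp.KernelSpec("gaussian", 0.0, 2.0),
    )


def interior(grid, margin):
    """Mask of nodes at least `margin` away from the domain ends."""
    return np.abs(grid.nodes) <= grid.half_width - margin
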