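import numpy as np
import pytest

from oceandark.grids import GridSpec
from oceandark.synthetic import TrendScenario, generate_kd_stack

YEARS = np.arange(2003, 2023)


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    return GridSpec(16, 16, -32.0, 32.0, -32.0, 32.0, 4.0)


@pytest.fixture(scope="session")
def linear_stack(small_grid):
    """Zero-noise stack: NW-quadrant pixels darken at +0.002 / yr."""
    slope = np.zeros(small_grid.shape)
    slope[:8, :8] = 0.002
    scenario = TrendScenario(baseline_kd=0.1, slope=slope, ar1_phi=0.0,
                             noise_sigma=0.0, years=YEARS, seed=0,
                             missing_fraction=0.0)
    return generate_kd_stack(small_grid, scenario)


@pytest.fixture(scope="session")
def years():
    return YEARS
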