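import numpy as np
import pytest

from simslipid.datacube import MassAxis
from simslipid.simulate import SimConfig


@pytest.fixture(scope="session")
def axis() -> MassAxis:
    return MassAxis()


@pytest.fixture(scope="session")
def small_axis() -> MassAxis:
    return MassAxis(100.0, 110.0, 0.05)


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    """Default study conditions (full axis, 128x128 grid, seed 1)."""
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def small_sim_config() -> SimConfig:
    """A reduced grid for image-heavy tests; lipidome and axis unchanged."""
    return SimConfig(seed=1, nx=48, ny=48, n_cells=3,
                     cell_semi_axes=(4.0, 7.0), n_control=4, n_treated=2)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
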