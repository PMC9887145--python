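import numpy as np
import pytest

from uavyield.geo import Affine, BandStack
from uavyield.synthetic import ScenarioConfig, generate_scenario, write_scenario


@pytest.fixture(scope="session")
def small_cfg():
    """A 24-plot scenario small enough for fast end-to-end runs."""
    return ScenarioConfig(n_plots=24, grid_cols=6, plot_shape=(6, 12), gap=2)


@pytest.fixture(scope="session")
def small_scenario(small_cfg):
    return generate_scenario(small_cfg, seed=7)


@pytest.fixture(scope="session")
def scenario_dir(small_scenario, tmp_path_factory):
    out = tmp_path_factory.mktemp("scenario")
    write_scenario(small_scenario, out)
    return out


@pytest.fixture
def unit_transform():
    """1 m/pixel, origin at (0, 100): pixel (row, col) center at (col+0.5, 99.5-row)."""
    return Affine(1.0, 0.0, 0.0, 0.0, -1.0, 100.0)


def uniform_stack(values: dict, shape=(4, 4), transform=None, **kw):
    """BandStack with each band spatially constant at the given value."""
    transform = transform or Affine(1.0, 0.0, 0.0, 0.0, -1.0, float(shape[0]))
    bands = {k: np.full(shape, float(v)) for k, v in values.items()}
    return BandStack(bands, transform, **kw)


@pytest.fixture
def make_uniform_stack():
    return uniform_stack
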