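import numpy as np
import pytest
import shapely

from psrb.spatial import RasterGrid, SpatialUnit
from psrb.synth import ScenarioConfig, generate_scenario


@pytest.fixture
def grid4() -> RasterGrid:
    """4x4 grid of 1..16, cell size 1, origin (0, 4)."""
    return RasterGrid(np.arange(1.0, 17.0).reshape(4, 4), cell_size=1.0, origin=(0.0, 4.0))


@pytest.fixture
def full_unit() -> SpatialUnit:
    return SpatialUnit("u_full", "full", "country", shapely.box(0, 0, 4, 4))


@pytest.fixture
def small_cfg() -> ScenarioConfig:
    return ScenarioConfig(seed=1, n_units=2, grid_shape=(10, 10), n_kba=4, n_pa=6)


@pytest.fixture
def scenario(small_cfg):
    return generate_scenario(small_cfg)
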