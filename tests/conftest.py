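import numpy as np
import pytest

from ambusim.raster import RasterGrid
from ambusim.synthetic import SyntheticSpec, generate_density, generate_friction_and_facilities, tiny_fixture


@pytest.fixture
def tiny():
    """5x5 hand-checkable region: uniform friction/density, central facility."""
    density, friction, facilities = tiny_fixture()
    return density, friction, facilities


@pytest.fixture(scope="session")
def synthetic_region():
    """A 30x30 synthetic region with towns, roads and two facilities."""
    spec = SyntheticSpec(shape=(30, 30), n_towns=5, n_roads=6, n_facilities=2, seed=42)
    density = generate_density(spec)
    friction, facilities = generate_friction_and_facilities(spec, density)
    return spec, density, friction, facilities


def make_grid(values, cell_km=1.0, nodata=float("nan"), units=""):
    values = np.asarray(values, dtype=float)
    nrows = values.shape[0]
    m = cell_km * 1000.0
    transform = (m, 0.0, 0.0, 0.0, -m, nrows * m)
    return RasterGrid(values=values, transform=transform, cell_width_km=cell_km,
                      cell_height_km=cell_km, nodata=nodata, units=units)
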