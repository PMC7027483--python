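import numpy as np
import pytest

import dairyshed as ds
from dairyshed.raster import GridSpec, RasterLayer


@pytest.fixture(scope="session")
def landscape():
    """One shared synthetic landscape for read-only tests."""
    return ds.generate_landscape(ds.LandscapeConfig(seed=7))


@pytest.fixture(scope="session")
def small_landscape():
    return ds.generate_landscape(ds.LandscapeConfig(grid_rows=32, grid_cols=32, seed=11))


@pytest.fixture(scope="session")
def feeds():
    return ds.herd.default_feeds()


@pytest.fixture()
def factors():
    return ds.EmissionFactors()


@pytest.fixture()
def km_grid():
    return GridSpec(pixel_size=1000.0)


def layer(values, grid=None, **kw):
    """Shorthand raster layer on a 1-km grid."""
    return RasterLayer(np.asarray(values, dtype=float), grid=grid or GridSpec(), **kw)


@pytest.fixture()
def make_layer():
    return layer
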