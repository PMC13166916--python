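import numpy as np
import pytest

from ugci import synthetic
from ugci.grids import GridRaster


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_landcover():
    """A 60x60 synthetic mosaic (seeded, deterministic)."""
    spec = synthetic.default_spec(seed=7, shape=(60, 60))
    return synthetic.generate_landcover(spec), spec


@pytest.fixture
def deficit_landscape():
    """A 120x120 mosaic with a 30% edge deficit and its component stack."""
    spec = synthetic.default_spec(seed=11, shape=(120, 120), edge_deficit=0.7)
    lc = synthetic.generate_landcover(spec)
    stack = synthetic.generate_components(lc, spec)
    return lc, stack, spec


def make_categorical(values, cell_size=30.0, nodata=None):
    return GridRaster(values=np.asarray(values), cell_size=cell_size,
                      nodata=nodata, categorical=True)


def make_continuous(values, cell_size=30.0, nodata=None, origin=(0.0, 0.0)):
    return GridRaster(values=np.asarray(values, dtype=float),
                      cell_size=cell_size, nodata=nodata, origin=origin,
                      categorical=False)
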