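import numpy as np
import pytest

from ovopet import EggGeometry, make_egg_phantom, make_grid
from ovopet.petsim import ScannerModel


@pytest.fixture(scope="session")
def small_egg():
    """A small egg on a compact grid, cheap enough for repeated recon tests."""
    geom = EggGeometry(semi_axes_mm=(9.0, 9.0, 2.5), shell_thickness_mm=0.0)
    grid = make_grid((32, 32, 8), 1.0)
    activity, labels, mu = make_egg_phantom(geom, 50.0, grid)
    return {"geometry": geom, "grid": grid, "activity": activity, "labels": labels, "mu": mu}


@pytest.fixture(scope="session")
def small_scanner(small_egg):
    return ScannerModel.for_grid(small_egg["grid"], n_angles=60)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
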