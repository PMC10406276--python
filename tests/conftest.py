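import numpy as np
import pytest
from hypothesis import settings

from tractent.io_core import GridGeometry, Tractogram

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")


@pytest.fixture
def grid2mm():
    """10^3 grid at 2 mm isotropic, origin at zero."""
    return GridGeometry.isotropic((10, 10, 10), 2.0)


@pytest.fixture
def grid16():
    """16^3 grid at 2 mm isotropic."""
    return GridGeometry.isotropic((16, 16, 16), 2.0)


def random_tractogram(g: GridGeometry, n_fibers: int, rng,
                      n_points: int = 40, step_mm: float = 1.0) -> Tractogram:
    """Small random-walk tractogram confined to the grid interior."""
    lo = np.asarray([0.0, 0.0, 0.0])
    hi = (np.asarray(g.shape) - 1) * g.voxel_size
    fibers = []
    for _ in range(n_fibers):
        pts = np.empty((n_points, 3))
        pts[0] = rng.uniform(lo + 2, hi - 2)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        for k in range(1, n_points):
            d = 0.8 * d + 0.2 * rng.normal(size=3)
            d /= np.linalg.norm(d)
            nxt = pts[k - 1] + step_mm * d
            pts[k] = np.clip(nxt, lo + 0.5, hi - 0.5)
            if np.any(nxt != pts[k]):
                d = -d
        fibers.append(pts)
    return Tractogram(fibers, g)
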