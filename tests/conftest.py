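import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from diffatlas.grids import VectorField


def make_smooth_velocity(shape, max_mag, seed, sigma=3.0) -> VectorField:
    """Seeded smooth random velocity field with given max component magnitude."""
    rng = np.random.default_rng(seed)
    d = len(shape)
    v = rng.normal(0.0, 1.0, (d, *shape))
    v = np.stack([gaussian_filter(c, sigma) for c in v])
    v *= max_mag / np.abs(v).max()
    return VectorField(v, "velocity")


@pytest.fixture
def smooth_velocity_2d():
    return make_smooth_velocity((32, 32), 2.0, seed=42)


@pytest.fixture
def smooth_velocity_3d():
    return make_smooth_velocity((16, 16, 16), 2.0, seed=7)
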