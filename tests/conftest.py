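import numpy as np
import pytest

from planaquant import VoxelGrid


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_grid(rng):
    """Small random float grid with unit spacing."""
    return VoxelGrid(rng.random((16, 16, 16)).astype(np.float32))


def gaussian_blob(shape, center, sigma, amplitude=1.0):
    """Analytic Gaussian blob rendered at voxel centers."""
    coords = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    d2 = sum((c - mu) ** 2 for c, mu in zip(coords, center))
    return (amplitude * np.exp(-d2 / (2.0 * sigma**2))).astype(np.float32)
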