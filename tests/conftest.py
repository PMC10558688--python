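import math

import numpy as np
import pytest

from fiberlearn.synthgen import FiberSpec, generate_fiber

FULL_SHAPE = (64, 192, 96)  # (z, y, x) voxels at 0.5 µm
SMALL_SHAPE = (32, 96, 64)


@pytest.fixture(scope="session")
def clean_fiber():
    """Noise-free, perfectly parallel fiber with the default ellipse."""
    spec = FiberSpec(sarcomere_length=2.5, semi_axes=(20, 10),
                     dispersion_kappa=math.inf, n_verniers=0, snr=math.inf)
    return generate_fiber(spec, shape=FULL_SHAPE, seed=7)


@pytest.fixture(scope="session")
def small_clean_fiber():
    spec = FiberSpec(sarcomere_length=2.5, semi_axes=(12, 7),
                     dispersion_kappa=100.0, n_verniers=0, snr=20.0)
    return generate_fiber(spec, shape=SMALL_SHAPE, seed=3)


@pytest.fixture(scope="session")
def ellipse_mask_stack():
    """Solid (20, 10) µm elliptical cross-section stack, 45 slices, 0.5 µm."""
    nz, ny, nx = 64, 45, 96
    z, x = np.meshgrid((np.arange(nz) - (nz - 1) / 2) * 0.5,
                       (np.arange(nx) - (nx - 1) / 2) * 0.5, indexing="ij")
    ell = (x / 20) ** 2 + (z / 10) ** 2 <= 1
    return np.repeat(ell[:, None, :], ny, axis=1)
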