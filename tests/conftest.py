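import numpy as np
import pytest

from ichradiomics.cohort import PhantomSpec, generate_phantom
from ichradiomics.imaging import RegionMask, VolumeGrid


@pytest.fixture(scope="session")
def phantom():
    """One default 5-mm-slice phantom (volume, mask)."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def thin_phantom():
    """A 1-mm isotropic phantom (no slab averaging)."""
    return generate_phantom(PhantomSpec(slice_thickness_mm=1.0, seed=11))


@pytest.fixture()
def random_volume():
    rng = np.random.default_rng(3)
    return VolumeGrid(rng.standard_normal((16, 16, 16)), (1.0, 1.0, 1.0))


def ball_mask(radius_vox: int = 20, spacing=(1.0, 1.0, 1.0)) -> RegionMask:
    """Digital ball of the given radius (voxel units) as an ICH mask."""
    n = 2 * radius_vox + 5
    c = (n - 1) / 2.0
    x, y, z = np.meshgrid(*([np.arange(n)] * 3), indexing="ij")
    ball = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= radius_vox**2
    return RegionMask(ball.astype(int), spacing)
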