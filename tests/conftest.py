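import numpy as np
import pytest

from thalfc.prep import BoldScan, TimeCourse


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def small_scan(rng):
    """8x8x6 random scan, 2.5 mm isotropic grid centred on the origin."""
    dims = (8, 8, 6)
    aff = np.diag([2.5, 2.5, 2.5, 1.0])
    aff[:3, 3] = -0.5 * (np.asarray(dims) - 1) * 2.5
    data = rng.normal(size=(*dims, 40))
    return BoldScan(data=data, affine=aff, tr_s=3.01, phase_name="baseline")


@pytest.fixture
def mni_like_scan(rng):
    """Grid covering the brainstem region of MNI space (for sphere ROIs)."""
    dims = (24, 28, 32)
    aff = np.diag([2.5, 2.5, 2.5, 1.0])
    aff[:3, 3] = np.array([-30.0, -60.0, -65.0])
    data = rng.normal(size=(*dims, 4))
    return BoldScan(data=data, affine=aff, tr_s=3.01)


def brute_force_sphere_count(scan, center, radius):
    """Independent oracle: enumerate every voxel and test its distance."""
    count = 0
    nx, ny, nz = scan.data.shape[:3]
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                world = scan.affine @ np.array([i, j, k, 1.0])
                if np.sum((world[:3] - np.asarray(center)) ** 2) <= radius ** 2 + 1e-9:
                    count += 1
    return count
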