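import numpy as np
import pytest

from ecmap.nifti_io import MaskGeometry, MaskedSeries


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_geometry(shape=(4, 4, 4), n_inside=None, voxel_mm=3.0, seed=0):
    """Full-grid or random-subset mask geometry on an isotropic grid."""
    inside = np.ones(shape, dtype=bool)
    if n_inside is not None:
        flat = np.zeros(int(np.prod(shape)), dtype=bool)
        idx = np.random.default_rng(seed).choice(flat.size, size=n_inside,
                                                 replace=False)
        flat[idx] = True
        inside = flat.reshape(shape)
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    return MaskGeometry.from_mask(inside, affine)


def make_series(n_voxels=20, n_timepoints=50, tr=2.0, seed=0,
                shape=(4, 4, 4)):
    if n_voxels > np.prod(shape):
        side = int(np.ceil(n_voxels ** (1 / 3)))
        shape = (side, side, side)
    geometry = make_geometry(shape=shape, n_inside=n_voxels, seed=seed)
    data = np.random.default_rng(seed).standard_normal(
        (geometry.n_voxels, n_timepoints))
    return MaskedSeries(geometry=geometry, data=data, tr_seconds=tr)


@pytest.fixture
def small_series():
    return make_series()
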