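import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from spacems.mask_io import VoxelMask
from spacems.phantom import LesionSpec, PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def make_mask(voxel_indices, shape=(10, 10, 10), affine=None, space_tag="phantom"):
    """Binary mask from a list of index triples (identity affine by default)."""
    data = np.zeros(shape, dtype=np.uint8)
    for idx in voxel_indices:
        data[tuple(idx)] = 1
    return VoxelMask(
        data=data,
        affine=np.eye(4) if affine is None else affine,
        space_tag=space_tag,
    )


@pytest.fixture
def simple_phantom():
    """One spherical lesion halfway down a 40^3 synthetic head."""
    spec = PhantomSpec(
        grid_shape=(40, 40, 40),
        sma_centre=(20.0, 20.0, 34.0),
        bs_centre=(20.0, 20.0, 6.0),
        lesions=(LesionSpec(axial_fraction=0.5, semi_axes_mm=(6.0, 6.0, 6.0)),),
    )
    mask_sets, truth = generate_phantom(spec)
    return spec, mask_sets, truth


def random_sparse_mask(rng, shape=(20, 20, 20), density=0.05):
    data = (rng.random(shape) < density).astype(np.uint8)
    return VoxelMask(data=data, affine=np.eye(4), space_tag="phantom")
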