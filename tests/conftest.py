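import numpy as np
import pytest

from srrkit.image_core import Image3D
from srrkit.phantom_sim import build_plan, make_phantom, simulate_dataset


@pytest.fixture(scope="session")
def small_phantom():
    """Coarse phantom for cheap geometric tests (24 mm cube, 1 mm voxels)."""
    return make_phantom(dims=(24, 24, 24), spacing=1.0, seed=7)


@pytest.fixture(scope="session")
def tiny_dataset(small_phantom):
    """Three orthogonal motion-free stacks of the small phantom with
    mildly anisotropic slices (1 mm in-plane, 3 mm thick)."""
    plan = build_plan("a+c+s", in_plane_spacing=1.0, thickness=3.0)
    stacks, truth = simulate_dataset(small_phantom, plan, seed=11)
    return stacks, truth


@pytest.fixture()
def random_image():
    rng = np.random.default_rng(3)
    return Image3D(rng.random((8, 8, 8)), (1.0, 1.0, 1.0))
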