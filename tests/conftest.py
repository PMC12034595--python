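import numpy as np
import pytest

from stereonav.camera import StereoRig, assemble_q
from stereonav.cloud import cloud_from_disparity
from stereonav.stereo import DisparityParams, compute_disparity
from stereonav.synthetic import make_rig, make_scene


@pytest.fixture(scope="session")
def toy_q():
    """Unit rig: f=1, principal point at origin, baseline 1 mm (T_x = -1)."""
    return assemble_q(1.0, 0.0, 0.0, 0.0, -1.0)


@pytest.fixture(scope="session")
def desk_rig() -> StereoRig:
    return make_rig("desk")


@pytest.fixture(scope="session")
def default_scene():
    """One rendered desk-scale vessel scene shared across tests."""
    return make_scene(seed=3)


@pytest.fixture(scope="session")
def default_disparity(default_scene):
    return compute_disparity(default_scene.frame, DisparityParams(max_disparity=64))


@pytest.fixture(scope="session")
def default_cloud(default_scene, default_disparity):
    return cloud_from_disparity(
        default_disparity, default_scene.rig.q_matrix, default_scene.frame.left_image
    )
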