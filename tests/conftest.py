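import numpy as np
import pytest

from endonav.camera import CameraIntrinsics
from endonav.phantom_sim import PhantomParams, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom():
    """One shared default phantom instance (generation is deterministic)."""
    return make_phantom(PhantomParams())


@pytest.fixture(scope="session")
def face_mesh(phantom):
    return phantom.face_mesh


@pytest.fixture
def intrinsics():
    """Mid-range distortion-free test camera."""
    return CameraIntrinsics(fx=800.0, fy=820.0, cx=320.0, cy=240.0,
                            width=640, height=480)


@pytest.fixture
def intrinsics_distorted():
    return CameraIntrinsics(
        fx=800.0, fy=820.0, cx=320.0, cy=240.0,
        dist=np.array([-0.2, 0.05, 0.001, -0.002, 0.01]),
        width=640, height=480,
    )
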