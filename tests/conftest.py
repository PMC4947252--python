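import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from proxhum.synthetic import HumerusParams, generate_humerus

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture(scope="session")
def coarse_bone():
    """Mean-anatomy synthetic humerus at 1.0 mm resolution (fast)."""
    params = HumerusParams(mesh_edge_length=1.0)
    return generate_humerus(params)


@pytest.fixture(scope="session")
def spherical_bone():
    """Spherical-head bone with the closed-form R=25, d=7 geometry."""
    params = HumerusParams(
        head_radius=25.0,
        neck_cut_distance=7.0,
        neck_inclination_deg=42.1,
        head_ap_scale=1.0,
        mesh_edge_length=1.0,
    )
    return generate_humerus(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(20160715)
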