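import numpy as np
import pytest

from spikehough import HoughSpec
from spikehough.network import Ht3dSnnDetector, SnnParams


@pytest.fixture(scope="session")
def small_spec():
    """Coarse space for fast SNN/reference comparisons (7 layers)."""
    return HoughSpec(48, 48, delta_d=2, delta_p=2, delta_theta=0.45, eta=3)


@pytest.fixture(scope="session")
def small_detector(small_spec):
    # delta_theta=0.45 exceeds the angular-resolution bound, so each feature
    # is seen by a single layer: one pattern spike must suffice as evidence
    return Ht3dSnnDetector(
        small_spec, SnnParams(theta_p1=4.0, theta_p2=4.0, endpoint_threshold=1.0)
    )


@pytest.fixture(scope="session")
def full_detector():
    """The default operating point on a 128x128 image (built once; reused
    by every end-to-end test because construction dominates runtime)."""
    return Ht3dSnnDetector(HoughSpec(128, 128), SnnParams())


def random_edge_image(size, n_points, seed):
    rng = np.random.default_rng(seed)
    img = np.zeros((size, size), np.uint8)
    pts = rng.integers(0, size, size=(n_points, 2))
    img[pts[:, 1], pts[:, 0]] = 1
    return img
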