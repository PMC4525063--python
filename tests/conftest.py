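import numpy as np
import pytest

from spinewell.anatomy import build_network
from spinewell.muscle import DEFAULT_MATERIALS


@pytest.fixture(scope="session")
def network():
    """Default 46-fascicle network on the synthetic geometry."""
    return build_network()


@pytest.fixture(scope="session")
def mf_material():
    return DEFAULT_MATERIALS["MF"]


@pytest.fixture()
def rng():
    return np.random.default_rng(20150805)


def random_rotation(rng):
    """Uniform-ish random proper rotation via QR of a Gaussian matrix."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def random_kinematics(rng, spread=0.08):
    """Random deformation gradient with J in [0.9, 1.1] and a unit fiber."""
    F = np.eye(3) + spread * rng.standard_normal((3, 3))
    J_target = rng.uniform(0.9, 1.1)
    F *= (J_target / np.linalg.det(F)) ** (1.0 / 3.0)
    N = rng.standard_normal(3)
    N /= np.linalg.norm(N)
    return F, N
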