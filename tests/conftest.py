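import numpy as np
import pytest

from allokit import synthdata as sd


@pytest.fixture(scope="session")
def toy_spec():
    return sd.SyntheticSpec(seed=11, n_frames=100)


@pytest.fixture(scope="session")
def toy_receptor(toy_spec):
    return sd.gen_toy_receptor(toy_spec)


@pytest.fixture(scope="session")
def toy_trajectory(toy_receptor, toy_spec):
    return sd.gen_trajectory(toy_receptor, toy_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng) -> np.ndarray:
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
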