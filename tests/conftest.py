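import numpy as np
import pytest

from iminoshift.triplet import DecomposedTable, default_lookup


@pytest.fixture(scope="session")
def decomposed():
    return DecomposedTable.default()


@pytest.fixture(scope="session")
def lookup():
    return default_lookup()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rigid(rng):
    """A random rotation matrix and translation vector."""
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q, rng.uniform(-20, 20, size=3)
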