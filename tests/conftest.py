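import numpy as np
import pytest

import osmoflux as of


@pytest.fixture(scope="session")
def registry():
    """Packaged membrane + compound constants."""
    return of.load_registry()


@pytest.fixture(scope="session")
def membrane(registry):
    return registry[0]


@pytest.fixture(scope="session")
def compounds(registry):
    return registry[1]


@pytest.fixture
def rng():
    return np.random.default_rng(20160046)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniform random proper rotation matrix (QR-based)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
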