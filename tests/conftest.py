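import numpy as np
import pytest

from memprobe.synthetic import HELIX_PHI, HELIX_PSI, build_backbone


@pytest.fixture(scope="session")
def ideal_helix_20():
    """20-residue ideal α-helical backbone."""
    return build_backbone(HELIX_PHI, HELIX_PSI, 20)


@pytest.fixture(scope="session")
def extended_20():
    """20-residue fully extended chain (φ = ψ = 180°)."""
    return build_backbone(180.0, 180.0, 20)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR with sign fix."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
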