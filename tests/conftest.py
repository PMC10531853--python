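import numpy as np
import pytest

from fogpipe.simulate import (
    SimDesign,
    simulate_experiment,
    simulate_helix_structure,
    simulate_protein_family,
)


@pytest.fixture(scope="session")
def small_experiment():
    """300-group synthetic experiment shared by read-only tests."""
    return simulate_experiment(SimDesign(n_groups=300, seed=5))


@pytest.fixture(scope="session")
def default_experiment():
    """Full default design (2000 groups), used by recovery tests."""
    return simulate_experiment(SimDesign(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def helix60():
    return simulate_helix_structure(60)


@pytest.fixture(scope="session")
def protein_family():
    return simulate_protein_family(
        120, {"c3_1": 0.02, "c3_2": 0.05, "c4_1": 0.3, "c4_2": 0.35, "c4_3": 0.4}, seed=2
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish proper rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
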