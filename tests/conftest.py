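import numpy as np
import pytest

from dirreact import fixtures as fx
from dirreact.molecule import perceive_bonds


@pytest.fixture(scope="session")
def benzene():
    return fx.make_ring_molecule(fx.FixtureSpec(n_rings=1))


@pytest.fixture(scope="session")
def benzene_bonds(benzene):
    return perceive_bonds(benzene)


@pytest.fixture(scope="session")
def chrysene():
    return fx.make_chrysene_like()


@pytest.fixture(scope="session")
def chrysene_bonds(chrysene):
    return perceive_bonds(chrysene)


@pytest.fixture
def planted_fixture():
    """One seeded random fixture with molecule and charge-state triple."""
    spec = fx.random_fixture(42)
    mol = fx.make_ring_molecule(spec)
    neutral, anion, cation = fx.plant_charge_states(mol, spec)
    return spec, mol, (neutral, anion, cation)


def random_rotation(seed: int) -> np.ndarray:
    """A proper rotation matrix drawn from a seeded RNG (QR of a Gaussian)."""
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
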