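import numpy as np
import pytest

from aimpol.system import AtomicSystem, RunConfig


@pytest.fixture
def dimer():
    """Two unlike atoms 4.5 bohr apart on the x axis, no periodicity."""
    return AtomicSystem(
        elements=("C", "N"),
        coordinates=np.array([[0.0, 0, 0], [4.5, 0, 0]]),
        lattice_vectors=np.zeros((3, 3)),
        periodic_flags=(False, False, False),
        r3_moments=np.array([14.0, 11.0]),
    )


@pytest.fixture
def isolated_atom():
    return AtomicSystem(
        elements=("C",),
        coordinates=np.zeros((1, 3)),
        lattice_vectors=np.zeros((3, 3)),
        periodic_flags=(False, False, False),
        r3_moments=np.array([14.0]),
    )


@pytest.fixture
def tight_config():
    return RunConfig(fcr_tol=1e-10)


def random_symmetric(n, seed):
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n, n))
    return 0.5 * (a + a.T), rng.standard_normal(n)
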