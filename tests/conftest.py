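import numpy as np
import pytest

from loopstate import synth


@pytest.fixture(scope="session")
def scaffold():
    return synth.make_scaffold()


@pytest.fixture(scope="session")
def scaffold_with_h():
    return synth.make_scaffold(synth.ScaffoldSpec(with_hydrogens=True))


@pytest.fixture(scope="session")
def ideal_helix():
    """9-residue ideal helix, residues 110-118, heavy atoms only."""
    return synth.make_ideal_helix(9, start_res=110)


@pytest.fixture(scope="session")
def ideal_helix_h():
    return synth.make_ideal_helix(9, start_res=110, with_hydrogens=True)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
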