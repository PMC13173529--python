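import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from oqsci import fci_space, make_fixture, solve_subspace


@pytest.fixture(scope="session")
def toy2():
    """Two-orbital, two-electron instance (4-qubit register)."""
    return make_fixture("toy2")


@pytest.fixture(scope="session")
def toy4():
    """Four-orbital, 2a+2b random decaying instance (8-qubit register)."""
    return make_fixture("toy4")


@pytest.fixture(scope="session")
def toy4_fci(toy4):
    """Dense-route FCI reference for the toy4 instance."""
    basis, ints = toy4
    dets = list(fci_space(basis))
    psi = solve_subspace(dets, ints)[0]
    return dets, psi


@pytest.fixture(scope="session")
def open_shell():
    """Three-orbital 2a+1b instance (6-qubit register), open shell."""
    return make_fixture("random", 3, 2, 1, seed=3)


def small_instances(n=6):
    """A spread of small sector shapes for oracle sweeps."""
    shapes = [(2, 1, 1), (3, 2, 1), (3, 1, 1), (4, 2, 2), (4, 3, 1), (4, 1, 2)]
    return [
        make_fixture("random", M, na, nb, seed=17 + i)
        for i, (M, na, nb) in enumerate(shapes[:n])
    ]
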