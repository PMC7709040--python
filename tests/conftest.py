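import numpy as np
import pytest

from stokesrad.chem_input import parse_molecule
from stokesrad.conformers import Conformer, ConformerEnsemble


@pytest.fixture(scope="session")
def alanine():
    return parse_molecule("CC(C(=O)O)N", "alanine")


@pytest.fixture(scope="session")
def methane():
    return parse_molecule("C", "methane")


@pytest.fixture(scope="session")
def water():
    return parse_molecule("O", "water")


def make_ensemble(energies, temperature=298.0):
    """Tiny synthetic ensemble of single-carbon conformers at given energies."""
    confs = tuple(
        Conformer(elements=("C",), coords=np.zeros((1, 3)), energy=float(e))
        for e in sorted(energies)
    )
    return ConformerEnsemble(conformers=confs, temperature=temperature)


@pytest.fixture
def two_point_conformer():
    """Two carbon atoms 10 Å apart: disjoint-spheres fixture."""
    return Conformer(
        elements=("C", "C"),
        coords=np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]]),
        energy=0.0,
    )
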