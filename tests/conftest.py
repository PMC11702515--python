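import numpy as np
import pytest

from scoper.saxs_core import default_q_grid, solvent_accessible_fraction
from scoper.structure_io import Atom, Structure
from scoper.synthetic_data import SyntheticSpec, make_pseudo_rna, plant_sites

ELEMENTS = ["C", "N", "O", "P"]


def random_structure(rng, n_atoms, box=25.0, min_sep=1.5):
    """Random atom cloud with a minimum separation (no coincident atoms)."""
    coords = []
    while len(coords) < n_atoms:
        c = rng.uniform(0, box, 3)
        if not coords or np.linalg.norm(np.array(coords) - c, axis=1).min() > min_sep:
            coords.append(c)
    atoms = [Atom(element=rng.choice(ELEMENTS), coord=c, name="X", residue_name="A",
                  residue_id=i + 1)
             for i, c in enumerate(coords)]
    return Structure(atoms, label="random")


def naive_debye(coords, F, q):
    """Independent double-loop Debye oracle: I(q) = sum_ij f_i f_j sinc(q d_ij)."""
    n = coords.shape[0]
    I = np.zeros_like(q)
    for i in range(n):
        d = np.linalg.norm(coords - coords[i], axis=1)  # (n,)
        with np.errstate(invalid="ignore"):
            snc = np.sinc(np.outer(q, d) / np.pi)  # (S, n)
        I += F[i] * (snc * F.T).sum(axis=1)
    return I


@pytest.fixture(scope="session")
def q_grid():
    return default_q_grid()


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec()


@pytest.fixture(scope="session")
def planted_system(default_spec):
    return plant_sites(make_pseudo_rna(default_spec), default_spec)


@pytest.fixture(scope="session")
def rna(planted_system):
    return planted_system.rna


@pytest.fixture(scope="session")
def rna_fractions(rna):
    return solvent_accessible_fraction(rna)
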