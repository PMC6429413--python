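import numpy as np
import pytest

from hingewatch import structio, synthetic
from hingewatch.structio import Atom, Structure


@pytest.fixture(scope="session")
def small_spec():
    """A scaled-down dimer spec shared by analysis tests."""
    return synthetic.SyntheticSpec(n_res_per_subunit=60, seed=7)


@pytest.fixture(scope="session")
def small_dimer(small_spec):
    return synthetic.make_toy_dimer(small_spec)


@pytest.fixture(scope="session")
def small_ca(small_dimer):
    return structio.select_atoms(small_dimer, "name CA")


@pytest.fixture(scope="session")
def small_modes(small_dimer, small_ca):
    """Mass-weighted ENM eigendecomposition of the small dimer's Cα network."""
    from hingewatch import nma

    h = nma.mass_weight(nma.build_enm_hessian(small_dimer, small_ca, cutoff=13.0))
    return nma.eigendecompose(h)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def toy_structure(coords, element="C", chain="A"):
    """A bare structure from raw coordinates, one pseudo-residue per atom."""
    coords = np.asarray(coords, dtype=float)
    return Structure(
        [
            Atom("CA", element, i + 1, "ALA", chain, c, structio.element_mass(element))
            for i, c in enumerate(coords)
        ]
    )


@pytest.fixture()
def octahedron():
    """Six non-collinear static atoms; rigid fits to itself are exact."""
    return np.array(
        [
            [5.0, 0, 0], [-5.0, 0, 0],
            [0, 5.0, 0], [0, -5.0, 0],
            [0, 0, 5.0], [0, 0, -5.0],
        ]
    )
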