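import numpy as np
import pytest

import cdrefine as cdr


@pytest.fixture(scope="session")
def refset48():
    """Default-sized synthetic reference basis (48 proteins, 190-240 nm)."""
    return cdr.make_reference_set(cdr.GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def refset5():
    """Small 5-protein basis for oracle comparisons."""
    return cdr.make_reference_set(cdr.GeneratorConfig(seed=2, n_references=5))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_stack(models_coords, atom_names, res_ids, res_names=None):
    """Build a biotite AtomArrayStack from explicit coordinates.

    ``models_coords``: list of (n_atoms, 3) arrays; ``atom_names`` and
    ``res_ids``: per-atom annotations shared by all models.
    """
    import biotite.structure as struc

    n_atoms = len(atom_names)
    if res_names is None:
        res_names = ["ALA"] * n_atoms
    arrays = []
    for coords in models_coords:
        a = struc.AtomArray(n_atoms)
        a.coord = np.asarray(coords, dtype=float)
        a.atom_name = np.asarray(atom_names)
        a.res_id = np.asarray(res_ids)
        a.res_name = np.asarray(res_names)
        a.chain_id = np.array(["A"] * n_atoms)
        a.element = np.array([n[0] for n in atom_names])
        a.hetero = np.zeros(n_atoms, dtype=bool)
        arrays.append(a)
    return struc.stack(arrays)
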