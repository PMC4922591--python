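"""Shared fixtures: synthetic structures and one reusable blind run."""

import numpy as np
import pytest

from enmexplore import explore, fixtures, relax, structio
from enmexplore.structio import ResidueKey, Structure


def build_structure(residues, chain_id="A"):
    """Assemble a Structure from [(resname, [(atom, element, xyz), ...]), ...]."""
    coords, names, elements, serials, atom_res, table = [], [], [], [], [], []
    if isinstance(chain_id, str):
        chain_id = [chain_id] * len(residues)
    serial = 0
    for ri, (resname, atoms) in enumerate(residues):
        table.append(ResidueKey(chain_id[ri], ri + 1, "", resname))
        for name, element, xyz in atoms:
            serial += 1
            coords.append(xyz)
            names.append(name)
            elements.append(element)
            serials.append(serial)
            atom_res.append(ri)
    return Structure(
        np.asarray(coords, dtype=float), names, elements, serials,
        np.asarray(atom_res), table,
    )


@pytest.fixture(scope="session")
def hinge():
    return fixtures.make_hinge(n_per_domain=28, target_rmsd=5.0, seed=1)


@pytest.fixture(scope="session")
def small_hinge():
    return fixtures.make_hinge(n_per_domain=20, target_rmsd=3.0, seed=2)


@pytest.fixture(scope="session")
def helix10():
    return fixtures.make_chain(10, "helix", seed=0)


@pytest.fixture(scope="session")
def blind_run(small_hinge):
    """A short blind run reused by engine and evaluation tests."""
    config = explore.ExploreConfig(
        mode="blind", DF=1.0, n_modes=3, max_generations=3,
        relax=relax.RelaxConfig(backend="fallback"), cluster_seed=7,
    )
    tree = explore.run(small_hinge.open_structure, config)
    return config, tree


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def rigidly_moved(structure, rng):
    R = random_rotation(rng)
    t = rng.uniform(-20, 20, size=3)
    return structure.with_coords(structure.coords @ R.T + t)
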