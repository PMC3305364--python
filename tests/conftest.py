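import numpy as np
import pytest

import clickchem as cc


@pytest.fixture(scope="session")
def panel() -> dict:
    """The canonical fixture panel, built once per session."""
    return {name: cc.build_fixture(name) for name in cc.PANEL_NAMES}


def random_molecule(rng: np.random.Generator, n: int, spread: float = 40.0) -> cc.Molecule:
    """A random-coordinate molecule (geometrically meaningless; used for
    round-trip and rigidity properties)."""
    elements = rng.choice(["C", "N", "O", "H", "S", "Cl"], size=n)
    atoms = [
        cc.Atom(element=str(e), coord=rng.uniform(-spread, spread, 3))
        for e in elements
    ]
    mol = cc.Molecule(atoms=atoms, label="random")
    n_bonds = int(rng.integers(0, max(n, 2)))
    for _ in range(n_bonds):
        i, j = rng.integers(0, n, 2)
        if i != j:
            mol.add_bond(int(i), int(j))
    return mol
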