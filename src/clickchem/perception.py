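"""Bond inference from 3D coordinates and graph-level chemistry queries.

PDB files of small molecules rarely carry trustworthy connectivity, so
bonds are perceived from interatomic distances against tabulated covalent
radii: atoms i and j are bonded when

    0.4 Å <= d(i, j) <= r_cov(i) + r_cov(j) + tolerance

with a 0.4 Å default tolerance. CONECT-derived bonds already present on
the molecule are kept (union). Hydrogens are capped at one bond (the
shortest wins), which suppresses spurious H···H contacts in tight
geometries.

Ring perception is bounded at ring size 8 — ample for click-relevant
chemistry — to avoid exponential cycle enumeration. No bond orders are
stored; multiplicity is inferred contextually by the functional-group
detectors (an alkyne is two bonded sp carbons, etc.).
"""

from __future__ import annotations

import numpy as np
import networkx as nx
from scipy.spatial.distance import squareform, pdist

from .elements import covalent_radius
from .structure import Molecule, _canon_bond

DEFAULT_BOND_TOLERANCE = 0.4  # Å
MIN_BOND_DISTANCE = 0.4  # Å; closer pairs are overlaps, not bonds

MAX_RING_SIZE = 8

Hybridization = str  # one of "sp", "sp2", "sp3", "other"


def infer_bonds(mol: Molecule, tolerance: float = DEFAULT_BOND_TOLERANCE) -> Molecule:
    """Return a copy of ``mol`` with distance-perceived bonds populated."""
    out = mol.copy()
    n = len(out)
    if n < 2:
        return out
    radii = np.array([covalent_radius(a.element) for a in out.atoms])
    dist = squareform(pdist(out.coords))
    cutoff = radii[:, None] + radii[None, :] + tolerance
    candidate = (dist <= cutoff) & (dist >= MIN_BOND_DISTANCE)
    inferred = {
        _canon_bond(int(i), int(j))
        for i, j in zip(*np.nonzero(np.triu(candidate, k=1)))
    }
    out.bonds |= inferred
    # cap hydrogens at one bond, keeping the shortest
    for idx, atom in enumerate(out.atoms):
        if atom.element != "H":
            continue
        partners = out.neighbors(idx)
        if len(partners) > 1:
            keep = min(partners, key=lambda j: (dist[idx, j], j))
            for j in partners:
                if j != keep:
                    out.bonds.discard(_canon_bond(idx, j))
    return out


def require_bonds(mol: Molecule) -> None:
    if len(mol) > 1 and not mol.bonds:
        raise ValueError(
            "molecule has no bonds; run infer_bonds() before graph queries"
        )


def to_graph(mol: Molecule) -> nx.Graph:
    """The molecule's bond graph with element node labels."""
    g = nx.Graph()
    for i, atom in enumerate(mol.atoms):
        g.add_node(i, element=atom.element)
    g.add_edges_from(mol.bonds)
    return g


def neighbors_of_element(mol: Molecule, atom: int, element: str) -> int:
    """How many atoms of ``element`` are bonded to ``atom``."""
    if not 0 <= atom < len(mol):
        raise IndexError(f"atom index {atom} out of range")
    return sum(1 for j in mol.neighbors(atom) if mol.atoms[j].element == element)


def first_neighbor_of_element(mol: Molecule, atom: int, element: str) -> int | None:
    """Lowest-index bonded atom of ``element``, or None."""
    if not 0 <= atom < len(mol):
        raise IndexError(f"atom index {atom} out of range")
    for j in mol.neighbors(atom):
        if mol.atoms[j].element == element:
            return j
    return None


def _angle(a: np.ndarray, center: np.ndarray, b: np.ndarray) -> float:
    """Angle a–center–b in degrees."""
    u = a - center
    v = b - center
    cosine = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosine, -1.0, 1.0))))


def hybridization(mol: Molecule, atom: int) -> Hybridization:
    """Classify an atom as sp/sp2/sp3/other from its connectivity and
    local bond angles.

    The thresholds (155° for linear sp, 350° angle-sum for trigonal sp2,
    mean angle within [115°, 128°] for a two-coordinate sp2 carbon) are
    chosen so that idealized geometries classify with a wide margin; only
    C, N, O and S are classified, everything else is "other".
    """
    if not 0 <= atom < len(mol):
        raise IndexError(f"atom index {atom} out of range")
    element = mol.atoms[atom].element
    if element not in ("C", "N", "O", "S"):
        return "other"
    nbrs = mol.neighbors(atom)
    degree = len(nbrs)
    if degree == 0:
        return "other"
    if degree == 1:
        return "sp3"
    center = mol.atoms[atom].coord
    angles = [
        _angle(mol.atoms[a].coord, center, mol.atoms[b].coord)
        for k, a in enumerate(nbrs)
        for b in nbrs[k + 1 :]
    ]
    if element == "C" and degree == 2 and max(angles) >= 155.0:
        return "sp"
    if degree == 3 and sum(angles) >= 350.0:
        return "sp2"
    if element == "C" and degree == 2 and 115.0 <= float(np.mean(angles)) <= 128.0:
        return "sp2"
    if degree <= 4:
        return "sp3"
    return "other"


def rings(mol: Molecule, max_size: int = MAX_RING_SIZE) -> list[tuple[int, ...]]:
    """All simple cycles of length <= ``max_size``, as atom-index tuples."""
    require_bonds(mol)
    g = to_graph(mol)
    return [tuple(c) for c in nx.simple_cycles(g, length_bound=max_size)]


def in_same_ring(mol: Molecule, a: int, b: int) -> bool:
    """True iff some simple cycle of length <= 8 contains both atoms."""
    for idx in (a, b):
        if not 0 <= idx < len(mol):
            raise IndexError(f"atom index {idx} out of range")
    for cycle in rings(mol):
        if a in cycle and b in cycle:
            return True
    return False


def bond_in_ring(mol: Molecule, a: int, b: int) -> bool:
    """True iff the a–b bond lies on some cycle (any size): removing it
    leaves a and b connected."""
    if not mol.bonded(a, b):
        raise ValueError(f"atoms {a} and {b} are not bonded")
    g = to_graph(mol)
    g.remove_edge(a, b)
    return nx.has_path(g, a, b)


def get_branch(mol: Molecule, anchor: int, direction: int) -> Molecule:
    """Cut the anchor–direction bond and return direction's side.

    The returned molecule contains every atom reachable from ``direction``
    without traversing the cut bond (including ``direction``, excluding
    ``anchor``), with bonds remapped. ``meta["parent_indices"]`` maps each
    branch atom back to its index in the parent molecule. Undefined for
    ring bonds.
    """
    if not mol.bonded(anchor, direction):
        raise ValueError(f"atoms {anchor} and {direction} are not bonded")
    if bond_in_ring(mol, anchor, direction):
        raise ValueError("branch undefined for ring bonds")
    g = to_graph(mol)
    g.remove_edge(anchor, direction)
    keep = sorted(nx.node_connected_component(g, direction))
    remap = {old: new for new, old in enumerate(keep)}
    branch = Molecule(
        atoms=[mol.atoms[i].copy() for i in keep],
        label=f"{mol.label}|branch" if mol.label else "branch",
        meta={"parent_indices": tuple(keep)},
    )
    for i, j in mol.bonds:
        if i in remap and j in remap:
            branch.add_bond(remap[i], remap[j])
    return branch
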