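"""Rigid-body coordinate manipulation.

All operations are pure: they return a new Molecule and leave the input
untouched. Rotations are right-handed with angles in radians. Every
operation except :func:`merge` is rigid — all intramolecular pairwise
distances are preserved.

Tether-based superposition follows the classic least-squares (Kabsch)
formulation: given atom–atom correspondences between a mobile and a
reference molecule, the rigid transform minimizing the sum of squared
tether lengths is found in closed form. With a single tether this reduces
to the pure translation zeroing that tether. Degenerate tether geometries
(e.g. two tethers, which leave a free spin about the tether axis) are
resolved deterministically by the solver's canonical decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.spatial.distance import cdist

from .structure import Molecule


@dataclass(frozen=True)
class Tether:
    """An atom–atom correspondence driving superposition: atom
    ``mobile_index`` of the mobile molecule is pulled toward atom
    ``target_index`` of the reference."""

    mobile_index: int
    target_index: int


@dataclass
class AlignmentResult:
    molecule: Molecule
    residual: float  # sum of squared tether lengths after alignment, Å²
    rotation: np.ndarray  # (3,3)
    translation: np.ndarray  # (3,)


def translate(mol: Molecule, v) -> Molecule:
    """Shift every coordinate by the vector ``v``."""
    v = np.asarray(v, dtype=float)
    if v.shape != (3,) or not np.all(np.isfinite(v)):
        raise ValueError("translation vector must be a finite 3-vector")
    out = mol.copy()
    out.set_coords(out.coords + v)
    return out


def set_atom_location(mol: Molecule, atom: int, target) -> Molecule:
    """Translate the whole molecule so atom ``atom`` lands on ``target``."""
    if not 0 <= atom < len(mol):
        raise IndexError(f"atom index {atom} out of range")
    target = np.asarray(target, dtype=float)
    return translate(mol, target - mol.atoms[atom].coord)


def _apply_rotation(mol: Molecule, R: np.ndarray, pivot: np.ndarray) -> Molecule:
    out = mol.copy()
    out.set_coords((out.coords - pivot) @ R.T + pivot)
    return out


def rotate_about_line(mol: Molecule, p1, p2, angle: float) -> Molecule:
    """Rotate about the axis through points ``p1`` -> ``p2``; points on the
    axis stay fixed."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    axis = p2 - p1
    norm = np.linalg.norm(axis)
    if norm <= 1e-6:
        raise ValueError("degenerate rotation axis: points coincide")
    R = Rotation.from_rotvec(axis / norm * angle).as_matrix()
    return _apply_rotation(mol, R, p1)


def rotate_about_bond(mol: Molecule, a: int, b: int, angle: float) -> Molecule:
    """Rotate about the axis through atoms ``a`` and ``b``."""
    if a == b:
        raise ValueError("bond axis needs two distinct atoms")
    for idx in (a, b):
        if not 0 <= idx < len(mol):
            raise IndexError(f"atom index {idx} out of range")
    return rotate_about_line(mol, mol.atoms[a].coord, mol.atoms[b].coord, angle)


def rotate_about_pivot(mol: Molecule, pivot, axis, angle: float) -> Molecule:
    """Rotate about an axis direction anchored at ``pivot``."""
    pivot = np.asarray(pivot, dtype=float)
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm <= 1e-12:
        raise ValueError("zero rotation axis")
    R = Rotation.from_rotvec(axis / norm * angle).as_matrix()
    return _apply_rotation(mol, R, pivot)


def align_by_tethers(
    mobile: Molecule, reference: Molecule, tethers: list[Tether]
) -> AlignmentResult:
    """Rigidly place ``mobile`` to minimize the sum of squared tether lengths.

    Returns the placed molecule together with the residual and the applied
    transform. A single tether yields the pure translation making that
    tether zero-length.
    """
    if not tethers:
        raise ValueError("at least one tether is required")
    for t in tethers:
        if not 0 <= t.mobile_index < len(mobile):
            raise IndexError(f"tether mobile index {t.mobile_index} out of range")
        if not 0 <= t.target_index < len(reference):
            raise IndexError(f"tether target index {t.target_index} out of range")
    P = np.array([mobile.atoms[t.mobile_index].coord for t in tethers])
    Q = np.array([reference.atoms[t.target_index].coord for t in tethers])
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    if len(tethers) == 1:
        R = np.eye(3)
    else:
        rot, _ = Rotation.align_vectors(Q - cq, P - cp)
        R = rot.as_matrix()
    translation = cq - cp @ R.T
    out = mobile.copy()
    out.set_coords(out.coords @ R.T + translation)
    placed = np.array([out.atoms[t.mobile_index].coord for t in tethers])
    residual = float(np.sum((placed - Q) ** 2))
    return AlignmentResult(out, residual, R, translation)


def merge(a: Molecule, b: Molecule) -> Molecule:
    """Concatenate two molecules; b's bond indices shift by ``len(a)``."""
    out = a.copy()
    offset = len(a)
    out.atoms.extend(atom.copy() for atom in b.atoms)
    for i, j in b.bonds:
        out.add_bond(i + offset, j + offset)
    if a.label and b.label:
        out.label = f"{a.label}+{b.label}"
    else:
        out.label = a.label or b.label
    return out


def min_intermolecular_distance(a: Molecule, b: Molecule) -> float:
    """Minimum Euclidean distance over all cross pairs of atoms, in Å."""
    if not a.atoms or not b.atoms:
        raise ValueError("min_intermolecular_distance needs two non-empty molecules")
    return float(cdist(a.coords, b.coords).min())
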