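"""Idealized product-core templates and internal-coordinate helpers.

A ReactionTemplate is a small molecule holding the idealized 3D geometry of
a product core. Ring atoms that will be superseded by reactant "handle"
atoms, and the exocyclic direction dummies used as tether targets, are
marked doomed and deleted after fragment merging.

The 1,2,3-triazole core is a planar five-ring with idealized bond lengths
(N–N 1.33 Å, N–C 1.35 Å, C–C 1.38 Å) solved onto a common circumcircle, and
exocyclic direction points 1.45 Å outward along each ring bisector. The
values are idealized, not fit to any crystal structure; downstream geometry
checks only require ring planarity and sane bonded distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import Atom, Molecule

# idealized azide geometry used when grafting an azide onto a carbon/nitrogen
AZIDE_C_N = 1.47  # Å, C–N(proximal)
AZIDE_N1_N2 = 1.24  # Å, proximal–medial
AZIDE_N2_N3 = 1.13  # Å, medial–distal
AZIDE_ANGLE_CNN = 115.0  # degrees, C–N1–N2
AZIDE_ANGLE_NNN = 172.0  # degrees, N1–N2–N3


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalize a zero vector")
    return v / n


def perp_unit(v: np.ndarray) -> np.ndarray:
    """A deterministic unit vector perpendicular to ``v``."""
    v = unit(v)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(v, ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    return unit(np.cross(v, ref))


def extend_position(
    prev: np.ndarray,
    center: np.ndarray,
    distance: float,
    angle_deg: float,
    plane_ref: np.ndarray | None = None,
) -> np.ndarray:
    """Place a new point X bonded to ``center`` with angle prev–center–X.

    The new point lies in the plane spanned by (center→prev) and
    ``plane_ref``; with no usable reference a deterministic perpendicular
    is chosen.
    """
    w = unit(np.asarray(prev, float) - np.asarray(center, float))
    if plane_ref is not None:
        ref = np.asarray(plane_ref, dtype=float)
        in_plane = ref - np.dot(ref, w) * w
        v = unit(in_plane) if np.linalg.norm(in_plane) > 1e-8 else perp_unit(w)
    else:
        v = perp_unit(w)
    theta = np.radians(angle_deg)
    direction = w * np.cos(theta) + v * np.sin(theta)
    return np.asarray(center, float) + distance * direction


@dataclass
class ReactionTemplate:
    """Idealized product core with role labels.

    ``roles`` maps role names to atom indices of ``core``; ``handle_roles``
    maps the core roles that reactant handle atoms superimpose onto to the
    reactant-side role names; ``doomed_roles`` are deleted after merging
    (they are superseded by the handles or were only direction dummies);
    ``new_bonds`` are role pairs bonded in the assembled product.
    """

    name: str
    core: Molecule
    roles: dict[str, int]
    handle_roles: dict[str, str]
    doomed_roles: tuple[str, ...]
    new_bonds: tuple[tuple[str, str], ...]

    def coord(self, role: str) -> np.ndarray:
        return self.core.atoms[self.roles[role]].coord


def _ring_on_circle(side_lengths: list[float]) -> np.ndarray:
    """Vertices of a planar polygon with the given side lengths inscribed
    in a common circle (z = 0, centroid at the origin)."""
    sides = np.asarray(side_lengths, float)

    def gap(radius: float) -> float:
        return float(np.sum(2.0 * np.arcsin(sides / (2.0 * radius))) - 2.0 * np.pi)

    lo = float(np.max(sides)) / 2.0 + 1e-9
    hi = 10.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if gap(mid) > 0:
            lo = mid
        else:
            hi = mid
    radius = 0.5 * (lo + hi)
    thetas = np.concatenate(
        ([0.0], np.cumsum(2.0 * np.arcsin(sides[:-1] / (2.0 * radius))))
    )
    pts = np.stack(
        [radius * np.cos(thetas), radius * np.sin(thetas), np.zeros_like(thetas)],
        axis=1,
    )
    return pts - pts.mean(axis=0)


def triazole_template() -> ReactionTemplate:
    """The planar 1,2,3-triazole core used by the Huisgen cycloaddition.

    Ring order N1–N2–N3–C4–C5. N1, C4 and C5 are superseded by reactant
    handles (the azide's proximal nitrogen and the two alkyne carbons);
    the exocyclic dummies E1/E4/E5 are tether targets that orient each
    fragment's handle-adjacent atom outward along the ring bisector.
    """
    sides = [1.33, 1.33, 1.35, 1.38, 1.35]  # N1N2, N2N3, N3C4, C4C5, C5N1
    ring = _ring_on_circle(sides)
    elements = ["N", "N", "N", "C", "C"]
    role_names = ["N1", "N2", "N3", "C4", "C5"]
    atoms = [
        Atom(element=el, coord=p, name=f"{el}{k + 1}")
        for k, (el, p) in enumerate(zip(elements, ring))
    ]
    roles = {name: k for k, name in enumerate(role_names)}
    exo_of = {"N1": "E1", "C4": "E4", "C5": "E5"}
    for ring_role, exo_role in exo_of.items():
        p = ring[roles[ring_role]]
        atoms.append(Atom(element="C", coord=p + 1.45 * unit(p), name=exo_role))
        roles[exo_role] = len(atoms) - 1
    core = Molecule(atoms=atoms, label="triazole_template")
    for k in range(5):
        core.add_bond(k, (k + 1) % 5)
    for ring_role, exo_role in exo_of.items():
        core.add_bond(roles[ring_role], roles[exo_role])
    return ReactionTemplate(
        name="triazole",
        core=core,
        roles=roles,
        handle_roles={"N1": "proximal_N", "C4": "alkyne_C", "C5": "alkyne_C"},
        doomed_roles=("N1", "C4", "C5", "E1", "E4", "E5"),
        new_bonds=(("N1", "N2"), ("N3", "C4"), ("C4", "C5"), ("C5", "N1")),
    )


def azide_arm_positions(
    attach: np.ndarray, n1: np.ndarray, plane_ref: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates for the medial and distal nitrogens of an azide grafted
    so its proximal nitrogen sits at ``n1`` bonded to ``attach``."""
    n2 = extend_position(attach, n1, AZIDE_N1_N2, AZIDE_ANGLE_CNN, plane_ref)
    n3 = extend_position(n1, n2, AZIDE_N2_N3, AZIDE_ANGLE_NNN, plane_ref)
    return n2, n3
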