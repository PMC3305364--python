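"""Programmatic generation of idealized 3D reactant models.

Every test and acceptance run builds its inputs here instead of shipping
data files. Molecules are assembled from idealized internal coordinates
(tetrahedral/trigonal/linear centers, standard bond lengths) with explicit
hydrogens, and are returned with perceived bonds populated.

``build_fixture`` provides a canonical panel of small named molecules;
``generate_reactant_set`` emits arbitrarily many structurally distinct
azides, terminal alkynes or alkyl bromides by decorating rooted alkyl
scaffolds (chain length 1–12, an optional methyl branch at each interior
position), which gives 2048 pairwise non-isomorphic scaffolds — enough for
library runs at the thousand-reactant scale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .perception import infer_bonds
from .structure import Atom, Molecule
from .templates import azide_arm_positions, extend_position, perp_unit, unit

# idealized bond lengths, Å
CC = 1.53
CH = 1.09
CN = 1.47
NH = 1.01
CO = 1.43
OH = 0.96
CS = 1.82
SH = 1.34
C_CL = 1.79
C_BR = 1.97
C_DBL_O = 1.22
C_DBL_C = 1.33
C_TRP_C = 1.20
CSP3_CSP = 1.46
CSP_H = 1.06
CAR = 1.39
CAR_H = 1.08
CAR_CSP3 = 1.51
CAR_CSP = 1.43

_TET = np.degrees(np.arccos(-1.0 / 3.0))  # 109.47°
_ALPHA = np.radians(0.5 * (180.0 - _TET))  # zigzag half-angle, 35.26°


class _Builder:
    """Accumulates atoms/bonds; hands out indices."""

    def __init__(self, label: str):
        self.mol = Molecule(label=label)

    def add(self, element: str, pos, *bond_to: int) -> int:
        self.mol.atoms.append(Atom(element=element, coord=np.asarray(pos, float)))
        idx = len(self.mol) - 1
        for j in bond_to:
            self.mol.add_bond(idx, j)
        return idx

    def done(self) -> Molecule:
        self.mol.validate()
        return self.mol


def _tetra_completion(u1: np.ndarray, u2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """The two unit directions completing a tetrahedral center whose other
    two bonds point along u1 and u2."""
    n = unit(np.cross(u1, u2))
    base = -0.5 * (u1 + u2)
    w_plus = unit(base + np.sqrt(2.0 / 3.0) * n)
    w_minus = unit(base - np.sqrt(2.0 / 3.0) * n)
    return w_plus, w_minus


def _terminal_dirs(u: np.ndarray, ref: np.ndarray | None = None, twist: float = 60.0):
    """Three unit directions at 109.47° from ``u`` (the direction to the
    sole existing neighbor), spaced 120° apart; ``twist`` rotates the set
    for staggered conformations."""
    u = unit(u)
    if ref is None:
        p = perp_unit(u)
    else:
        ref = np.asarray(ref, float)
        in_plane = ref - np.dot(ref, u) * u
        p = unit(in_plane) if np.linalg.norm(in_plane) > 1e-8 else perp_unit(u)
    q = np.cross(u, p)
    out = []
    for k in range(3):
        theta = np.radians(twist + 120.0 * k)
        out.append(unit(-u / 3.0 + np.sqrt(8.0) / 3.0 * (p * np.cos(theta) + q * np.sin(theta))))
    return out


# ---------------------------------------------------------------------------
# Alkyl scaffolds and head groups (shared by panel members and the
# reactant-set generator)


def _backbone(length: int) -> tuple[np.ndarray, np.ndarray]:
    """Zigzag carbon backbone in the xz plane; returns (positions, head
    direction at C1)."""
    positions = [np.zeros(3)]
    for k in range(length - 1):
        v = CC * np.array([np.cos(_ALPHA), 0.0, ((-1.0) ** k) * np.sin(_ALPHA)])
        positions.append(positions[-1] + v)
    head_dir = np.array([-np.cos(_ALPHA), 0.0, np.sin(_ALPHA)])
    return np.array(positions), head_dir


def _attach_methyl(b: _Builder, carbon: int, direction: np.ndarray, back_ref: np.ndarray) -> None:
    c_pos = b.mol.atoms[carbon].coord
    cb = b.add("C", c_pos + CC * direction, carbon)
    for d in _terminal_dirs(-direction, ref=back_ref):
        b.add("H", b.mol.atoms[cb].coord + CH * d, cb)


def _attach_head(b: _Builder, c1: int, head_dir: np.ndarray, kind: str, plane_ref: np.ndarray) -> None:
    p0 = b.mol.atoms[c1].coord
    if kind == "azide":
        n1 = b.add("N", p0 + CN * head_dir, c1)
        n2_pos, n3_pos = azide_arm_positions(p0, b.mol.atoms[n1].coord, plane_ref)
        n2 = b.add("N", n2_pos, n1)
        b.add("N", n3_pos, n2)
    elif kind == "terminal_alkyne":
        ca = b.add("C", p0 + CSP3_CSP * head_dir, c1)
        cb = b.add("C", b.mol.atoms[ca].coord + C_TRP_C * head_dir, ca)
        b.add("H", b.mol.atoms[cb].coord + CSP_H * head_dir, cb)
    elif kind == "alkyl_bromide":
        b.add("Br", p0 + C_BR * head_dir, c1)
    else:
        raise ValueError(f"unknown head kind {kind!r}")


def build_alkyl_scaffold(
    kind: str, length: int, branches: frozenset[int] = frozenset(), label: str = ""
) -> Molecule:
    """A rooted alkyl chain carrying a reactive head group at C1.

    ``branches`` holds 1-based interior backbone positions (2..length-1)
    that carry a methyl substituent; branch sides alternate with position
    parity to keep substituents clear of each other.
    """
    if length < 1:
        raise ValueError("chain length must be >= 1")
    bad = [p for p in branches if not 2 <= p <= length - 1]
    if bad:
        raise ValueError(f"branch positions {bad} are not interior (2..{length - 1})")
    b = _Builder(label or f"{kind}_L{length}")
    positions, head_dir = _backbone(length)
    carbon_idx = [b.add("C", p) for p in positions]
    for k in range(length - 1):
        b.mol.add_bond(carbon_idx[k], carbon_idx[k + 1])
    plane_ref = (
        positions[1] - positions[0] if length > 1 else np.array([1.0, 0.0, 0.0])
    )
    _attach_head(b, carbon_idx[0], head_dir, kind, plane_ref)

    for k, c in enumerate(carbon_idx):
        pos = positions[k]
        if k == 0:
            existing = [head_dir]
            if length > 1:
                existing.append(unit(positions[1] - pos))
        else:
            existing = [unit(positions[k - 1] - pos)]
            if k + 1 < length:
                existing.append(unit(positions[k + 1] - pos))
        if len(existing) == 2:
            w_plus, w_minus = _tetra_completion(existing[0], existing[1])
            site = k + 1  # 1-based backbone position
            if site in branches:
                # w_plus alternates sides with backbone parity (the cross
                # product flips), keeping neighboring branches apart
                _attach_methyl(b, c, w_plus, back_ref=existing[0])
                b.add("H", pos + CH * w_minus, c)
            else:
                b.add("H", pos + CH * w_plus, c)
                b.add("H", pos + CH * w_minus, c)
        else:
            for d in _terminal_dirs(existing[0], ref=np.array([0.0, 1.0, 0.0])):
                b.add("H", pos + CH * d, c)
    return infer_bonds(b.done())


# ---------------------------------------------------------------------------
# Ring scaffolds


def _benzene_core(b: _Builder, substituted: int = 0) -> tuple[list[int], np.ndarray]:
    """Six ring carbons in the xy plane plus hydrogens on all positions
    except ``substituted``; returns (ring indices, outward radial unit at
    the substituted carbon)."""
    ring = []
    radial_sub = np.zeros(3)
    for k in range(6):
        theta = np.radians(60.0 * k)
        radial = np.array([np.cos(theta), np.sin(theta), 0.0])
        ring.append(b.add("C", CAR * radial))
        if k == substituted:
            radial_sub = radial
    for k in range(6):
        b.mol.add_bond(ring[k], ring[(k + 1) % 6])
        if k != substituted:
            theta = np.radians(60.0 * k)
            radial = np.array([np.cos(theta), np.sin(theta), 0.0])
            b.add("H", (CAR + CAR_H) * radial, ring[k])
    return ring, radial_sub


def _benzyl(label: str, head: str) -> Molecule:
    """Benzene with a CH2–X head (X = Br or azide) or a direct C≡CH arm."""
    b = _Builder(label)
    ring, radial = _benzene_core(b)
    if head == "ethynyl":
        ca = b.add("C", b.mol.atoms[ring[0]].coord + CAR_CSP * radial, ring[0])
        cb = b.add("C", b.mol.atoms[ca].coord + C_TRP_C * radial, ca)
        b.add("H", b.mol.atoms[cb].coord + CSP_H * radial, cb)
        return infer_bonds(b.done())
    cb_pos = b.mol.atoms[ring[0]].coord + CAR_CSP3 * radial
    cb = b.add("C", cb_pos, ring[0])
    dirs = _terminal_dirs(-radial, ref=np.array([0.0, 0.0, 1.0]), twist=90.0)
    if head == "bromide":
        b.add("Br", cb_pos + C_BR * dirs[0], cb)
    elif head == "azide":
        n1 = b.add("N", cb_pos + CN * dirs[0], cb)
        n2_pos, n3_pos = azide_arm_positions(cb_pos, b.mol.atoms[n1].coord, radial)
        n2 = b.add("N", n2_pos, n1)
        b.add("N", n3_pos, n2)
    else:
        raise ValueError(head)
    for d in dirs[1:]:
        b.add("H", cb_pos + CH * d, cb)
    return infer_bonds(b.done())


# ---------------------------------------------------------------------------
# The canonical panel

_Z = np.array([0.0, 0.0, 1.0])
_X = np.array([1.0, 0.0, 0.0])
_Y = np.array([0.0, 1.0, 0.0])


def _methane() -> Molecule:
    b = _Builder("methane")
    c = b.add("C", np.zeros(3))
    for d in np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / np.sqrt(3):
        b.add("H", CH * d, c)
    return infer_bonds(b.done())


def _ethane() -> Molecule:
    b = _Builder("ethane")
    c1 = b.add("C", np.zeros(3))
    c2 = b.add("C", CC * _Z, c1)
    for d in _terminal_dirs(_Z, ref=_X, twist=0.0):
        b.add("H", CH * d, c1)
    for d in _terminal_dirs(-_Z, ref=_X, twist=60.0):
        b.add("H", CC * _Z + CH * d, c2)
    return infer_bonds(b.done())


def _ethene() -> Molecule:
    b = _Builder("ethene")
    half = C_DBL_C / 2.0
    c1 = b.add("C", -half * _X)
    c2 = b.add("C", half * _X, c1)
    theta = np.radians(180.0 - 121.5)  # H splays 121.5° from the C=C axis
    for c, sign in ((c1, -1.0), (c2, 1.0)):
        pos = b.mol.atoms[c].coord
        for updown in (1.0, -1.0):
            d = unit(sign * _X * np.cos(theta) + updown * _Y * np.sin(theta))
            b.add("H", pos + CH * d, c)
    return infer_bonds(b.done())


def _ethyne() -> Molecule:
    b = _Builder("ethyne")
    half = C_TRP_C / 2.0
    c1 = b.add("C", -half * _X)
    c2 = b.add("C", half * _X, c1)
    b.add("H", (-half - CSP_H) * _X, c1)
    b.add("H", (half + CSP_H) * _X, c2)
    return infer_bonds(b.done())


def _benzene() -> Molecule:
    b = _Builder("benzene")
    ring = []
    for k in range(6):
        theta = np.radians(60.0 * k)
        radial = np.array([np.cos(theta), np.sin(theta), 0.0])
        ring.append(b.add("C", CAR * radial))
        b.add("H", (CAR + CAR_H) * radial, ring[-1])
    for k in range(6):
        b.mol.add_bond(ring[k], ring[(k + 1) % 6])
    return infer_bonds(b.done())


def _methylamine() -> Molecule:
    b = _Builder("methylamine")
    c = b.add("C", np.zeros(3))
    n = b.add("N", CN * _Z, c)
    for d in _terminal_dirs(_Z, ref=_X, twist=0.0):
        b.add("H", CH * d, c)
    for d in _terminal_dirs(-_Z, ref=_X, twist=60.0)[:2]:
        b.add("H", CN * _Z + NH * d, n)
    return infer_bonds(b.done())


def _acetamide() -> Molecule:
    b = _Builder("acetamide")
    c1 = b.add("C", np.zeros(3))
    c2_pos = CAR_CSP3 * _X
    c2 = b.add("C", c2_pos, c1)
    o = b.add("O", extend_position(np.zeros(3), c2_pos, C_DBL_O, 121.0, _Y), c2)
    n_pos = extend_position(np.zeros(3), c2_pos, 1.35, 121.0, -_Y)
    n = b.add("N", n_pos, c2)
    b.add("H", extend_position(c2_pos, n_pos, NH, 119.0, _Y), n)
    b.add("H", extend_position(c2_pos, n_pos, NH, 119.0, -_Y), n)
    for d in _terminal_dirs(_X, ref=_Z, twist=0.0):
        b.add("H", CH * d, c1)
    return infer_bonds(b.done())


def _acid_like(label: str, leaving: str) -> Molecule:
    """CH3–C(=O)–X with X = OH (acid) or Cl (acyl chloride)."""
    b = _Builder(label)
    c1 = b.add("C", np.zeros(3))
    c2_pos = CAR_CSP3 * _X
    c2 = b.add("C", c2_pos, c1)
    b.add("O", extend_position(np.zeros(3), c2_pos, C_DBL_O, 122.0, _Y), c2)
    if leaving == "OH":
        o_pos = extend_position(np.zeros(3), c2_pos, 1.36, 113.0, -_Y)
        o2 = b.add("O", o_pos, c2)
        b.add("H", extend_position(c2_pos, o_pos, OH, 106.0, -_Y), o2)
    else:
        b.add("Cl", extend_position(np.zeros(3), c2_pos, C_CL, 112.0, -_Y), c2)
    for d in _terminal_dirs(_X, ref=_Z, twist=0.0):
        b.add("H", CH * d, c1)
    return infer_bonds(b.done())


def _ethyl_hetero(label: str, element: str) -> Molecule:
    """CH3–CH2–XH with X = S or O."""
    b = _Builder(label)
    positions, head_dir = _backbone(2)
    c1 = b.add("C", positions[0])
    c2 = b.add("C", positions[1], c1)
    dist, h_dist, angle = (CS, SH, 96.0) if element == "S" else (CO, OH, 108.0)
    x_pos = positions[0] + dist * head_dir
    x = b.add(element, x_pos, c1)
    b.add("H", extend_position(positions[0], x_pos, h_dist, angle, positions[1] - positions[0]), x)
    u_head = head_dir
    u_next = unit(positions[1] - positions[0])
    w_plus, w_minus = _tetra_completion(u_head, u_next)
    b.add("H", positions[0] + CH * w_plus, c1)
    b.add("H", positions[0] + CH * w_minus, c1)
    for d in _terminal_dirs(unit(positions[0] - positions[1]), ref=_Y, twist=0.0):
        b.add("H", positions[1] + CH * d, c2)
    return infer_bonds(b.done())


def _oxirane(methylated: bool) -> Molecule:
    b = _Builder("propylene_oxide" if methylated else "ethylene_oxide")
    half = 1.47 / 2.0
    height = float(np.sqrt(CO**2 - half**2))
    c1 = b.add("C", np.array([-half, 0.0, 0.0]))
    c2 = b.add("C", np.array([half, 0.0, 0.0]), c1)
    b.add("O", np.array([0.0, height, 0.0]), c1, c2)
    for c, sign in ((c1, -1.0), (c2, 1.0)):
        pos = b.mol.atoms[c].coord
        u1 = unit(b.mol.atoms[c2 if c == c1 else c1].coord - pos)
        u2 = unit(np.array([0.0, height, 0.0]) - pos)
        w_plus, w_minus = _tetra_completion(u1, u2)
        if methylated and c == c1:
            _attach_methyl(b, c, w_plus, back_ref=u1)
            b.add("H", pos + CH * w_minus, c)
        else:
            b.add("H", pos + CH * w_plus, c)
            b.add("H", pos + CH * w_minus, c)
    return infer_bonds(b.done())


def _glucose() -> Molecule:
    """Open-chain (aldehyde) D-glucose with idealized geometry: CHO head,
    four CHOH centers, terminal CH2OH. Hydroxyls alternate sides along the
    zigzag to stay clear of each other."""
    b = _Builder("glucose")
    positions, head_dir = _backbone(6)
    carbons = [b.add("C", p) for p in positions]
    for k in range(5):
        b.mol.add_bond(carbons[k], carbons[k + 1])
    # C1: aldehyde (sp2): =O along head direction plane, one H
    c1_pos = positions[0]
    u_next = unit(positions[1] - c1_pos)
    o1 = extend_position(positions[1], c1_pos, C_DBL_O, 121.0, head_dir)
    b.add("O", o1, carbons[0])
    b.add("H", extend_position(positions[1], c1_pos, CH, 119.0, -np.asarray(head_dir)), carbons[0])
    # C2..C5: one OH, one H, alternating sides
    for k in range(1, 5):
        pos = positions[k]
        u1 = unit(positions[k - 1] - pos)
        u2 = unit(positions[k + 1] - pos)
        w_plus, w_minus = _tetra_completion(u1, u2)
        oh_dir, h_dir = (w_plus, w_minus) if k % 2 == 1 else (w_minus, w_plus)
        o_pos = pos + CO * oh_dir
        o = b.add("O", o_pos, carbons[k])
        b.add("H", extend_position(pos, o_pos, OH, 108.0, u1), o)
        b.add("H", pos + CH * h_dir, carbons[k])
    # C6: CH2OH along one terminal direction
    u_back = unit(positions[4] - positions[5])
    dirs = _terminal_dirs(u_back, ref=_Y, twist=0.0)
    o_pos = positions[5] + CO * dirs[0]
    o = b.add("O", o_pos, carbons[5])
    b.add("H", extend_position(positions[5], o_pos, OH, 108.0, u_back), o)
    b.add("H", positions[5] + CH * dirs[1], carbons[5])
    b.add("H", positions[5] + CH * dirs[2], carbons[5])
    return infer_bonds(b.done())


def _butyne2() -> Molecule:
    b = _Builder("2-butyne")
    ca = b.add("C", -0.5 * C_TRP_C * _Z)
    cb = b.add("C", 0.5 * C_TRP_C * _Z, ca)
    cm1 = b.add("C", (-0.5 * C_TRP_C - CSP3_CSP) * _Z, ca)
    cm2 = b.add("C", (0.5 * C_TRP_C + CSP3_CSP) * _Z, cb)
    for cm, u, twist in ((cm1, _Z, 0.0), (cm2, -_Z, 60.0)):
        pos = b.mol.atoms[cm].coord
        for d in _terminal_dirs(u, ref=_X, twist=twist):
            b.add("H", pos + CH * d, cm)
    return infer_bonds(b.done())


@dataclass(frozen=True)
class FixtureSpec:
    """Declared composition for a panel member, used by connectivity
    audits: the built molecule must match exactly."""

    name: str
    formula: dict[str, int]
    n_bonds: int


_PANEL: dict[str, tuple] = {
    "methane": (_methane, {"C": 1, "H": 4}, 4),
    "ethane": (_ethane, {"C": 2, "H": 6}, 7),
    "ethene": (_ethene, {"C": 2, "H": 4}, 5),
    "ethyne": (_ethyne, {"C": 2, "H": 2}, 3),
    "benzene": (_benzene, {"C": 6, "H": 6}, 12),
    "methylamine": (_methylamine, {"C": 1, "H": 5, "N": 1}, 6),
    "acetamide": (_acetamide, {"C": 2, "H": 5, "N": 1, "O": 1}, 8),
    "acetic_acid": (lambda: _acid_like("acetic_acid", "OH"), {"C": 2, "H": 4, "O": 2}, 7),
    "acetyl_chloride": (
        lambda: _acid_like("acetyl_chloride", "Cl"),
        {"C": 2, "H": 3, "Cl": 1, "O": 1},
        6,
    ),
    "ethanethiol": (lambda: _ethyl_hetero("ethanethiol", "S"), {"C": 2, "H": 6, "S": 1}, 8),
    "ethanol": (lambda: _ethyl_hetero("ethanol", "O"), {"C": 2, "H": 6, "O": 1}, 8),
    "ethylene_oxide": (lambda: _oxirane(False), {"C": 2, "H": 4, "O": 1}, 7),
    "propylene_oxide": (lambda: _oxirane(True), {"C": 3, "H": 6, "O": 1}, 10),
    "methyl_azide": (
        lambda: build_alkyl_scaffold("azide", 1, label="methyl_azide"),
        {"C": 1, "H": 3, "N": 3},
        6,
    ),
    "benzyl_azide": (
        lambda: _benzyl("benzyl_azide", "azide"),
        {"C": 7, "H": 7, "N": 3},
        17,
    ),
    "propyne": (
        lambda: build_alkyl_scaffold("terminal_alkyne", 1, label="propyne"),
        {"C": 3, "H": 4},
        6,
    ),
    "phenylacetylene": (
        lambda: _benzyl("phenylacetylene", "ethynyl"),
        {"C": 8, "H": 6},
        14,
    ),
    "2-butyne": (_butyne2, {"C": 4, "H": 6}, 9),
    "benzyl_bromide": (
        lambda: _benzyl("benzyl_bromide", "bromide"),
        {"C": 7, "H": 7, "Br": 1},
        15,
    ),
    "glucose": (_glucose, {"C": 6, "H": 12, "O": 6}, 23),
}

PANEL_NAMES: tuple[str, ...] = tuple(_PANEL)


def fixture_spec(name: str) -> FixtureSpec:
    if name not in _PANEL:
        raise KeyError(f"unknown fixture {name!r}")
    _, formula, n_bonds = _PANEL[name]
    return FixtureSpec(name=name, formula=dict(formula), n_bonds=n_bonds)


def build_fixture(name: str) -> Molecule:
    """Build one canonical panel member (explicit H, perceived bonds)."""
    if name not in _PANEL:
        raise KeyError(f"unknown fixture {name!r}; panel: {', '.join(PANEL_NAMES)}")
    builder = _PANEL[name][0]
    return builder()


# ---------------------------------------------------------------------------
# Bulk reactant sets


def _scaffold_catalog(max_length: int = 16) -> list[tuple[int, frozenset[int]]]:
    """All (chain length, branch set) scaffolds, deterministic order.

    Branch pairs exactly two positions apart are excluded: with
    side-alternating substituents they would sit on the same side of the
    rigid all-anti backbone only 2.5 Å apart (a syn-pentane-like strain
    the builder cannot relax away).
    """
    catalog: list[tuple[int, frozenset[int]]] = []
    for length in range(1, max_length + 1):
        interior = list(range(2, length))
        for r in range(len(interior) + 1):
            for combo in itertools.combinations(interior, r):
                if any(b - a == 2 for a, b in itertools.combinations(combo, 2)):
                    continue
                catalog.append((length, frozenset(combo)))
    return catalog


def generate_reactant_set(kind: str, n: int, seed: int) -> list[Molecule]:
    """``n`` structurally distinct reactants of a requested kind.

    Scaffolds are rooted alkyl chains (head group at C1), so every
    (length, branch-set) pair is a distinct constitutional isomer. The
    catalog order is shuffled deterministically from ``seed``; the same
    seed always returns the same set. Terminal alkynes built this way are
    always non-symmetric (the far substituent is a lone hydrogen).
    """
    if kind not in ("azide", "terminal_alkyne", "alkyl_bromide"):
        raise ValueError(f"unknown reactant kind {kind!r}")
    if n < 1:
        raise ValueError("n must be >= 1")
    catalog = _scaffold_catalog()
    if n > len(catalog):
        raise ValueError(
            f"cannot generate {n} distinct {kind}s (catalog holds {len(catalog)})"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(catalog))[:n]
    out = []
    for serial, idx in enumerate(order):
        length, branches = catalog[int(idx)]
        label = f"{kind}_{serial:05d}"
        out.append(build_alkyl_scaffold(kind, length, branches, label=label))
    return out
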