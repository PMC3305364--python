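"""Template-based geometric assembly of click-chemistry products.

The central procedure (the azide–alkyne Huisgen cycloaddition) works in six
steps: (1) fragment the alkyne along its triple bond and the azide along
its proximal–medial N–N bond, so each organic fragment keeps one "handle"
atom (an alkyne carbon, or the proximal azide nitrogen); (2) translate each
fragment so its handle superimposes on the corresponding atom of an
idealized 1,2,3-triazole core, then rotate about the handle to point the
handle-adjacent atom along the core's exocyclic direction; (3) rotate
fragments about the new exocyclic single bonds to relieve steric clashes
(discrete dihedral scan maximizing the minimum cross-fragment distance);
(4) delete the core scaffold atoms superseded by the handles, merge, and
form the ring bonds. Non-symmetric alkynes yield both regioisomers ("1,4"
and "1,5"); symmetric alkynes yield one product.

The other reactions of the core set (azide formation from halides and
amines, epoxide ring opening, amide condensation, alkene epoxidation)
follow the same grammar: delete leaving atoms, graft or place fragments
with idealized internal coordinates, relieve sterics about the new single
bond. Additional reactions plug into ``REGISTRY`` without engine changes.

Stereochemistry is not modeled: products are single 3D conformers, and no
inversion bookkeeping happens at epoxide carbons. Unresolvable clashes
(closest non-bonded contact < 0.7 Å after relief) flag the product rather
than dropping it, so library counts stay predictable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .elements import covalent_radius
from .geometry import merge, rotate_about_pivot, set_atom_location
from .groups import FGMatch, detect_groups, is_symmetric_alkyne
from .perception import DEFAULT_BOND_TOLERANCE, bond_in_ring, get_branch, rings, to_graph
from .structure import Atom, Molecule
from .templates import (
    AZIDE_C_N,
    azide_arm_positions,
    extend_position,
    perp_unit,
    triazole_template,
    unit,
)

CLASH_DISTANCE = 0.7  # Å; closest allowed non-bonded contact
DEFAULT_STEP_DEG = 10.0  # steric-relief dihedral scan step

# new-bond lengths for grafted fragments, Å
BOND_C_N = 1.47
BOND_C_S = 1.82
BOND_AMIDE_C_N = 1.35
BOND_O_H = 0.96
EPOXIDE_C_O = 1.43


# ---------------------------------------------------------------------------
# Records and sanity checking


@dataclass
class ProductRecord:
    """A built product plus its provenance."""

    molecule: Molecule
    reaction: str
    parents: tuple[str, str | None]
    regio: str = "-"
    clash_flagged: bool = False
    sanity: "SanityReport | None" = None


@dataclass
class SanityReport:
    ok: bool
    violations: list[str] = field(default_factory=list)
    max_triazole_deviation: float | None = None


def _triazole_rings(mol: Molecule) -> list[tuple[int, ...]]:
    """Five-rings with three contiguous nitrogens and two carbons."""
    out = []
    for cycle in rings(mol, max_size=5):
        if len(cycle) != 5:
            continue
        pattern = "".join(mol.atoms[i].element for i in cycle)
        if sorted(pattern) != ["C", "C", "N", "N", "N"]:
            continue
        if "NNN" in pattern + pattern:  # contiguous around the cycle
            out.append(cycle)
    return out


def geometry_sanity(mol: Molecule, tolerance: float = DEFAULT_BOND_TOLERANCE) -> SanityReport:
    """Check a built structure for geometric plausibility.

    Bonded atoms must sit within [0.7 Å, r_i + r_j + tolerance] (lower
    bound floored so heavy-halogen bonds are not false failures); no two
    non-bonded atoms may approach within 0.7 Å; and every
    1,2,3-triazole ring must be planar to 0.1 Å.
    """
    violations: list[str] = []
    n = len(mol)
    if n >= 2:
        xyz = mol.coords
        dist = cdist(xyz, xyz)
        bonded = np.zeros((n, n), dtype=bool)
        for a, b in mol.bonds:
            bonded[a, b] = bonded[b, a] = True
        for a, b in sorted(mol.bonds):
            upper = max(
                1.9,
                covalent_radius(mol.atoms[a].element)
                + covalent_radius(mol.atoms[b].element)
                + tolerance,
            )
            if not CLASH_DISTANCE <= dist[a, b] <= upper:
                violations.append(
                    f"bond {a}-{b} length {dist[a, b]:.2f} Å outside "
                    f"[{CLASH_DISTANCE}, {upper:.2f}]"
                )
        masked = dist + np.where(bonded, np.inf, 0.0)
        np.fill_diagonal(masked, np.inf)
        i, j = np.unravel_index(np.argmin(masked), masked.shape)
        if masked[i, j] < CLASH_DISTANCE:
            violations.append(
                f"non-bonded atoms {min(i, j)}-{max(i, j)} only "
                f"{masked[i, j]:.2f} Å apart"
            )
    max_dev: float | None = None
    if mol.bonds:
        for cycle in _triazole_rings(mol):
            pts = np.array([mol.atoms[i].coord for i in cycle])
            centered = pts - pts.mean(axis=0)
            normal = np.linalg.svd(centered, full_matrices=False)[2][-1]
            dev = float(np.max(np.abs(centered @ normal)))
            max_dev = dev if max_dev is None else max(max_dev, dev)
            if dev > 0.1:
                violations.append(
                    f"triazole ring {cycle} deviates {dev:.3f} Å from planarity"
                )
    return SanityReport(ok=not violations, violations=violations, max_triazole_deviation=max_dev)


# ---------------------------------------------------------------------------
# Steric relief


@dataclass
class ReliefResult:
    molecule: Molecule
    angle: float  # radians actually applied
    min_distance_before: float
    min_distance_after: float


def _cross_min_distance(
    xyz: np.ndarray,
    moving: list[int],
    static: list[int],
    bonded: set[tuple[int, int]],
) -> float:
    if not moving or not static:
        return np.inf
    d = cdist(xyz[moving], xyz[static])
    for r, i in enumerate(moving):
        for c, j in enumerate(static):
            if (min(i, j), max(i, j)) in bonded:
                d[r, c] = np.inf
    return float(d.min())


def steric_relief(
    product: Molecule,
    fragment_partition: tuple[set[int], set[int]],
    bond: tuple[int, int],
    step_deg: float = DEFAULT_STEP_DEG,
) -> ReliefResult:
    """Dihedral scan about ``bond`` maximizing the minimum cross-fragment
    distance.

    The first partition set rotates about the axis through the bond atoms;
    ties favor the smallest rotation, so an already-clear geometry is
    returned unchanged. Atoms of the bond itself and bonded cross pairs
    are excluded from the distance criterion. Ring bonds cannot be scanned
    and produce a warning plus a no-op.
    """
    a, b = bond
    if bond_in_ring(product, a, b):
        warnings.warn(f"steric relief skipped: bond {a}-{b} is in a ring", stacklevel=2)
        d0 = _relief_metric(product, fragment_partition, bond)
        return ReliefResult(product.copy(), 0.0, d0, d0)
    moving_set, static_set = fragment_partition
    moving = sorted(moving_set - set(bond))
    static = sorted(static_set - set(bond))
    xyz = product.coords
    p1, p2 = xyz[a], xyz[b]
    axis = unit(p2 - p1)
    d_before = _cross_min_distance(xyz, moving, static, product.bonds)
    if not moving or not static or not np.isfinite(d_before):
        return ReliefResult(product.copy(), 0.0, d_before, d_before)
    n_steps = max(1, int(round(360.0 / step_deg)))
    best_angle, best_d = 0.0, d_before
    rel = xyz[moving] - p1
    for k in range(n_steps):
        angle = np.radians(k * step_deg)
        R = Rotation.from_rotvec(axis * angle).as_matrix()
        trial = xyz.copy()
        trial[moving] = rel @ R.T + p1
        d = _cross_min_distance(trial, moving, static, product.bonds)
        if d > best_d + 1e-12:
            best_angle, best_d = angle, d
    out = product.copy()
    if best_angle != 0.0:
        R = Rotation.from_rotvec(axis * best_angle).as_matrix()
        new_xyz = xyz.copy()
        new_xyz[moving] = rel @ R.T + p1
        out.set_coords(new_xyz)
    return ReliefResult(out, best_angle, d_before, best_d)


def _relief_metric(
    product: Molecule, partition: tuple[set[int], set[int]], bond: tuple[int, int]
) -> float:
    moving = sorted(partition[0] - set(bond))
    static = sorted(partition[1] - set(bond))
    return _cross_min_distance(product.coords, moving, static, product.bonds)


# ---------------------------------------------------------------------------
# Placement helpers


def _place_fragment(
    frag: Molecule,
    handle_idx: int,
    handle_target: np.ndarray,
    adj_idx: int | None,
    adj_target: np.ndarray | None,
) -> Molecule:
    """Translate a fragment so its handle sits exactly on the target, then
    rotate about the handle so the handle-adjacent atom points along the
    target direction."""
    placed = set_atom_location(frag, handle_idx, handle_target)
    if adj_idx is None or adj_target is None:
        return placed
    v_cur = placed.atoms[adj_idx].coord - handle_target
    v_tgt = np.asarray(adj_target, float) - handle_target
    if np.linalg.norm(v_cur) < 1e-8 or np.linalg.norm(v_tgt) < 1e-8:
        return placed
    rot, _ = Rotation.align_vectors(v_tgt[None, :], v_cur[None, :])
    rotvec = rot.as_rotvec()
    angle = float(np.linalg.norm(rotvec))
    if angle < 1e-12:
        return placed
    return rotate_about_pivot(placed, handle_target, rotvec / angle, angle)


def _branch_index(branch: Molecule, parent_index: int) -> int:
    return branch.meta["parent_indices"].index(parent_index)


def _fragment(mol: Molecule, anchor: int, direction: int, what: str) -> Molecule:
    try:
        return get_branch(mol, anchor, direction)
    except ValueError as exc:
        raise ValueError(f"cannot fragment {what}: {exc}") from exc


def _finalize(record: ProductRecord) -> ProductRecord:
    record.molecule.validate()
    record.sanity = geometry_sanity(record.molecule)
    record.clash_flagged = any(
        "non-bonded" in v or "planarity" in v for v in record.sanity.violations
    ) or not record.sanity.ok
    return record


# ---------------------------------------------------------------------------
# Huisgen cycloaddition


def _branch_rank(branch: Molecule) -> tuple[int, int]:
    heavy = sum(1 for a in branch.atoms if a.element != "H")
    return (heavy, len(branch))


def huisgen_cycloaddition(
    azide_mol: Molecule,
    azide_match: FGMatch,
    alkyne_mol: Molecule,
    alkyne_match: FGMatch,
    step_deg: float = DEFAULT_STEP_DEG,
) -> list[ProductRecord]:
    """Build 1,2,3-triazole product model(s) from an azide and an alkyne.

    Returns two records (regio "1,4" and "1,5") for non-symmetric alkynes
    and one for symmetric ones. "1,4" places the larger alkyne branch at
    ring position 4 (para-like to the azide substituent at N1).
    """
    if azide_match.kind != "azide":
        raise ValueError("first match must be an azide")
    if alkyne_match.kind not in ("terminal_alkyne", "internal_alkyne"):
        raise ValueError("second match must be an alkyne")

    prox = azide_match.roles["proximal_N"]
    med = azide_match.roles["medial_N"]
    attach = azide_match.roles["attach_C"]
    c1, c2 = alkyne_match.roles["c1"], alkyne_match.roles["c2"]

    frag_az = _fragment(azide_mol, anchor=med, direction=prox, what="azide")
    frag1 = _fragment(alkyne_mol, anchor=c2, direction=c1, what="alkyne")
    frag2 = _fragment(alkyne_mol, anchor=c1, direction=c2, what="alkyne")

    def adjacent(parent_c: int, other_c: int) -> int:
        others = [j for j in alkyne_mol.neighbors(parent_c) if j != other_c]
        if not others:
            raise ValueError("alkyne carbon has no substituent (missing hydrogens?)")
        return others[0]

    frag_info = {
        "frag1": (frag1, _branch_index(frag1, c1), _branch_index(frag1, adjacent(c1, c2))),
        "frag2": (frag2, _branch_index(frag2, c2), _branch_index(frag2, adjacent(c2, c1))),
    }
    big, small = ("frag1", "frag2")
    if _branch_rank(frag2) > _branch_rank(frag1):
        big, small = ("frag2", "frag1")

    symmetric = is_symmetric_alkyne(alkyne_mol, alkyne_match)
    assignments = [((big, small), "1,4")]
    if not symmetric:
        assignments.append(((small, big), "1,5"))

    tmpl = triazole_template()
    az_handle = _branch_index(frag_az, prox)
    az_adj = _branch_index(frag_az, attach)
    records: list[ProductRecord] = []
    for (at_c4, at_c5), regio in assignments:
        placed_az = _place_fragment(
            frag_az, az_handle, tmpl.coord("N1"), az_adj, tmpl.coord("E1")
        )
        f4, h4, a4 = frag_info[at_c4]
        f5, h5, a5 = frag_info[at_c5]
        placed4 = _place_fragment(f4, h4, tmpl.coord("C4"), a4, tmpl.coord("E4"))
        placed5 = _place_fragment(f5, h5, tmpl.coord("C5"), a5, tmpl.coord("E5"))

        product = merge(merge(merge(placed_az, placed4), placed5), tmpl.core)
        off4 = len(placed_az)
        off5 = off4 + len(placed4)
        off_t = off5 + len(placed5)
        handle_of = {"N1": az_handle, "C4": off4 + h4, "C5": off5 + h5}
        set_az = set(range(len(placed_az)))
        set4 = set(range(off4, off5))
        set5 = set(range(off5, off_t))

        doomed = [off_t + tmpl.roles[r] for r in tmpl.doomed_roles]
        remap = product.delete_atoms(doomed)
        tmpl_of = {
            r: remap[off_t + tmpl.roles[r]]
            for r in tmpl.roles
            if r not in tmpl.doomed_roles
        }

        def resolve(role: str) -> int:
            return handle_of[role] if role in handle_of else tmpl_of[role]

        for r1, r2 in tmpl.new_bonds:
            product.add_bond(resolve(r1), resolve(r2))

        all_atoms = set(range(len(product)))
        relief_plan = [
            (set_az, (handle_of["N1"], az_adj)),
            (set4, (handle_of["C4"], off4 + a4)),
            (set5, (handle_of["C5"], off5 + a5)),
        ]
        for moving, bond in relief_plan:
            result = steric_relief(product, (moving, all_atoms - moving), bond, step_deg)
            product = result.molecule

        product.label = f"{azide_mol.label}+{alkyne_mol.label}"
        records.append(
            _finalize(
                ProductRecord(
                    molecule=product,
                    reaction="huisgen_cycloaddition",
                    parents=(azide_mol.label, alkyne_mol.label),
                    regio=regio,
                )
            )
        )
    return records


# ---------------------------------------------------------------------------
# Azide formation


def halide_to_azide(mol: Molecule, match: FGMatch) -> ProductRecord:
    """Replace an alkyl halide's halogen with a linear azide unit."""
    if match.kind != "alkyl_halide":
        raise ValueError("halide_to_azide needs an alkyl_halide match")
    c, x = match.roles["carbon"], match.roles["halogen"]
    c_pos = mol.atoms[c].coord
    direction = unit(mol.atoms[x].coord - c_pos)
    others = [j for j in mol.neighbors(c) if j != x]
    plane_ref = (
        mol.atoms[others[0]].coord - c_pos if others else perp_unit(direction)
    )
    n1 = c_pos + AZIDE_C_N * direction
    n2, n3 = azide_arm_positions(c_pos, n1, plane_ref)

    out = mol.copy()
    remap = out.delete_atoms([x])
    base = len(out)
    for coord in (n1, n2, n3):
        out.atoms.append(Atom(element="N", coord=coord))
    out.add_bond(remap[c], base)
    out.add_bond(base, base + 1)
    out.add_bond(base + 1, base + 2)
    out.label = f"{mol.label}~azide" if mol.label else "azide"
    return _finalize(
        ProductRecord(out, "halide_to_azide", (mol.label, None), regio="-")
    )


def amine_to_azide(mol: Molecule, match: FGMatch) -> ProductRecord:
    """Convert a primary amine to an azide: both amine hydrogens leave and
    two nitrogens continue the chain with idealized azide geometry."""
    if match.kind != "primary_amine":
        raise ValueError("amine_to_azide needs a primary_amine match")
    n = match.roles["nitrogen"]
    attach = match.roles["attach_C"]
    n_pos = mol.atoms[n].coord
    c_pos = mol.atoms[attach].coord
    others = [j for j in mol.neighbors(attach) if j != n]
    plane_ref = (
        mol.atoms[others[0]].coord - n_pos if others else perp_unit(n_pos - c_pos)
    )
    n2, n3 = azide_arm_positions(c_pos, n_pos, plane_ref)

    out = mol.copy()
    remap = out.delete_atoms([match.roles["h1"], match.roles["h2"]])
    base = len(out)
    for coord in (n2, n3):
        out.atoms.append(Atom(element="N", coord=coord))
    out.add_bond(remap[n], base)
    out.add_bond(base, base + 1)
    out.label = f"{mol.label}~azide" if mol.label else "azide"
    return _finalize(
        ProductRecord(out, "amine_to_azide", (mol.label, None), regio="-")
    )


# ---------------------------------------------------------------------------
# Epoxide opening

NUCLEOPHILE_KINDS = ("primary_amine", "secondary_amine", "thiol", "azide")


def _nucleophile_prep(nu_mol: Molecule, nu_match: FGMatch):
    """Returns (prepped molecule, attach index, orientation index, bond length)."""
    kind = nu_match.kind
    nu = nu_mol.copy()
    if kind == "primary_amine":
        attach, second, lost = (
            nu_match.roles["nitrogen"],
            nu_match.roles["attach_C"],
            nu_match.roles["h1"],
        )
        length = BOND_C_N
    elif kind == "secondary_amine":
        attach, second, lost = (
            nu_match.roles["nitrogen"],
            nu_match.roles["c1"],
            nu_match.roles["h"],
        )
        length = BOND_C_N
    elif kind == "thiol":
        attach, second, lost = nu_match.roles["s"], nu_match.roles["c"], nu_match.roles["h"]
        length = BOND_C_S
    elif kind == "azide":
        attach, second, lost = (
            nu_match.roles["proximal_N"],
            nu_match.roles["attach_C"],
            None,
        )
        length = BOND_C_N
    else:
        raise ValueError(f"unsupported nucleophile kind {kind!r}")
    if lost is not None:
        remap = nu.delete_atoms([lost])
        attach, second = remap[attach], remap[second]
    return nu, attach, second, length


def epoxide_is_symmetric(ep_mol: Molecule, ep_match: FGMatch) -> bool:
    """True iff attack at C1 and at C2 give graph-isomorphic products.

    Decided on the epoxide scaffold alone (a marker node stands in for the
    incoming nucleophile), so dry-run counting and full generation agree by
    construction.
    """
    o, ca, cb = ep_match.roles["o"], ep_match.roles["c1"], ep_match.roles["c2"]

    def marked(attacked: int) -> nx.Graph:
        g = to_graph(ep_mol)
        g.remove_edge(attacked, o)
        g.add_node("nu", element="*")
        g.add_edge("nu", attacked)
        return g

    return nx.is_isomorphic(
        marked(ca), marked(cb), node_match=lambda a, b: a["element"] == b["element"]
    )


def epoxide_opening(
    ep_mol: Molecule,
    ep_match: FGMatch,
    nu_mol: Molecule,
    nu_match: FGMatch,
    step_deg: float = DEFAULT_STEP_DEG,
) -> list[ProductRecord]:
    """Open an epoxide with an amine, thiol or azide nucleophile.

    The nucleophile attacks either ring carbon anti to the C–O bond being
    broken; the ring oxygen becomes a hydroxyl. Two regio products
    ("attack_C1"/"attack_C2") are built unless they are graph-isomorphic
    (symmetric epoxide), in which case one is emitted.
    """
    if ep_match.kind != "epoxide":
        raise ValueError("epoxide_opening needs an epoxide match")
    if nu_match.kind not in NUCLEOPHILE_KINDS:
        raise ValueError(f"unsupported nucleophile kind {nu_match.kind!r}")
    o = ep_match.roles["o"]
    carbons = {"attack_C1": ep_match.roles["c1"], "attack_C2": ep_match.roles["c2"]}
    labels = ["attack_C1"]
    if not epoxide_is_symmetric(ep_mol, ep_match):
        labels.append("attack_C2")

    records: list[ProductRecord] = []
    for label in labels:
        ca = carbons[label]
        cb = carbons["attack_C2" if label == "attack_C1" else "attack_C1"]
        scaffold = ep_mol.copy()
        o_pos = scaffold.atoms[o].coord
        ca_pos = scaffold.atoms[ca].coord
        cb_pos = scaffold.atoms[cb].coord
        scaffold.bonds.discard((min(ca, o), max(ca, o)))
        if nu_match.kind != "azide":
            # the proton lost by the amine/thiol caps the ring oxygen; an
            # azide has none to give, so its product keeps an alkoxide-like
            # oxygen and the formula still sums exactly
            h_pos = o_pos + BOND_O_H * unit(o_pos - ca_pos)
            scaffold.atoms.append(Atom(element="H", coord=h_pos))
            scaffold.add_bond(o, len(scaffold) - 1)

        nu, attach, second, length = _nucleophile_prep(nu_mol, nu_match)
        direction = unit(ca_pos - o_pos)
        p1 = ca_pos + length * direction
        in_plane = cb_pos - ca_pos
        vperp = in_plane - np.dot(in_plane, direction) * direction
        v = -unit(vperp) if np.linalg.norm(vperp) > 1e-8 else perp_unit(direction)
        r2 = float(np.linalg.norm(nu.atoms[second].coord - nu.atoms[attach].coord))
        theta = np.radians(112.0)
        p2 = p1 + r2 * (-direction * np.cos(theta) + v * np.sin(theta))
        placed = _place_fragment(nu, attach, p1, second, p2)

        product = merge(scaffold, placed)
        attach_g = len(scaffold) + attach
        product.add_bond(ca, attach_g)
        moving = set(range(len(scaffold), len(product)))
        result = steric_relief(
            product, (moving, set(range(len(product))) - moving), (ca, attach_g), step_deg
        )
        product = result.molecule
        product.label = f"{ep_mol.label}+{nu_mol.label}"
        records.append(
            _finalize(
                ProductRecord(
                    product,
                    "epoxide_opening",
                    (ep_mol.label, nu_mol.label),
                    regio=label,
                )
            )
        )
    return records


# ---------------------------------------------------------------------------
# Amide formation


def amide_formation(
    acid_mol: Molecule,
    acid_match: FGMatch,
    amine_mol: Molecule,
    amine_match: FGMatch,
    step_deg: float = DEFAULT_STEP_DEG,
) -> ProductRecord:
    """Condense a carboxylic acid (or acyl halide) with an amine.

    The acid loses its hydroxyl (or halogen), the amine loses one N–H, and
    a planar amide C–N bond is formed with the amine substituent trans to
    the carbonyl oxygen.
    """
    if acid_match.kind not in ("carboxylic_acid", "acyl_halide"):
        raise ValueError("amide_formation needs a carboxylic_acid or acyl_halide match")
    if amine_match.kind not in ("primary_amine", "secondary_amine"):
        raise ValueError("amide_formation needs a primary or secondary amine")
    c = acid_match.roles["c"]
    o_carb = acid_match.roles["o_carbonyl"]
    if acid_match.kind == "carboxylic_acid":
        leaving = [acid_match.roles["o_hydroxyl"], acid_match.roles["h_hydroxyl"]]
        leave_pos = acid_mol.atoms[acid_match.roles["o_hydroxyl"]].coord
    else:
        leaving = [acid_match.roles["halogen"]]
        leave_pos = acid_mol.atoms[acid_match.roles["halogen"]].coord

    c_pos = acid_mol.atoms[c].coord
    direction = unit(leave_pos - c_pos)
    p1 = c_pos + BOND_AMIDE_C_N * direction
    carbonyl_vec = acid_mol.atoms[o_carb].coord - c_pos
    vperp = carbonyl_vec - np.dot(carbonyl_vec, direction) * direction
    v = -unit(vperp) if np.linalg.norm(vperp) > 1e-8 else perp_unit(direction)
    theta = np.radians(120.0)
    nu, attach, second, _ = _nucleophile_prep(amine_mol, amine_match)
    r2 = float(np.linalg.norm(nu.atoms[second].coord - nu.atoms[attach].coord))
    p2 = p1 + r2 * (-direction * np.cos(theta) + v * np.sin(theta))
    placed = _place_fragment(nu, attach, p1, second, p2)

    scaffold = acid_mol.copy()
    remap = scaffold.delete_atoms(leaving)
    product = merge(scaffold, placed)
    attach_g = len(scaffold) + attach
    product.add_bond(remap[c], attach_g)
    moving = set(range(len(scaffold), len(product)))
    result = steric_relief(
        product, (moving, set(range(len(product))) - moving), (remap[c], attach_g), step_deg
    )
    product = result.molecule
    product.label = f"{acid_mol.label}+{amine_mol.label}"
    return _finalize(
        ProductRecord(
            product, "amide_formation", (acid_mol.label, amine_mol.label), regio="-"
        )
    )


# ---------------------------------------------------------------------------
# Alkene epoxidation


def alkene_epoxidation(mol: Molecule, match: FGMatch) -> ProductRecord:
    """Insert an oxygen above the C=C midpoint, forming a three-ring."""
    if match.kind != "alkene":
        raise ValueError("alkene_epoxidation needs an alkene match")
    c1, c2 = match.roles["c1"], match.roles["c2"]
    p1, p2 = mol.atoms[c1].coord, mol.atoms[c2].coord
    midpoint = 0.5 * (p1 + p2)
    half = 0.5 * float(np.linalg.norm(p2 - p1))
    height = float(np.sqrt(max(EPOXIDE_C_O**2 - half**2, 0.2**2)))
    others = [j for j in mol.neighbors(c1) if j != c2]
    if others:
        normal = unit(np.cross(p2 - p1, mol.atoms[others[0]].coord - p1))
    else:
        normal = perp_unit(p2 - p1)
    out = mol.copy()
    out.atoms.append(Atom(element="O", coord=midpoint + height * normal))
    o_idx = len(out) - 1
    out.add_bond(c1, o_idx)
    out.add_bond(c2, o_idx)
    out.label = f"{mol.label}~epoxide" if mol.label else "epoxide"
    return _finalize(
        ProductRecord(out, "alkene_epoxidation", (mol.label, None), regio="-")
    )


# ---------------------------------------------------------------------------
# Registry and dispatch


@dataclass(frozen=True)
class ReactionRule:
    """A registry entry: which functional-group kinds react, and how many
    molecules participate. New reactions plug in by appending a rule."""

    name: str
    arity: int
    kinds_primary: frozenset[str]
    kinds_secondary: frozenset[str] | None


REGISTRY: tuple[ReactionRule, ...] = (
    ReactionRule(
        "huisgen_cycloaddition",
        2,
        frozenset({"azide"}),
        frozenset({"terminal_alkyne", "internal_alkyne"}),
    ),
    ReactionRule(
        "epoxide_opening", 2, frozenset({"epoxide"}), frozenset(NUCLEOPHILE_KINDS)
    ),
    ReactionRule(
        "amide_formation",
        2,
        frozenset({"carboxylic_acid", "acyl_halide"}),
        frozenset({"primary_amine", "secondary_amine"}),
    ),
    ReactionRule("halide_to_azide", 1, frozenset({"alkyl_halide"}), None),
    ReactionRule("amine_to_azide", 1, frozenset({"primary_amine"}), None),
    ReactionRule("alkene_epoxidation", 1, frozenset({"alkene"}), None),
)


def _match_order(m: FGMatch) -> tuple[int, ...]:
    return tuple(sorted(m.roles.values()))


def applicable_reactions(
    mol_a: Molecule, mol_b: Molecule | None = None
) -> list[tuple[str, FGMatch, FGMatch | None]]:
    """Cross detected functional groups against the reaction registry.

    With one molecule, only unimolecular transformations are returned;
    with two, every (primary, secondary) match pairing in either
    orientation. Order is deterministic: registry order, then orientation,
    then match atom indices.
    """
    groups_a = detect_groups(mol_a)
    groups_b = detect_groups(mol_b) if mol_b is not None else []
    out: list[tuple[str, FGMatch, FGMatch | None]] = []
    for rule in REGISTRY:
        if mol_b is None:
            if rule.arity != 1:
                continue
            for m in sorted(groups_a, key=_match_order):
                if m.kind in rule.kinds_primary:
                    out.append((rule.name, m, None))
        else:
            if rule.arity != 2:
                continue
            assert rule.kinds_secondary is not None
            for primary_pool, secondary_pool in ((groups_a, groups_b), (groups_b, groups_a)):
                for mp in sorted(primary_pool, key=_match_order):
                    if mp.kind not in rule.kinds_primary:
                        continue
                    for ms in sorted(secondary_pool, key=_match_order):
                        if ms.kind in rule.kinds_secondary:
                            out.append((rule.name, mp, ms))
                if groups_a is groups_b:
                    break
    return out


def run_reaction(
    name: str,
    primary: FGMatch,
    secondary: FGMatch | None = None,
    step_deg: float = DEFAULT_STEP_DEG,
) -> list[ProductRecord]:
    """Dispatch a registry reaction on detected matches; always returns a
    list of product records."""
    if name == "huisgen_cycloaddition":
        assert secondary is not None
        return huisgen_cycloaddition(
            primary.molecule, primary, secondary.molecule, secondary, step_deg
        )
    if name == "epoxide_opening":
        assert secondary is not None
        return epoxide_opening(
            primary.molecule, primary, secondary.molecule, secondary, step_deg
        )
    if name == "amide_formation":
        assert secondary is not None
        return [
            amide_formation(
                primary.molecule, primary, secondary.molecule, secondary, step_deg
            )
        ]
    if name == "halide_to_azide":
        return [halide_to_azide(primary.molecule, primary)]
    if name == "amine_to_azide":
        return [amine_to_azide(primary.molecule, primary)]
    if name == "alkene_epoxidation":
        return [alkene_epoxidation(primary.molecule, primary)]
    raise ValueError(f"unknown reaction {name!r}")
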