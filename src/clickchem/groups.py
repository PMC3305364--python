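"""Detection of click-reactive functional groups with role-labelled atoms.

Patterns are graph rules over elements, degrees and hybridization, applied
to an explicit-hydrogen molecule with perceived bonds. Each match carries a
``roles`` map naming the atoms the reaction engine manipulates (e.g. the
azide's proximal/medial/distal nitrogens and its attachment carbon).

Overlap policy: kinds are scanned in a fixed precedence order (most
specific first — see ``KIND_PRECEDENCE``); a candidate match is dropped if
any of its role atoms was already claimed by an earlier match. This makes
acyl halides win over alkyl halides, carboxylic acids over alcohols, and
guarantees that no two reported matches share an atom.

Chemistry guards beyond the bare patterns:

* amines adjacent to a carbonyl carbon are amides, not reactive amines;
* the alcohol pattern skips carboxyl hydroxyls;
* the alkene pattern skips pairs inside all-sp2 six-membered rings (a
  crude aromaticity guard so benzene is never "epoxidized"), and skips
  carbonyl carbons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

from .elements import HALOGENS
from .perception import (
    get_branch,
    hybridization,
    require_bonds,
    rings,
    to_graph,
)
from .structure import Molecule

FGKind = str

KIND_PRECEDENCE: tuple[FGKind, ...] = (
    "azide",
    "terminal_alkyne",
    "internal_alkyne",
    "acyl_halide",
    "carboxylic_acid",
    "epoxide",
    "alkyl_halide",
    "primary_amine",
    "secondary_amine",
    "thiol",
    "alcohol",
    "alkene",
)


@dataclass
class FGMatch:
    """A detected functional group: kind tag plus role-labelled atom
    indices into ``molecule``."""

    kind: FGKind
    roles: dict[str, int]
    molecule: Molecule = field(repr=False)

    @property
    def atoms(self) -> frozenset[int]:
        return frozenset(self.roles.values())


def _element(mol: Molecule, i: int) -> str:
    return mol.atoms[i].element


def _h_neighbors(mol: Molecule, i: int) -> list[int]:
    return [j for j in mol.neighbors(i) if _element(mol, j) == "H"]


def _carbonyl_oxygens(mol: Molecule, c: int) -> list[int]:
    """Degree-1 oxygen neighbors of a carbon (C=O proxies)."""
    return [
        j
        for j in mol.neighbors(c)
        if _element(mol, j) == "O" and mol.degree(j) == 1
    ]


def _is_amide_carbon(mol: Molecule, c: int) -> bool:
    return _element(mol, c) == "C" and bool(_carbonyl_oxygens(mol, c))


def _detect_azide(mol: Molecule):
    for n2, atom in enumerate(mol.atoms):
        if atom.element != "N":
            continue
        nbrs = mol.neighbors(n2)
        if len(nbrs) != 2 or any(_element(mol, j) != "N" for j in nbrs):
            continue
        for n3 in nbrs:
            n1 = nbrs[0] if n3 == nbrs[1] else nbrs[1]
            if mol.degree(n3) != 1:
                continue
            carbons = [j for j in mol.neighbors(n1) if _element(mol, j) == "C"]
            if len(carbons) != 1 or mol.degree(n1) != 2:
                continue
            yield {
                "proximal_N": n1,
                "medial_N": n2,
                "distal_N": n3,
                "attach_C": carbons[0],
            }
            break


def _detect_alkynes(mol: Molecule, terminal: bool):
    seen: set[frozenset[int]] = set()
    for i, j in sorted(mol.bonds):
        if frozenset((i, j)) in seen:
            continue
        if _element(mol, i) != "C" or _element(mol, j) != "C":
            continue
        if mol.degree(i) != 2 or mol.degree(j) != 2:
            continue
        if hybridization(mol, i) != "sp" or hybridization(mol, j) != "sp":
            continue
        seen.add(frozenset((i, j)))
        h_on = [bool(_h_neighbors(mol, k)) for k in (i, j)]
        is_terminal = any(h_on)
        if is_terminal != terminal:
            continue
        if is_terminal and h_on[1] and not h_on[0]:
            c_term, c_subst = j, i
        else:
            c_term, c_subst = i, j
        roles = {"c1": c_subst, "c2": c_term}
        if is_terminal:
            roles["terminal_H"] = _h_neighbors(mol, c_term)[0]
        yield roles


def _detect_acyl_halide(mol: Molecule):
    for c, atom in enumerate(mol.atoms):
        if atom.element != "C":
            continue
        carbonyls = _carbonyl_oxygens(mol, c)
        halos = [j for j in mol.neighbors(c) if _element(mol, j) in HALOGENS]
        if len(carbonyls) == 1 and len(halos) == 1:
            yield {"c": c, "o_carbonyl": carbonyls[0], "halogen": halos[0]}


def _detect_carboxylic_acid(mol: Molecule):
    for c, atom in enumerate(mol.atoms):
        if atom.element != "C":
            continue
        oxygens = [j for j in mol.neighbors(c) if _element(mol, j) == "O"]
        if len(oxygens) != 2:
            continue
        carbonyl = [o for o in oxygens if mol.degree(o) == 1]
        hydroxyl = [o for o in oxygens if _h_neighbors(mol, o)]
        if len(carbonyl) == 1 and len(hydroxyl) == 1 and carbonyl[0] != hydroxyl[0]:
            yield {
                "c": c,
                "o_carbonyl": carbonyl[0],
                "o_hydroxyl": hydroxyl[0],
                "h_hydroxyl": _h_neighbors(mol, hydroxyl[0])[0],
            }


def _detect_epoxide(mol: Molecule):
    for o, atom in enumerate(mol.atoms):
        if atom.element != "O" or mol.degree(o) != 2:
            continue
        nbrs = mol.neighbors(o)
        if all(_element(mol, j) == "C" for j in nbrs) and mol.bonded(*nbrs):
            c1, c2 = sorted(nbrs)
            yield {"o": o, "c1": c1, "c2": c2}


def _detect_alkyl_halide(mol: Molecule):
    for c, atom in enumerate(mol.atoms):
        if atom.element != "C":
            continue
        halos = [j for j in mol.neighbors(c) if _element(mol, j) in HALOGENS]
        if len(halos) != 1:
            continue
        if _carbonyl_oxygens(mol, c):
            continue  # acyl halide territory
        if hybridization(mol, c) != "sp3":
            continue
        yield {"carbon": c, "halogen": halos[0]}


def _detect_amine(mol: Molecule, n_h: int):
    for n, atom in enumerate(mol.atoms):
        if atom.element != "N":
            continue
        hs = _h_neighbors(mol, n)
        carbons = [j for j in mol.neighbors(n) if _element(mol, j) == "C"]
        if len(hs) != n_h or len(carbons) != (3 - n_h):
            continue
        if mol.degree(n) != 3:
            continue
        if any(_is_amide_carbon(mol, c) for c in carbons):
            continue
        if n_h == 2:
            yield {"nitrogen": n, "attach_C": carbons[0], "h1": hs[0], "h2": hs[1]}
        else:
            yield {"nitrogen": n, "c1": carbons[0], "c2": carbons[1], "h": hs[0]}


def _detect_thiol(mol: Molecule):
    for s, atom in enumerate(mol.atoms):
        if atom.element != "S" or mol.degree(s) != 2:
            continue
        hs = _h_neighbors(mol, s)
        carbons = [j for j in mol.neighbors(s) if _element(mol, j) == "C"]
        if len(hs) == 1 and len(carbons) == 1:
            yield {"s": s, "h": hs[0], "c": carbons[0]}


def _detect_alcohol(mol: Molecule):
    for o, atom in enumerate(mol.atoms):
        if atom.element != "O" or mol.degree(o) != 2:
            continue
        hs = _h_neighbors(mol, o)
        carbons = [j for j in mol.neighbors(o) if _element(mol, j) == "C"]
        if len(hs) != 1 or len(carbons) != 1:
            continue
        if _is_amide_carbon(mol, carbons[0]):
            continue  # carboxyl hydroxyl
        yield {"o": o, "h": hs[0], "c": carbons[0]}


def _aromatic_guard_pairs(mol: Molecule) -> set[frozenset[int]]:
    """Bonded carbon pairs inside six-membered rings whose members are all
    sp2 — treated as aromatic and excluded from alkene matching."""
    guarded: set[frozenset[int]] = set()
    for cycle in rings(mol, max_size=6):
        if len(cycle) != 6:
            continue
        if all(
            _element(mol, i) == "C" and hybridization(mol, i) == "sp2" for i in cycle
        ):
            for k, i in enumerate(cycle):
                guarded.add(frozenset((i, cycle[(k + 1) % 6])))
    return guarded


def _detect_alkene(mol: Molecule):
    guarded = _aromatic_guard_pairs(mol)
    for i, j in sorted(mol.bonds):
        if _element(mol, i) != "C" or _element(mol, j) != "C":
            continue
        if hybridization(mol, i) != "sp2" or hybridization(mol, j) != "sp2":
            continue
        if frozenset((i, j)) in guarded:
            continue
        if _carbonyl_oxygens(mol, i) or _carbonyl_oxygens(mol, j):
            continue
        yield {"c1": i, "c2": j}


_DETECTORS = {
    "azide": _detect_azide,
    "terminal_alkyne": lambda m: _detect_alkynes(m, terminal=True),
    "internal_alkyne": lambda m: _detect_alkynes(m, terminal=False),
    "acyl_halide": _detect_acyl_halide,
    "carboxylic_acid": _detect_carboxylic_acid,
    "epoxide": _detect_epoxide,
    "alkyl_halide": _detect_alkyl_halide,
    "primary_amine": lambda m: _detect_amine(m, n_h=2),
    "secondary_amine": lambda m: _detect_amine(m, n_h=1),
    "thiol": _detect_thiol,
    "alcohol": _detect_alcohol,
    "alkene": _detect_alkene,
}


def detect_groups(
    mol: Molecule, kinds: Iterable[FGKind] | None = None
) -> list[FGMatch]:
    """Find every click-reactive functional group in ``mol``.

    ``kinds`` optionally restricts which kinds are reported (precedence
    and atom claiming still run over the full set, so a restricted query
    never reports a pattern a broader query would have superseded).
    """
    require_bonds(mol)
    wanted = set(KIND_PRECEDENCE if kinds is None else kinds)
    unknown = wanted - set(KIND_PRECEDENCE)
    if unknown:
        raise ValueError(f"unknown functional-group kinds: {sorted(unknown)}")
    claimed: set[int] = set()
    matches: list[FGMatch] = []
    for kind in KIND_PRECEDENCE:
        for roles in _DETECTORS[kind](mol):
            atoms = set(roles.values())
            if atoms & claimed:
                continue
            claimed |= atoms
            if kind in wanted:
                matches.append(FGMatch(kind=kind, roles=dict(roles), molecule=mol))
    return matches


def _branch_graph(mol: Molecule, anchor: int, direction: int) -> nx.Graph:
    branch = get_branch(mol, anchor, direction)
    return to_graph(branch)


def is_symmetric_alkyne(mol: Molecule, match: FGMatch) -> bool:
    """True iff the two substituent branches across the triple bond are
    isomorphic as element-labelled graphs.

    A terminal alkyne is symmetric only when both substituents are lone
    hydrogens (acetylene itself); the Huisgen engine emits a single
    product for symmetric alkynes because the two regioisomers coincide.
    """
    if match.kind not in ("terminal_alkyne", "internal_alkyne"):
        raise ValueError("symmetry test applies to alkyne matches only")
    c1, c2 = match.roles["c1"], match.roles["c2"]
    g1 = _branch_graph(mol, anchor=c2, direction=c1)
    g2 = _branch_graph(mol, anchor=c1, direction=c2)
    return nx.is_isomorphic(
        g1, g2, node_match=lambda a, b: a["element"] == b["element"]
    )
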