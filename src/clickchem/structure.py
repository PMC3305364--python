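"""Atom/Molecule data model and fixed-column PDB reading and writing.

Small-molecule PDB files are the exchange format of this package: explicit
hydrogens, 3D coordinates, optional CONECT records. Bond perception from
coordinates lives in :mod:`clickchem.perception`; here bonds are just an
(optional) set of index pairs carried by the molecule.

Atom indices are 0-based internally; PDB serials are 1-based and renumbered
on output.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Mapping

import numpy as np

from .elements import atomic_weight, is_element, normalize_symbol


class PDBFormatError(ValueError):
    """Raised for unreadable or out-of-contract PDB content."""


@dataclass
class Atom:
    """One atom of a small-molecule model.

    ``coord`` is a length-3 float array in Å. ``occupancy`` and
    ``temp_factor`` are carried through unchanged; nothing downstream
    interprets them.
    """

    element: str
    coord: np.ndarray
    name: str = ""
    serial: int = 0
    residue_name: str = "LIG"
    chain: str = "A"
    residue_number: int = 1
    occupancy: float = 1.00
    temp_factor: float = 0.00

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,):
            raise ValueError(f"atom coordinate must be a 3-vector, got {self.coord!r}")
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinate for atom {self.name or self.element!r}")
        if not is_element(self.element):
            raise ValueError(f"unknown element symbol {self.element!r} for atom {self.name!r}")

    def copy(self) -> "Atom":
        return replace(self, coord=self.coord.copy())


Bond = tuple[int, int]


def _canon_bond(i: int, j: int) -> Bond:
    return (i, j) if i < j else (j, i)


@dataclass
class Molecule:
    """An ordered list of atoms plus an (optional) undirected bond set.

    ``bonds`` holds sorted 0-based index pairs. ``label`` is a provenance
    tag (usually the source filename stem); ``meta`` carries bookkeeping
    such as branch provenance indices and never affects geometry.
    """

    atoms: list[Atom] = field(default_factory=list)
    bonds: set[Bond] = field(default_factory=set)
    label: str = ""
    meta: dict = field(default_factory=dict)

    # -- container basics ------------------------------------------------
    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) array of coordinates (a copy)."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.coord for a in self.atoms], dtype=float)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for atom, row in zip(self.atoms, xyz):
            atom.coord = row.copy()

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def copy(self) -> "Molecule":
        return Molecule(
            atoms=[a.copy() for a in self.atoms],
            bonds=set(self.bonds),
            label=self.label,
            meta=dict(self.meta),
        )

    # -- bonds -----------------------------------------------------------
    def add_bond(self, i: int, j: int) -> None:
        n = len(self.atoms)
        if not (0 <= i < n and 0 <= j < n):
            raise IndexError(f"bond ({i},{j}) references a missing atom (n={n})")
        if i == j:
            raise ValueError(f"self-bond on atom {i}")
        self.bonds.add(_canon_bond(i, j))

    def bonded(self, i: int, j: int) -> bool:
        return _canon_bond(i, j) in self.bonds

    def neighbors(self, i: int) -> list[int]:
        """Bonded partners of atom ``i``, ascending."""
        out = []
        for a, b in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def degree(self, i: int) -> int:
        return len(self.neighbors(i))

    # -- editing ---------------------------------------------------------
    def delete_atoms(self, indices: Iterable[int]) -> dict[int, int]:
        """Delete atoms in-place; returns old-index -> new-index map for the
        surviving atoms. Bonds touching deleted atoms are dropped."""
        doomed = set(indices)
        for i in doomed:
            if not 0 <= i < len(self.atoms):
                raise IndexError(f"cannot delete missing atom {i}")
        remap: dict[int, int] = {}
        new_atoms: list[Atom] = []
        for old, atom in enumerate(self.atoms):
            if old in doomed:
                continue
            remap[old] = len(new_atoms)
            new_atoms.append(atom)
        self.atoms = new_atoms
        self.bonds = {
            _canon_bond(remap[a], remap[b])
            for a, b in self.bonds
            if a not in doomed and b not in doomed
        }
        return remap

    def validate(self) -> None:
        """Check structural invariants; raises ValueError on violation."""
        n = len(self.atoms)
        for a, b in self.bonds:
            if not (0 <= a < n and 0 <= b < n):
                raise ValueError(f"bond ({a},{b}) references a missing atom")
            if a == b:
                raise ValueError(f"self-bond on atom {a}")
        if n > 1:
            xyz = self.coords
            d2 = np.sum((xyz[:, None, :] - xyz[None, :, :]) ** 2, axis=-1)
            np.fill_diagonal(d2, np.inf)
            if np.min(d2) < 0.01**2:
                i, j = np.unravel_index(np.argmin(d2), d2.shape)
                raise ValueError(f"atoms {i} and {j} coincide within 0.01 Å")


# ---------------------------------------------------------------------------
# PDB reading

# Protein-style "remoteness" letters: a name like "CA"/"NE"/"OG" is a Cα,
# Nε, Oγ — a one-letter element with a position tag — not calcium etc.
_REMOTENESS = set("ABGDEZH")
_ORGANIC_FIRST = set("CNOSHP")


def _element_from_name(name: str) -> str | None:
    """Infer the element from a PDB atom-name field.

    Leading spaces and digits are stripped. A two-letter symbol ("CL",
    "Br") is recognized case-insensitively unless it looks like a
    protein-style remoteness name ("CA", "NE"), which resolves to the
    one-letter element; the explicit element columns override this
    heuristic entirely when present.
    """
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return None
    two = stripped[:2]
    if len(two) == 2:
        cand = normalize_symbol(two)
        if cand is not None and len(cand) == 2:
            ambiguous = (
                two[0].upper() in _ORGANIC_FIRST
                and two[1].upper() in _REMOTENESS
                and normalize_symbol(two[0]) is not None
            )
            if not ambiguous:
                return cand
    return normalize_symbol(stripped[0])


def _parse_atom_line(line: str, lineno: int) -> Atom:
    def _float_field(lo: int, hi: int, what: str) -> float:
        text = line[lo:hi]
        try:
            return float(text)
        except ValueError:
            raise PDBFormatError(
                f"line {lineno}: unparseable {what} field {text.strip()!r}"
            ) from None

    try:
        serial = int(line[6:11])
    except ValueError:
        serial = 0
    name = line[12:16]
    x = _float_field(30, 38, "x coordinate")
    y = _float_field(38, 46, "y coordinate")
    z = _float_field(46, 54, "z coordinate")
    occ_text = line[54:60].strip()
    tf_text = line[60:66].strip()
    element_field = line[76:78].strip()

    element = normalize_symbol(element_field) if element_field else None
    if element is None:
        element = _element_from_name(name)
    if element is None:
        raise PDBFormatError(
            f"line {lineno}: cannot assign an element to atom "
            f"{name.strip()!r} (serial {serial})"
        )
    return Atom(
        element=element,
        coord=np.array([x, y, z]),
        name=name.strip(),
        serial=serial,
        residue_name=line[17:20].strip() or "LIG",
        chain=line[21:22].strip() or "A",
        residue_number=int(line[22:26]) if line[22:26].strip() else 1,
        occupancy=float(occ_text) if occ_text else 1.0,
        temp_factor=float(tf_text) if tf_text else 0.0,
    )


def load_pdb(source: str | Path | IO[str]) -> Molecule:
    """Read a small-molecule PDB model.

    One Atom per ATOM/HETATM record, in file order. The element comes from
    columns 77–78 when present, else from the atom-name field. CONECT
    records populate ``bonds`` (deduplicated, symmetric); only the first
    MODEL is read and only blank/'A' altLocs are kept.
    """
    label = ""
    if isinstance(source, (str, Path)):
        path = Path(source)
        label = path.stem
        text = path.read_text()
    else:
        text = source.read()
        label = getattr(source, "name", "") or ""
        if label:
            label = Path(label).stem

    mol = Molecule(label=label)
    serial_to_index: dict[int, int] = {}
    conect_pairs: set[tuple[int, int]] = set()
    in_first_model = True
    for lineno, line in enumerate(text.splitlines(), start=1):
        record = line[:6]
        if record == "ENDMDL":
            in_first_model = False
            continue
        if not in_first_model:
            continue
        if record in ("ATOM  ", "HETATM"):
            altloc = line[16:17]
            if altloc not in (" ", "", "A"):
                continue
            atom = _parse_atom_line(line.ljust(80), lineno)
            if atom.serial:
                serial_to_index.setdefault(atom.serial, len(mol.atoms))
            mol.atoms.append(atom)
        elif record == "CONECT":
            fields = line[6:].split()
            try:
                serials = [int(f) for f in fields]
            except ValueError:
                raise PDBFormatError(f"line {lineno}: unparseable CONECT record")
            if len(serials) >= 2:
                for other in serials[1:]:
                    conect_pairs.add(
                        (serials[0], other) if serials[0] < other else (other, serials[0])
                    )
    if not mol.atoms:
        raise PDBFormatError("empty structure: no ATOM/HETATM records found")
    for sa, sb in conect_pairs:
        if sa in serial_to_index and sb in serial_to_index:
            mol.add_bond(serial_to_index[sa], serial_to_index[sb])
    mol.validate()
    return mol


def loads_pdb(text: str) -> Molecule:
    """Parse PDB content from a string."""
    return load_pdb(io.StringIO(text))


# ---------------------------------------------------------------------------
# PDB writing


def format_pdb(mol: Molecule) -> str:
    """Render a molecule as fixed-column PDB text (HETATM + CONECT + END).

    Serials are renumbered from 1; coordinates are printed to 3 decimals;
    the element sits right-justified in columns 77–78. Every bond is
    emitted in both directions.
    """
    if not mol.atoms:
        raise PDBFormatError("refusing to write an empty molecule")
    lines: list[str] = []
    counts: Counter[str] = Counter()
    for idx, atom in enumerate(mol.atoms):
        serial = idx + 1
        name = atom.name
        if not name:
            counts[atom.element] += 1
            name = f"{atom.element}{counts[atom.element]}"
        name = name[:4]
        # one-letter elements start in column 14 by convention
        name_field = f" {name:<3s}" if len(atom.element) == 1 and len(name) < 4 else f"{name:<4s}"
        coord_fields = []
        for value in atom.coord:
            text = f"{value:8.3f}"
            if len(text) > 8:
                raise PDBFormatError(
                    f"coordinate {value:.3f} overflows the fixed-column PDB format"
                )
            coord_fields.append(text)
        lines.append(
            f"HETATM{serial:>5d} {name_field} {atom.residue_name:<3.3s} "
            f"{atom.chain:1.1s}{atom.residue_number:>4d}    "
            f"{coord_fields[0]}{coord_fields[1]}{coord_fields[2]}"
            f"{atom.occupancy:6.2f}{atom.temp_factor:6.2f}          "
            f"{atom.element:>2s}"
        )
    for a, b in sorted(mol.bonds):
        lines.append(f"CONECT{a + 1:>5d}{b + 1:>5d}")
        lines.append(f"CONECT{b + 1:>5d}{a + 1:>5d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def save_pdb(mol: Molecule, destination: str | Path | IO[str]) -> None:
    text = format_pdb(mol)
    if isinstance(destination, (str, Path)):
        Path(destination).write_text(text)
    else:
        destination.write(text)


# ---------------------------------------------------------------------------
# Composition


def molecular_formula(mol: Molecule) -> dict[str, int]:
    """Element -> count over all atoms."""
    return dict(Counter(a.element for a in mol.atoms))


def hill_formula(mol: Molecule | Mapping[str, int]) -> str:
    """Render a formula string in Hill order (C, H, then alphabetical)."""
    counts = molecular_formula(mol) if isinstance(mol, Molecule) else dict(mol)
    ordered: list[str] = []
    for sym in ("C", "H"):
        if sym in counts:
            ordered.append(sym)
    ordered.extend(sorted(k for k in counts if k not in ("C", "H")))
    return "".join(f"{sym}{counts[sym] if counts[sym] != 1 else ''}" for sym in ordered)


def molecular_weight(mol: Molecule) -> float:
    """Sum of standard atomic weights, in Da."""
    return float(sum(atomic_weight(a.element) for a in mol.atoms))
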