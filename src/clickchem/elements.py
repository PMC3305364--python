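"""Internal periodic table: symbols, standard atomic weights, covalent radii.

Weights are IUPAC 2021 conventional values (Da). Covalent radii are
single-bond radii (Å) after Cordero et al.; they drive distance-based bond
perception (two atoms are bonded when their separation is at most the sum of
their radii plus a tolerance, 0.4 Å by default).
"""

from __future__ import annotations

# symbol -> (atomic weight / Da, covalent radius / Å)
_ELEMENTS: dict[str, tuple[float, float]] = {
    "H": (1.008, 0.31),
    "B": (10.81, 0.84),
    "C": (12.011, 0.76),
    "N": (14.007, 0.71),
    "O": (15.999, 0.66),
    "F": (18.998, 0.57),
    "Na": (22.990, 1.66),
    "Mg": (24.305, 1.41),
    "Si": (28.085, 1.11),
    "P": (30.974, 1.07),
    "S": (32.06, 1.05),
    "Cl": (35.45, 1.02),
    "K": (39.098, 2.03),
    "Ca": (40.078, 1.76),
    "Fe": (55.845, 1.32),
    "Cu": (63.546, 1.32),
    "Zn": (65.38, 1.22),
    "Se": (78.971, 1.20),
    "Br": (79.904, 1.20),
    "I": (126.904, 1.39),
}

HALOGENS = frozenset({"Cl", "Br", "I"})


def is_element(symbol: str) -> bool:
    return symbol in _ELEMENTS


def normalize_symbol(raw: str) -> str | None:
    """Return the canonical capitalization of ``raw`` if it names a known
    element (case-insensitive), else None."""
    sym = raw.strip().capitalize()
    return sym if sym in _ELEMENTS else None


def atomic_weight(symbol: str) -> float:
    try:
        return _ELEMENTS[symbol][0]
    except KeyError:
        raise KeyError(f"no atomic weight tabulated for element {symbol!r}") from None


def covalent_radius(symbol: str) -> float:
    try:
        return _ELEMENTS[symbol][1]
    except KeyError:
        raise KeyError(f"no covalent radius tabulated for element {symbol!r}") from None
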