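"""Chemical elements: symbols by atomic number and single-bond covalent radii.

The radii are the single-bond covalent radii of Pyykko & Atsumi (values in
Angstrom); they feed the distance criterion used for bond perception.
"""

from __future__ import annotations

SYMBOLS: tuple[str, ...] = (
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr", "Y", "Zr",
    "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd",
    "Pm", "Sm", "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb",
    "Lu", "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
    "Tl", "Pb", "Bi", "Po", "At", "Rn", "Fr", "Ra", "Ac", "Th",
    "Pa", "U", "Np", "Pu", "Am", "Cm", "Bk", "Cf", "Es", "Fm",
    "Md", "No", "Lr",
)

_BY_SYMBOL = {s.upper(): z + 1 for z, s in enumerate(SYMBOLS)}

COVALENT_RADII: dict[str, float] = {
    "H": 0.32, "He": 0.46, "Li": 1.33, "Be": 1.02, "B": 0.85,
    "C": 0.75, "N": 0.71, "O": 0.63, "F": 0.64, "Ne": 0.67,
    "Na": 1.55, "Mg": 1.39, "Al": 1.26, "Si": 1.16, "P": 1.11,
    "S": 1.03, "Cl": 0.99, "Ar": 0.96, "K": 1.96, "Ca": 1.71,
    "Sc": 1.48, "Ti": 1.36, "V": 1.34, "Cr": 1.22, "Mn": 1.19,
    "Fe": 1.16, "Co": 1.11, "Ni": 1.10, "Cu": 1.12, "Zn": 1.18,
    "Ga": 1.24, "Ge": 1.21, "As": 1.21, "Se": 1.16, "Br": 1.14,
    "Kr": 1.17, "Rb": 2.10, "Sr": 1.85, "Y": 1.63, "Zr": 1.54,
    "Nb": 1.47, "Mo": 1.38, "Tc": 1.28, "Ru": 1.25, "Rh": 1.25,
    "Pd": 1.20, "Ag": 1.28, "Cd": 1.36, "In": 1.42, "Sn": 1.40,
    "Sb": 1.40, "Te": 1.36, "I": 1.33, "Xe": 1.31, "Cs": 2.32,
    "Ba": 1.96, "La": 1.80, "Ce": 1.63, "Pr": 1.76, "Nd": 1.74,
    "Pm": 1.73, "Sm": 1.72, "Eu": 1.68, "Gd": 1.69, "Tb": 1.68,
    "Dy": 1.67, "Ho": 1.66, "Er": 1.65, "Tm": 1.64, "Yb": 1.70,
    "Lu": 1.62, "Hf": 1.52, "Ta": 1.46, "W": 1.37, "Re": 1.31,
    "Os": 1.29, "Ir": 1.22, "Pt": 1.23, "Au": 1.24, "Hg": 1.33,
    "Tl": 1.44, "Pb": 1.44, "Bi": 1.51, "Po": 1.45, "At": 1.47,
    "Rn": 1.42, "Fr": 2.23, "Ra": 2.01, "Ac": 1.86, "Th": 1.75,
    "Pa": 1.69, "U": 1.70, "Np": 1.71, "Pu": 1.72, "Am": 1.66,
    "Cm": 1.66,
}

_DEFAULT_RADIUS = 1.70  # fallback for the heaviest elements


def symbol_for_number(z: int) -> str:
    """Element symbol for atomic number ``z`` (1..103)."""
    if not 1 <= z <= len(SYMBOLS):
        raise ValueError(f"atomic number {z} out of range 1..{len(SYMBOLS)}")
    return SYMBOLS[z - 1]


def number_for_symbol(symbol: str) -> int:
    """Atomic number for an element symbol, case-insensitively."""
    try:
        return _BY_SYMBOL[symbol.upper()]
    except KeyError:
        raise ValueError(f"unknown element symbol {symbol!r}") from None


def is_element(symbol: str) -> bool:
    return symbol.upper() in _BY_SYMBOL


def covalent_radius(symbol: str) -> float:
    """Single-bond covalent radius in Angstrom."""
    z = number_for_symbol(symbol)  # validates
    return COVALENT_RADII.get(SYMBOLS[z - 1], _DEFAULT_RADIUS)
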