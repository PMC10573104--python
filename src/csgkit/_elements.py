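"""Element tables: IUPAC standard atomic weights and Bondi van der Waals radii.

Masses are 2021 IUPAC conventional atomic weights (amu).  Radii are the
Bondi (1964) van der Waals set (Å), used for Merz-Singh-Kollman style
shell construction.  Unknown elements raise; descriptor code must never
silently assign a default mass.
"""

from __future__ import annotations

ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "D": 2.014,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "NA": 22.990,
    "MG": 24.305,
    "P": 30.974,
    "S": 32.06,
    "CL": 35.45,
    "K": 39.098,
    "CA": 40.078,
    "MN": 54.938,
    "FE": 55.845,
    "CU": 63.546,
    "ZN": 65.38,
    "SE": 78.971,
    "BR": 79.904,
    "I": 126.904,
}

#: Bondi vdW radii, Å.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "NA": 2.27,
    "K": 2.75,
}

ATOMIC_NUMBERS: dict[str, int] = {
    "H": 1, "D": 1, "C": 6, "N": 7, "O": 8, "F": 9, "NA": 11, "MG": 12,
    "P": 15, "S": 16, "CL": 17, "K": 19, "CA": 20, "MN": 25, "FE": 26,
    "CU": 29, "ZN": 30, "SE": 34, "BR": 35, "I": 53,
}

#: Two-letter element symbols we accept when inferring elements from atom
#: names (monatomic-ion style names, e.g. "NA" in residue "NA").
TWO_LETTER_IONS = {"NA", "CL", "MG", "ZN", "FE", "MN", "CU", "BR", "K"}


def mass_of(element: str) -> float:
    """Atomic mass (amu) for an element symbol; unknown symbol is an error."""
    try:
        return ATOMIC_MASSES[element.upper()]
    except KeyError:
        raise ValueError(f"unknown element symbol {element!r}: no mass available") from None


def vdw_radius_of(element: str) -> float:
    try:
        return VDW_RADII[element.upper()]
    except KeyError:
        raise ValueError(f"unknown element symbol {element!r}: no vdW radius available") from None


def element_from_name(name: str, resname: str = "") -> str:
    """Infer an element symbol from a PDB atom name.

    Digits are stripped; the first remaining alphabetic character is the
    element, except for monatomic-ion names ("NA", "CL", ...) where the
    whole stripped name matches a two-letter symbol and the residue name
    agrees (so "CA" in an amino acid stays carbon).
    """
    stripped = "".join(ch for ch in name if ch.isalpha()).upper()
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {name!r}")
    res = resname.strip().upper().rstrip("+-")
    if stripped in TWO_LETTER_IONS and res == stripped:
        return stripped
    return stripped[0]
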