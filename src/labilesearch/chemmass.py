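"""Monoisotopic mass bookkeeping: elements, compositions, residues, m/z.

All arithmetic is done at full double precision; rounding happens only in
reporting/tests. Two charge-carrier conventions are exposed because
user-facing diagnostic-ion m/z values are conventionally printed as
neutral-fragment mass plus one hydrogen *atom*, while internal fragment m/z
computation uses the proton mass.
"""

from __future__ import annotations

import math
import re
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

__all__ = [
    "ATOMIC_MASS",
    "PROTON_MASS",
    "HYDROGEN_MASS",
    "WATER_MASS",
    "AMMONIA_MASS",
    "ISOTOPE_SPACING",
    "RESIDUE_COMPOSITION",
    "RESIDUE_MASS",
    "Composition",
    "parse_composition",
    "mass_of",
    "peptide_mass",
    "mz_from_mass",
    "neutral_from_mz",
    "ppm_diff",
]

# Monoisotopic atomic masses (Da), CODATA/IUPAC.
ATOMIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207117,
    "Se": 79.9165213,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
    "Br": 78.9183371,
    "F": 18.99840322,
    "I": 126.904473,
    "Fe": 55.9349375,
}

PROTON_MASS = 1.00727646688
HYDROGEN_MASS = ATOMIC_MASS["H"]
ISOTOPE_SPACING = 1.00335483  # C13 - C12


class Composition(dict):
    """Element -> count mapping with additive arithmetic.

    Subtraction may produce negative counts as an intermediate; ``mass_of``
    rejects negative finalized compositions.
    """

    def __init__(self, counts: Mapping[str, int] | Iterable[tuple[str, int]] = ()):
        super().__init__()
        for element, count in dict(counts).items():
            if element not in ATOMIC_MASS:
                raise ValueError(f"unknown element symbol: {element!r}")
            if count:
                self[element] = int(count)

    def __add__(self, other: "Composition") -> "Composition":
        result = dict(self)
        for element, count in other.items():
            result[element] = result.get(element, 0) + count
        return Composition({e: c for e, c in result.items() if c})

    def __sub__(self, other: "Composition") -> "Composition":
        out = Composition()
        merged = dict(self)
        for element, count in other.items():
            merged[element] = merged.get(element, 0) - count
        for element, count in merged.items():
            if count:
                dict.__setitem__(out, element, count)
        return out

    def __mul__(self, k: int) -> "Composition":
        return Composition({e: c * k for e, c in self.items()})

    __rmul__ = __mul__


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_composition(formula: str) -> Composition:
    """Parse an element-count formula such as ``"C15H21N5O13P2"``.

    Counts default to 1. Unknown element symbols and malformed input raise
    ``ValueError`` naming the offending token.
    """
    if not isinstance(formula, str) or not formula.strip():
        raise ValueError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    formula = formula.strip()
    while pos < len(formula):
        m = _FORMULA_TOKEN.match(formula, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise ValueError(f"malformed formula at {formula[pos:]!r}")
        element, digits = m.group(1), m.group(2)
        if element not in ATOMIC_MASS:
            raise ValueError(f"unknown element symbol: {element!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return Composition(counts)


def mass_of(comp: Mapping[str, int]) -> float:
    """Monoisotopic mass (Da) of a finalized, non-negative composition."""
    total = 0.0
    for element, count in comp.items():
        if count < 0:
            raise ValueError(f"negative count for {element}: {count}")
        try:
            total += count * ATOMIC_MASS[element]
        except KeyError:
            raise ValueError(f"unknown element symbol: {element!r}") from None
    return total


# Residue (i.e. amino acid minus water) elemental compositions.
RESIDUE_COMPOSITION: dict[str, Composition] = {
    "G": parse_composition("C2H3NO"),
    "A": parse_composition("C3H5NO"),
    "S": parse_composition("C3H5NO2"),
    "P": parse_composition("C5H7NO"),
    "V": parse_composition("C5H9NO"),
    "T": parse_composition("C4H7NO2"),
    "C": parse_composition("C3H5NOS"),
    "L": parse_composition("C6H11NO"),
    "I": parse_composition("C6H11NO"),
    "N": parse_composition("C4H6N2O2"),
    "D": parse_composition("C4H5NO3"),
    "Q": parse_composition("C5H8N2O2"),
    "K": parse_composition("C6H12N2O"),
    "E": parse_composition("C5H7NO3"),
    "M": parse_composition("C5H9NOS"),
    "H": parse_composition("C6H7N3O"),
    "F": parse_composition("C9H9NO"),
    "R": parse_composition("C6H12N4O"),
    "Y": parse_composition("C9H9NO2"),
    "W": parse_composition("C11H10N2O"),
}

RESIDUE_MASS: dict[str, float] = {
    aa: mass_of(comp) for aa, comp in RESIDUE_COMPOSITION.items()
}

WATER_MASS = mass_of(parse_composition("H2O"))
AMMONIA_MASS = mass_of(parse_composition("NH3"))


def peptide_mass(sequence: str, mods: Iterable[tuple[int, float]] = ()) -> float:
    """Neutral monoisotopic peptide mass.

    ``mods`` is a list of ``(position, delta_Da)`` with 1-based residue
    positions; position 0 denotes the N terminus. The delta is added
    regardless of position (position only needs to be in range).
    """
    total = WATER_MASS
    for aa in sequence:
        try:
            total += RESIDUE_MASS[aa]
        except KeyError:
            raise ValueError(f"non-canonical residue: {aa!r} in {sequence!r}") from None
    n = len(sequence)
    for position, delta in mods:
        if not 0 <= position <= n:
            raise ValueError(f"mod position {position} outside peptide of length {n}")
        total += delta
    return total


@dataclass(frozen=True)
class ChargeConvention:
    """Mass of the charge carrier added per unit charge."""

    carrier_mass: float
    name: str = "proton"


PROTON = ChargeConvention(PROTON_MASS, "proton")
HYDROGEN = ChargeConvention(HYDROGEN_MASS, "hydrogen")


def mz_from_mass(neutral: float, z: int, convention: ChargeConvention = PROTON) -> float:
    """m/z of a neutral mass at charge ``z`` (>= 1)."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return (neutral + z * convention.carrier_mass) / z


def neutral_from_mz(mz: float, z: int, convention: ChargeConvention = PROTON) -> float:
    """Inverse of :func:`mz_from_mass`."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return z * mz - z * convention.carrier_mass


def ppm_diff(observed: float, theoretical: float) -> float:
    """Signed relative error in parts per million."""
    if theoretical <= 0:
        raise ValueError(f"theoretical mass must be > 0, got {theoretical}")
    return 1e6 * (observed - theoretical) / theoretical


def ppm_window(mass: float, tol_ppm: float) -> float:
    """Absolute half-width (Da) of a ppm tolerance window around ``mass``."""
    return abs(mass) * tol_ppm * 1e-6


def log10_factorial(n: int, cap: int = 64) -> float:
    """log10(n!) with ``n`` capped; used by the hyperscore."""
    n = min(int(n), cap)
    return math.lgamma(n + 1) / math.log(10.0)
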