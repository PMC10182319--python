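"""Theoretical backbone fragment ions (b/y/c/z) with remainder-mass variants.

The labile offset of a candidate never shifts a fragment (complete-loss
model); fragment-remainder variants are generated one site at a time by
:func:`apply_fragment_remainder` during scoring/localization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .chemmass import (
    AMMONIA_MASS,
    HYDROGEN_MASS,
    PROTON,
    RESIDUE_MASS,
    WATER_MASS,
    ChargeConvention,
    mz_from_mass,
)
from .protein_db import ModForm

PREFIX_SERIES = frozenset("bc")
SUFFIX_SERIES = frozenset("yz")

# Neutral-mass offsets relative to the plain residue sum of the span.
# b: prefix residues; y: suffix + H2O; c: b + NH3; z: z-dot = y - NH3 + H.
_SERIES_OFFSET = {
    "b": 0.0,
    "y": WATER_MASS,
    "c": AMMONIA_MASS,
    "z": WATER_MASS - AMMONIA_MASS + HYDROGEN_MASS,
}


@dataclass(frozen=True)
class TheoreticalIon:
    series: str  # b, y, c or z
    ordinal: int  # 1..n-1
    charge: int
    mz: float
    remainder: float = 0.0  # 0 for a base ion

    @property
    def is_prefix(self) -> bool:
        return self.series in PREFIX_SERIES

    def covers(self, site: int, peptide_length: int) -> bool:
        """True if this ion's residue span contains 1-based ``site``.

        N-terminal mods (site 0) ride on prefix ions; a C-terminal site
        (n) rides on suffix ions.
        """
        if self.is_prefix:
            return site <= self.ordinal
        return site > peptide_length - self.ordinal or site == peptide_length


def default_fragment_charges(precursor_charge: int) -> tuple[int, ...]:
    """Engine convention: singly charged fragments for z<=2 precursors."""
    return (1,) if precursor_charge <= 2 else (1, 2)


def theoretical_ions(
    form: ModForm,
    series: Iterable[str] = "by",
    max_frag_charge: int = 1,
    convention: ChargeConvention = PROTON,
) -> list[TheoreticalIon]:
    """All base ions for a ModForm: ordinals 1..n-1, charges 1..max.

    Placed variable mods shift every ion whose span covers their site; the
    labile offset shifts nothing.
    """
    series = list(series)
    if not series:
        raise ValueError("series set must be nonempty")
    seq = form.sequence
    n = len(seq)
    residue = [RESIDUE_MASS[aa] for aa in seq]
    mod_at = [0.0] * (n + 1)  # index 0 = N-term
    for pos, delta, _ in form.var_mods:
        mod_at[pos] += delta

    prefix = [0.0] * (n + 1)  # prefix[i] = residues 1..i + mods at 0..i
    acc = mod_at[0]
    for i in range(1, n + 1):
        acc += residue[i - 1] + mod_at[i]
        prefix[i] = acc
    total = prefix[n]

    ions: list[TheoreticalIon] = []
    for s in series:
        try:
            offset = _SERIES_OFFSET[s]
        except KeyError:
            raise ValueError(f"unknown ion series {s!r}") from None
        for ordinal in range(1, n):
            if s in PREFIX_SERIES:
                neutral = prefix[ordinal] + offset
            else:
                neutral = total - prefix[n - ordinal] + offset
            for z in range(1, max_frag_charge + 1):
                ions.append(TheoreticalIon(s, ordinal, z, mz_from_mass(neutral, z, convention)))
    return ions


def apply_fragment_remainder(
    ions: Sequence[TheoreticalIon],
    form: ModForm,
    site: int,
    remainder: float,
) -> list[TheoreticalIon]:
    """Remainder variants of the base ions whose span covers ``site``.

    Returns only the *additional* ions; ``remainder`` may be negative and a
    zero remainder yields no variants (they would duplicate the base ions).
    """
    n = len(form.sequence)
    if not 0 <= site <= n:
        raise ValueError(f"site {site} outside peptide of length {n}")
    if remainder == 0.0:
        return []
    variants = []
    for ion in ions:
        if ion.remainder == 0.0 and ion.covers(site, n):
            variants.append(replace(ion, mz=ion.mz + remainder / ion.charge, remainder=remainder))
    return variants


def peptide_remainder_mzs(
    form: ModForm,
    remainders: Sequence[float],
    charges: Iterable[int],
    convention: ChargeConvention = PROTON,
) -> list[tuple[float, str]]:
    """m/z values of intact-peptide ions retaining a modification remainder.

    Uses the peptide mass with placed mods but without the labile offset
    (the remainder replaces the lost modification). ``r = 0`` gives the
    complete-loss peptide ion.
    """
    base = form.placed_mass
    out = []
    for r in remainders:
        for z in charges:
            out.append((mz_from_mass(base + r, z, convention), f"pepR{r:+.5f}/z{z}"))
    return out
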