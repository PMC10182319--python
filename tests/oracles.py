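"""Independent reference implementations used to check the package.

Everything here is deliberately naive: hand-typed constants, linear scans
and exhaustive enumeration. Nothing imports the modules under test except
for shared dataclass containers.
"""

from __future__ import annotations

import itertools
import math

# Hand-typed residue monoisotopic masses (5 dp, standard table) — kept
# separate from the package's composition-derived table on purpose.
ORACLE_RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
ORACLE_WATER = 18.01056
ORACLE_PROTON = 1.00727646688
ORACLE_NH3 = 17.02655
ORACLE_H = 1.00782503207


def oracle_peptide_mass(sequence: str) -> float:
    return sum(ORACLE_RESIDUE_MASS[aa] for aa in sequence) + ORACLE_WATER


def oracle_digest(sequence: str, missed: int, min_len: int, max_len: int,
                  clip_met: bool) -> set[tuple[str, bool]]:
    """All strict-trypsin peptides by brute-force cut-point enumeration."""
    cuts = [0] + [i + 1 for i in range(len(sequence) - 1) if sequence[i] in "KR"] \
        + [len(sequence)]
    out: set[tuple[str, bool]] = set()
    for a_idx in range(len(cuts) - 1):
        for b_idx in range(a_idx + 1, len(cuts)):
            if b_idx - a_idx - 1 > missed:
                continue
            pep = sequence[cuts[a_idx]: cuts[b_idx]]
            if min_len <= len(pep) <= max_len:
                out.add((pep, False))
            if clip_met and cuts[a_idx] == 0 and sequence.startswith("M"):
                clipped = pep[1:]
                if min_len <= len(clipped) <= max_len:
                    out.add((clipped, True))
    return out


def oracle_by_ions(sequence: str, mods: dict[int, float], max_charge: int,
                   series: str = "by") -> list[tuple[str, int, int, float]]:
    """(series, ordinal, charge, mz) by direct prefix/suffix summation."""
    n = len(sequence)
    ions = []
    for s in series:
        for i in range(1, n):
            if s in "bc":
                neutral = sum(ORACLE_RESIDUE_MASS[aa] for aa in sequence[:i])
                neutral += sum(d for p, d in mods.items() if p <= i)
                if s == "c":
                    neutral += ORACLE_NH3
            else:
                neutral = sum(ORACLE_RESIDUE_MASS[aa] for aa in sequence[n - i:]) + ORACLE_WATER
                neutral += sum(d for p, d in mods.items() if p > n - i)
                if s == "z":
                    neutral += ORACLE_H - ORACLE_NH3
            for z in range(1, max_charge + 1):
                ions.append((s, i, z, (neutral + z * ORACLE_PROTON) / z))
    return ions


def oracle_hyperscore(peaks_mz, peaks_int, ions, tol_ppm,
                      remainder_targets=()) -> float:
    """Naive greedy-unique hyperscore: for each ion in order, claim the
    nearest unclaimed peak (per prefix/suffix pool) within tolerance."""
    used_prefix: set[int] = set()
    used_suffix: set[int] = set()
    nb = ny = 0
    ib = iy = 0.0
    for series, _ordinal, _z, mz in ions:
        prefix = series in "bc"
        used = used_prefix if prefix else used_suffix
        best, bestd = -1, float("inf")
        for j, pmz in enumerate(peaks_mz):
            if j in used:
                continue
            d = abs(pmz - mz)
            if d <= abs(mz) * tol_ppm * 1e-6 and d < bestd:
                best, bestd = j, d
        if best < 0:
            continue
        used.add(best)
        if prefix:
            nb += 1
            ib += peaks_int[best]
        else:
            ny += 1
            iy += peaks_int[best]
    rem_int = 0.0
    claimed: set[int] = set()
    for target in remainder_targets:
        best, bestd = -1, float("inf")
        for j, pmz in enumerate(peaks_mz):
            if j in claimed:
                continue
            d = abs(pmz - target)
            if d <= abs(target) * tol_ppm * 1e-6 and d < bestd:
                best, bestd = j, d
        if best >= 0:
            claimed.add(best)
            rem_int += peaks_int[best]
    if nb + ny == 0 and rem_int == 0.0:
        return 0.0
    return (
        math.log10(math.factorial(min(nb, 64)))
        + math.log10(math.factorial(min(ny, 64)))
        + math.log10(max(ib, 1.0))
        + math.log10(max(iy + rem_int, 1.0))
    )


def oracle_qvalues(scores_flags: list[tuple[float, bool]]) -> list[float]:
    """q per input PSM by brute force over every threshold."""
    qs = []
    for score, _flag in scores_flags:
        best = float("inf")
        for t, _ in scores_flags:
            if t > score:  # acceptance set {s >= t} must contain this PSM
                continue
            nd = sum(1 for s, d in scores_flags if s >= t and d)
            nt = sum(1 for s, d in scores_flags if s >= t and not d)
            best = min(best, nd / max(1, nt))
        qs.append(min(best, 1.0))
    return qs


def oracle_window_query(entries, lo: float, hi: float):
    return [e for e in entries if lo <= e.neutral_mass <= hi]


# ---------------------------------------------------------------------------
# Exhaustive no-index reference search (for oracle-equivalence acceptance).
# Shares only verified mass constants with the package; candidate retrieval,
# ion generation, matching and tie-breaking are reimplemented with plain
# loops.

from labilesearch.chemmass import (  # noqa: E402  (constants only)
    PROTON_MASS as _PROTON,
    RESIDUE_MASS as _RESMASS,
    WATER_MASS as _WATER,
)


def _ref_ions(sequence: str, max_charge: int, series: str = "by"):
    """(series, ordinal, charge, mz) in the engine's documented order."""
    n = len(sequence)
    out = []
    for s in series:
        for i in range(1, n):
            if s == "b":
                neutral = sum(_RESMASS[aa] for aa in sequence[:i])
            else:
                neutral = sum(_RESMASS[aa] for aa in sequence[n - i:]) + _WATER
            for z in range(1, max_charge + 1):
                out.append((s, i, z, (neutral + z * _PROTON) / z))
    return out


def _ref_gate(mz_list, int_list, spec, tol_ppm):
    if spec.diagnostic_min_intensity <= 0:
        return True
    total = 0.0
    for target in spec.diagnostic_mzs:
        best, bestd = None, float("inf")
        for m, it in zip(mz_list, int_list):
            d = abs(m - target)
            if d <= target * tol_ppm * 1e-6 and d < bestd:
                best, bestd = it, d
        if best is not None:
            total += best
    return total >= spec.diagnostic_min_intensity


def reference_search(spectrum, entries, spec, *, precursor_tol_ppm=20.0,
                     fragment_tol_ppm=10.0, min_matched=4, max_frag_charge=1):
    """Exhaustive labile-mode search of one spectrum over all entries.

    Returns (sequence, is_decoy, labile_count, score) for the winner or
    None. Mirrors the engine contract: offsets {0, k*offset} (k <= max,
    gated), complete-loss vs per-site remainder pathways, greedy-unique
    hyperscore, tie-break by (score desc, mod count, nonlabile first,
    sequence).
    """
    mz_list = list(spectrum.mz)
    int_list = list(spectrum.intensity)
    precursor = (spectrum.precursor_charge * spectrum.precursor_mz
                 - spectrum.precursor_charge * _PROTON)
    tol_da = precursor * precursor_tol_ppm * 1e-6
    gate = _ref_gate(mz_list, int_list, spec, fragment_tol_ppm)
    offsets = [(0.0, 0)]
    if gate:
        offsets += [(k * spec.offset, k) for k in range(1, spec.max_per_peptide + 1)]

    candidates = []
    for entry in entries:
        for offset, count in offsets:
            if abs(precursor - offset - entry.neutral_mass) > tol_da:
                continue
            ions = _ref_ions(entry.sequence, max_frag_charge)
            rem_targets = []
            if count > 0 and spec.peptide_remainders:
                for r in spec.peptide_remainders:
                    for z in range(1, spectrum.precursor_charge + 1):
                        rem_targets.append((entry.neutral_mass + r + z * _PROTON) / z)
            variants_sets = [ions]
            if count == 1 and spec.fragment_remainders:
                n = len(entry.sequence)
                sites = ([i + 1 for i in range(n)] if "*" in spec.residues else
                         [i + 1 for i, aa in enumerate(entry.sequence)
                          if aa in spec.residues])
                for remainder in spec.fragment_remainders:
                    for site in sites:
                        extra = []
                        for s, i, z, m in ions:
                            covered = site <= i if s == "b" else site >= n - i + 1
                            if covered:
                                extra.append((s, i, z, m + remainder / z))
                        if extra:
                            variants_sets.append(ions + extra)
            best_score = None
            for ion_set in variants_sets:
                score = oracle_hyperscore(mz_list, int_list, ion_set,
                                          fragment_tol_ppm,
                                          rem_targets if count > 0 else ())
                nb_ny = _ref_matched_count(mz_list, ion_set, fragment_tol_ppm)
                if best_score is None or score > best_score[0]:
                    best_score = (score, nb_ny)
            score, matched = best_score
            if score > 0 and matched >= min_matched:
                candidates.append((score, count, entry.sequence,
                                   entry.is_decoy))
    if not candidates:
        return None
    candidates.sort(key=lambda c: (-c[0], c[1], 1 if c[1] > 0 else 0, c[2]))
    score, count, seq, decoy = candidates[0]
    return seq, decoy, count, score


def _ref_matched_count(mz_list, ions, tol_ppm):
    used_prefix, used_suffix = set(), set()
    for series, _i, _z, mz in ions:
        used = used_prefix if series in "bc" else used_suffix
        best, bestd = -1, float("inf")
        for j, pmz in enumerate(mz_list):
            if j in used:
                continue
            d = abs(pmz - mz)
            if d <= abs(mz) * tol_ppm * 1e-6 and d < bestd:
                best, bestd = j, d
        if best >= 0:
            used.add(best)
    return len(used_prefix) + len(used_suffix)
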