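"""The search core: diagnostic-ion gating, mass-offset candidate selection,
hyperscore with remainder-ion evidence, nonlabile/labile/hybrid candidate
competition, and remainder-based site localization.

A spectrum is searched by enumerating, for every admissible precursor-mass
explanation (zero offset, each gated labile-offset multiple, each
variable-mod delta combination, each isotope error), the peptide entries in
the matching index window, expanding them to concrete candidates, scoring
every candidate and keeping the best.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .chemmass import ISOTOPE_SPACING, log10_factorial, ppm_window
from .fragments import (
    TheoreticalIon,
    apply_fragment_remainder,
    default_fragment_charges,
    peptide_remainder_mzs,
    theoretical_ions,
)
from .protein_db import ModForm, PeptideEntry, PeptideMassIndex, VariableMod
from .spectra_io import ProcessedSpectrum

UNLOCALIZED = -1


@dataclass(frozen=True)
class LabileModSpec:
    """One labile modification: offset, gating and remainder configuration."""

    label: str
    offset: float
    residues: str  # allowed residues; '*' = any; may include '[' / ']'
    max_per_peptide: int = 1
    diagnostic_mzs: tuple[float, ...] = ()
    diagnostic_min_intensity: float = 0.0  # normalized units; 0 disables gating
    peptide_remainders: tuple[float, ...] = ()
    fragment_remainders: tuple[float, ...] = ()  # may be negative

    def __post_init__(self) -> None:
        if self.offset == 0:
            raise ValueError("labile offset must be nonzero")
        if self.max_per_peptide < 1:
            raise ValueError("max_per_peptide must be >= 1")
        if self.diagnostic_min_intensity < 0:
            raise ValueError("diagnostic threshold must be >= 0")

    def allowed_sites(self, sequence: str) -> list[int]:
        if "*" in self.residues:
            return list(range(1, len(sequence) + 1))
        sites = [i + 1 for i, aa in enumerate(sequence) if aa in self.residues]
        if "[" in self.residues:
            sites.insert(0, 0)
        return sites


@dataclass
class SearchParams:
    precursor_tol_ppm: float = 20.0
    fragment_tol_ppm: float = 10.0
    mode: str = "labile"  # nonlabile | labile | hybrid
    series: str = "by"
    fixed_mods: tuple[VariableMod, ...] = ()
    variable_mods: tuple[VariableMod, ...] = ()
    max_variable_mods: int = 3
    labile_specs: tuple[LabileModSpec, ...] = ()
    min_matched_fragments: int = 4
    isotope_errors: tuple[int, ...] = (0, 1, 2)
    max_frag_charge: int | None = None  # None -> by precursor charge

    def __post_init__(self) -> None:
        if self.precursor_tol_ppm <= 0 or self.fragment_tol_ppm <= 0:
            raise ValueError("tolerances must be > 0")
        if self.mode not in ("nonlabile", "labile", "hybrid"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode in ("labile", "hybrid") and not self.labile_specs:
            raise ValueError(f"{self.mode} mode requires at least one labile spec")


@dataclass
class MatchDetail:
    n_prefix: int = 0
    n_suffix: int = 0
    intensity_prefix: float = 0.0
    intensity_suffix: float = 0.0
    peptide_remainder_intensity: float = 0.0
    n_remainder_ions: int = 0  # fragment-remainder variants among the matches
    matched_mzs: tuple[float, ...] = ()

    @property
    def n_matched(self) -> int:
        return self.n_prefix + self.n_suffix


@dataclass
class Localization:
    site: int  # 1-based residue position, or UNLOCALIZED
    site_scores: dict[int, float] = field(default_factory=dict)
    best_remainder: float = 0.0


@dataclass
class PSM:
    scan_id: str
    form: ModForm
    hyperscore: float
    detail: MatchDetail
    precursor_delta: float = 0.0
    isotope_error: int = 0
    next_best: float = 0.0
    localization: Localization | None = None
    pathway: str = "base"  # base | complete-loss | remainder@<site>
    charge: int = 0
    q_value: float = float("nan")

    @property
    def is_decoy(self) -> bool:
        return self.form.entry.is_decoy

    @property
    def delta_score(self) -> float:
        return max(0.0, self.hyperscore - self.next_best)


def diagnostic_gate(
    s: ProcessedSpectrum, spec: LabileModSpec, tol_ppm: float
) -> bool:
    """True iff summed intensity at the diagnostic m/z values meets threshold.

    For each configured m/z the nearest peak within tolerance contributes
    its intensity. A zero threshold (or no diagnostic ions) always passes.
    """
    if spec.diagnostic_min_intensity <= 0:
        return True
    total = 0.0
    for target in spec.diagnostic_mzs:
        tol = ppm_window(target, tol_ppm)
        lo = np.searchsorted(s.mz, target - tol, side="left")
        hi = np.searchsorted(s.mz, target + tol, side="right")
        if hi > lo:
            nearest = lo + int(np.argmin(np.abs(s.mz[lo:hi] - target)))
            total += float(s.intensity[nearest])
    return total >= spec.diagnostic_min_intensity


def offset_combinations(
    specs: Sequence[LabileModSpec],
    gate_results: Sequence[bool],
    cap: int,
) -> list[tuple[float, str, int]]:
    """(offset, label, count) variants; each spec gated independently; 0 always present."""
    variants: list[tuple[float, str, int]] = [(0.0, "", 0)]
    active = [
        spec for spec, passed in zip(specs, gate_results) if passed
    ]
    if not active:
        return variants
    ranges = [range(0, spec.max_per_peptide + 1) for spec in active]
    for counts in itertools.product(*ranges):
        total = sum(counts)
        if total == 0 or total > cap:
            continue
        offset = sum(k * spec.offset for k, spec in zip(counts, active))
        label = "+".join(f"{s.label}x{k}" for k, s in zip(counts, active) if k)
        variants.append((offset, label, total))
    return variants


def _effective_variable_mods(params: SearchParams) -> list[VariableMod]:
    mods = list(params.variable_mods)
    if params.mode == "hybrid":
        for spec in params.labile_specs:
            mods.append(VariableMod(spec.label, spec.offset, spec.residues, spec.max_per_peptide))
    return mods


def variable_delta_sums(mods: Sequence[VariableMod], cap: int) -> list[float]:
    """Distinct achievable total deltas of <= ``cap`` variable mods (0 included)."""
    sums = {0.0}
    ranges = [range(0, min(m.max_per_peptide, cap) + 1) for m in mods]
    for counts in itertools.product(*ranges):
        if 0 < sum(counts) <= cap:
            sums.add(sum(k * m.delta for k, m in zip(counts, mods)))
    uniq: dict[float, float] = {}
    for v in sums:
        uniq.setdefault(round(v, 5), v)
    return sorted(uniq.values())


def candidates_for(
    s: ProcessedSpectrum,
    index: PeptideMassIndex,
    specs: Sequence[LabileModSpec],
    mode: str,
    tol_ppm: float,
    gate_results: Sequence[bool],
    cap: int = 3,
    isotope_errors: Sequence[int] = (0,),
    var_delta_sums: Sequence[float] = (0.0,),
) -> list[tuple[PeptideEntry, float, str, int, int]]:
    """Peptide entries whose mass + an allowed offset (plus, optionally, a
    variable-mod delta sum) explains the precursor.

    Returns (entry, offset, offset_label, labile_count, isotope_error)
    tuples. When the gate failed for every spec (or mode is nonlabile) only
    zero-offset candidates are produced.
    """
    if mode == "nonlabile":
        variants = [(0.0, "", 0)]
    else:
        variants = offset_combinations(specs, gate_results, cap)
    precursor = s.precursor_neutral_mass
    half = ppm_window(precursor, tol_ppm)
    out = []
    seen: set[tuple[int, float, int]] = set()
    for iso in isotope_errors:
        target_base = precursor - iso * ISOTOPE_SPACING
        for offset, label, count in variants:
            for vsum in var_delta_sums:
                center = target_base - offset - vsum
                for entry in index.query(center - half, center + half):
                    key = (id(entry), offset, iso)
                    if key not in seen:
                        seen.add(key)
                        out.append((entry, offset, label, count, iso))
    return out


def hyperscore(
    s: ProcessedSpectrum,
    ions: Sequence[TheoreticalIon],
    tol_ppm: float,
    remainder_peaks: Sequence[tuple[float, str]] = (),
) -> tuple[float, MatchDetail]:
    """X!Tandem-style hyperscore with remainder-ion evidence.

    Theoretical ions are greedily matched to the nearest unclaimed peak
    within tolerance; each peak is matched at most once per series pool
    (prefix vs suffix). Matched peptide-remainder peaks add intensity to
    the suffix sum but never to the factorial counts. Score is
    ``log10(Nb! * Ny! * max(SIb,1) * max(SIy,1))`` and 0 when nothing
    matched.
    """
    used: dict[bool, set[int]] = {True: set(), False: set()}
    detail = MatchDetail()
    matched: list[float] = []
    n_prefix = n_suffix = n_rem = 0
    i_prefix = i_suffix = 0.0
    mz, inten = s.mz, s.intensity
    for ion in ions:
        tol = ppm_window(ion.mz, tol_ppm)
        lo = np.searchsorted(mz, ion.mz - tol, side="left")
        hi = np.searchsorted(mz, ion.mz + tol, side="right")
        best_j, best_d = -1, math.inf
        pool = used[ion.is_prefix]
        for j in range(lo, hi):
            if j in pool:
                continue
            d = abs(mz[j] - ion.mz)
            if d < best_d:
                best_j, best_d = j, d
        if best_j < 0:
            continue
        pool.add(best_j)
        matched.append(float(mz[best_j]))
        if ion.remainder != 0.0:
            n_rem += 1
        if ion.is_prefix:
            n_prefix += 1
            i_prefix += float(inten[best_j])
        else:
            n_suffix += 1
            i_suffix += float(inten[best_j])

    pep_rem_intensity = 0.0
    claimed: set[int] = set()
    for target, _label in remainder_peaks:
        tol = ppm_window(target, tol_ppm)
        lo = np.searchsorted(mz, target - tol, side="left")
        hi = np.searchsorted(mz, target + tol, side="right")
        best_j, best_d = -1, math.inf
        for j in range(lo, hi):
            if j in claimed:
                continue
            d = abs(mz[j] - target)
            if d < best_d:
                best_j, best_d = j, d
        if best_j >= 0:
            claimed.add(best_j)
            pep_rem_intensity += float(inten[best_j])

    detail = MatchDetail(
        n_prefix=n_prefix,
        n_suffix=n_suffix,
        intensity_prefix=i_prefix,
        intensity_suffix=i_suffix,
        peptide_remainder_intensity=pep_rem_intensity,
        n_remainder_ions=n_rem,
        matched_mzs=tuple(matched),
    )
    if n_prefix + n_suffix == 0 and pep_rem_intensity == 0.0:
        return 0.0, detail
    score = (
        log10_factorial(n_prefix)
        + log10_factorial(n_suffix)
        + math.log10(max(i_prefix, 1.0))
        + math.log10(max(i_suffix + pep_rem_intensity, 1.0))
    )
    return score, detail


def _frag_charges(params: SearchParams, precursor_charge: int) -> int:
    if params.max_frag_charge is not None:
        return params.max_frag_charge
    return max(default_fragment_charges(precursor_charge))


def _spec_for_offset(specs: Sequence[LabileModSpec], label: str) -> LabileModSpec | None:
    """The single spec behind an offset label, or None for mixed/zero offsets."""
    involved = [s for s in specs if f"{s.label}x" in label]
    return involved[0] if len(involved) == 1 else None


def score_labile(
    s: ProcessedSpectrum,
    form: ModForm,
    spec: LabileModSpec | None,
    params: SearchParams,
) -> PSM:
    """Score a nonzero-offset candidate: complete loss vs fragment-remainder.

    Computes the complete-loss score (base ions + peptide-remainder
    evidence), then for each configured fragment remainder and each allowed
    site a score with the remainder variants added, returning the best
    variant. Exact ties go to the complete-loss pathway.
    """
    maxz = _frag_charges(params, s.precursor_charge)
    ions = theoretical_ions(form, params.series, maxz)
    rem_peaks: list[tuple[float, str]] = []
    if spec is not None and spec.peptide_remainders:
        charges = range(1, s.precursor_charge + 1)
        rem_peaks = peptide_remainder_mzs(form, spec.peptide_remainders, charges)
    base_score, base_detail = hyperscore(s, ions, params.fragment_tol_ppm, rem_peaks)
    best = PSM(s.scan_id, form, base_score, base_detail, pathway="complete-loss")

    if spec is not None and spec.fragment_remainders and form.labile_count == 1:
        for remainder in spec.fragment_remainders:
            for site in spec.allowed_sites(form.sequence):
                variants = apply_fragment_remainder(ions, form, site, remainder)
                if not variants:
                    continue
                score, detail = hyperscore(
                    s, list(ions) + variants, params.fragment_tol_ppm, rem_peaks
                )
                if score > best.hyperscore:
                    best = PSM(
                        s.scan_id, form, score, detail,
                        pathway=f"remainder{remainder:+.5f}@{site}",
                    )
    return best


def _score_candidate(
    s: ProcessedSpectrum,
    form: ModForm,
    params: SearchParams,
) -> PSM:
    if form.labile_count > 0:
        spec = _spec_for_offset(params.labile_specs, form.labile_label)
        return score_labile(s, form, spec, params)
    maxz = _frag_charges(params, s.precursor_charge)
    ions = theoretical_ions(form, params.series, maxz)
    score, detail = hyperscore(s, ions, params.fragment_tol_ppm)
    return PSM(s.scan_id, form, score, detail, pathway="base")


def _tiebreak_key(psm: PSM) -> tuple:
    # higher score first; then fewer mods, nonlabile before labile, lexicographic
    return (
        -psm.hyperscore,
        psm.form.n_mods,
        1 if psm.form.labile_count > 0 else 0,
        psm.form.sequence,
        psm.form.var_mods,
    )


def _expand_entry(
    entry: PeptideEntry,
    offset: float,
    label: str,
    count: int,
    params: SearchParams,
    needed_var_delta: float,
    tol_da: float,
) -> list[ModForm]:
    """Concrete ModForms of an entry at a fixed offset whose placed variable
    mods sum (within tolerance) to the residual precursor delta."""
    forms: list[ModForm] = []
    effective_var = _effective_variable_mods(params)
    cap = params.max_variable_mods

    if abs(needed_var_delta) <= tol_da:
        forms.append(ModForm(entry, (), offset, label, count))

    if not effective_var:
        return forms

    pool: list[tuple[VariableMod, int]] = []
    for m in effective_var:
        sites = [i + 1 for i, aa in enumerate(entry.sequence) if aa in m.residues]
        if "[" in m.residues:
            sites.insert(0, 0)
        if "]" in m.residues:
            sites.append(len(entry.sequence))
        pool.extend((m, site) for site in sites)

    max_r = max(0, cap - count)
    for r in range(1, max_r + 1):
        for combo in itertools.combinations(pool, r):
            positions = [site for _, site in combo]
            if len(set(positions)) != len(positions):
                continue
            per_mod: dict[str, int] = {}
            ok = True
            total_delta = 0.0
            for m, _ in combo:
                per_mod[m.label] = per_mod.get(m.label, 0) + 1
                if per_mod[m.label] > m.max_per_peptide:
                    ok = False
                    break
                total_delta += m.delta
            if not ok or abs(total_delta - needed_var_delta) > tol_da:
                continue
            placements = tuple(sorted((site, m.delta, m.label) for m, site in combo))
            forms.append(ModForm(entry, placements, offset, label, count))
    return _dedupe_forms(forms)


def _dedupe_forms(forms: list[ModForm]) -> list[ModForm]:
    seen: set = set()
    out = []
    for f in forms:
        key = (f.sequence, f.entry.is_decoy, f.var_mods, round(f.labile_offset, 6), f.labile_count)
        if key not in seen:
            seen.add(key)
            out.append(f)
    return out


def search_spectrum(
    s: ProcessedSpectrum,
    index: PeptideMassIndex,
    params: SearchParams,
) -> PSM | None:
    """Search one preprocessed spectrum; returns the best PSM or None.

    Candidates are enumerated per mode, every candidate is scored (labile
    candidates via :func:`score_labile`), the argmax under deterministic
    tie-breaking wins, and the runner-up score from a *different* peptide
    sequence is recorded. PSMs with fewer matched fragments than the
    configured minimum are discarded.
    """
    if not getattr(s, "searchable", True):
        return None
    gates = [
        diagnostic_gate(s, spec, params.fragment_tol_ppm) for spec in params.labile_specs
    ]
    precursor = s.precursor_neutral_mass
    tol_da = ppm_window(precursor, params.precursor_tol_ppm)
    vsums = variable_delta_sums(_effective_variable_mods(params), params.max_variable_mods)
    cands = candidates_for(
        s, index, params.labile_specs, params.mode, params.precursor_tol_ppm,
        gates, cap=params.max_variable_mods, isotope_errors=params.isotope_errors,
        var_delta_sums=vsums,
    )
    scored: list[PSM] = []
    seen_forms: set = set()
    for entry, offset, label, count, iso in cands:
        needed = precursor - iso * ISOTOPE_SPACING - offset - entry.neutral_mass
        for form in _expand_entry(entry, offset, label, count, params, needed, tol_da):
            key = (form.sequence, form.entry.is_decoy, form.var_mods,
                   round(form.labile_offset, 6), form.labile_count)
            if key in seen_forms:
                continue
            seen_forms.add(key)
            psm = _score_candidate(s, form, params)
            psm.precursor_delta = needed if count == 0 else precursor - form.neutral_mass
            psm.isotope_error = iso
            if psm.hyperscore > 0 and psm.detail.n_matched >= params.min_matched_fragments:
                scored.append(psm)
    if not scored:
        return None
    scored.sort(key=_tiebreak_key)
    best = scored[0]
    best.charge = s.precursor_charge
    for other in scored[1:]:
        if other.form.sequence != best.form.sequence:
            best.next_best = other.hyperscore
            break
    if best.form.labile_count > 0:
        best.localization = localize(best, s, params)
    return best


def localize(psm: PSM, s: ProcessedSpectrum, params: SearchParams) -> Localization | None:
    """Best-site localization using fragment-remainder ions.

    Applicable only to single-labile-mod winners with >=1 configured
    fragment remainder; multi-labile forms are reported unlocalized. A site
    wins only if some site-discriminating remainder ion matched; full ties
    are unlocalized.
    """
    form = psm.form
    spec = _spec_for_offset(params.labile_specs, form.labile_label)
    if spec is None or not spec.fragment_remainders:
        return None
    if form.labile_count != 1:
        return Localization(UNLOCALIZED)
    sites = spec.allowed_sites(form.sequence)
    if not sites:
        return Localization(UNLOCALIZED)
    maxz = _frag_charges(params, s.precursor_charge)
    ions = theoretical_ions(form, params.series, maxz)
    rem_peaks: list[tuple[float, str]] = []
    if spec.peptide_remainders:
        rem_peaks = peptide_remainder_mzs(
            form, spec.peptide_remainders, range(1, s.precursor_charge + 1)
        )
    site_scores: dict[int, float] = {}
    site_rem_matches: dict[int, int] = {}
    best_rem: dict[int, float] = {}
    for site in sites:
        best_site_score, n_rem_best, rem_best = -math.inf, 0, 0.0
        for remainder in spec.fragment_remainders:
            variants = apply_fragment_remainder(ions, form, site, remainder)
            score, detail = hyperscore(
                s, list(ions) + variants, params.fragment_tol_ppm, rem_peaks
            )
            if score > best_site_score:
                best_site_score = score
                n_rem_best = detail.n_remainder_ions
                rem_best = remainder
        site_scores[site] = best_site_score
        site_rem_matches[site] = n_rem_best
        best_rem[site] = rem_best
    if len(sites) == 1:
        return Localization(sites[0], site_scores, best_rem[sites[0]])
    ranked = sorted(sites, key=lambda k: (-site_scores[k], k))
    top = ranked[0]
    if site_rem_matches[top] == 0 or math.isclose(
        site_scores[top], site_scores[ranked[1]], abs_tol=1e-9
    ):
        return Localization(UNLOCALIZED, site_scores)
    return Localization(top, site_scores, best_rem[top])


def search_dataset(
    spectra: Iterable[ProcessedSpectrum],
    index: PeptideMassIndex,
    params: SearchParams,
) -> list[PSM]:
    """Search many spectra; unsearchable or unmatched spectra are skipped."""
    results = []
    for s in spectra:
        psm = search_spectrum(s, index, params)
        if psm is not None:
            results.append(psm)
    return results
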