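"""FASTA parsing, tryptic digestion, decoy generation, modified-form
enumeration and the peptide-mass index used for candidate retrieval."""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .chemmass import peptide_mass

DECOY_PREFIX = "rev_"


@dataclass
class ProteinRecord:
    accession: str
    description: str
    sequence: str
    is_decoy: bool = False


@dataclass
class PeptideEntry:
    sequence: str
    accessions: frozenset[str]
    missed_cleavages: int
    met_clipped: bool
    neutral_mass: float  # unmodified + fixed mods
    is_decoy: bool = False


@dataclass(frozen=True)
class VariableMod:
    """A site-placed variable modification rule."""

    label: str
    delta: float
    residues: str  # residue letters; '[' = peptide N-term, ']' = C-term
    max_per_peptide: int = 3


@dataclass
class ModForm:
    """A concrete search candidate: peptide + placed mods + site-free offset."""

    entry: PeptideEntry
    var_mods: tuple[tuple[int, float, str], ...] = ()  # (pos 1-based; 0=N-term, delta, label)
    labile_offset: float = 0.0
    labile_label: str = ""
    labile_count: int = 0

    @property
    def sequence(self) -> str:
        return self.entry.sequence

    @property
    def neutral_mass(self) -> float:
        """Total candidate mass including placed mods and the labile offset."""
        return self.entry.neutral_mass + sum(d for _, d, _ in self.var_mods) + self.labile_offset

    @property
    def placed_mass(self) -> float:
        """Mass of the peptide with placed mods only (offset excluded)."""
        return self.entry.neutral_mass + sum(d for _, d, _ in self.var_mods)

    @property
    def n_mods(self) -> int:
        return len(self.var_mods) + self.labile_count


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse FASTA text into protein records (uppercased, '*' stripped)."""
    path = Path(path)
    records: list[ProteinRecord] = []
    accession, description, chunks = None, "", []
    seen: set[str] = set()

    def flush() -> None:
        if accession is None:
            return
        seq = "".join(chunks).upper().replace("*", "").replace(" ", "")
        if not seq:
            raise ValueError(f"FASTA record {accession!r} has no sequence")
        if accession in seen:
            warnings.warn(f"duplicate FASTA accession {accession!r}; keeping both")
        seen.add(accession)
        records.append(ProteinRecord(accession, description, seq,
                                     is_decoy=accession.startswith(DECOY_PREFIX)))

    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                accession, _, description = header.partition(" ")
                chunks = []
            else:
                chunks.append(line.strip())
    flush()
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def make_decoys(proteins: Sequence[ProteinRecord], prefix: str = DECOY_PREFIX) -> list[ProteinRecord]:
    """Whole-protein reversal decoys, one per target."""
    decoys = []
    for p in proteins:
        if p.is_decoy or p.accession.startswith(prefix):
            raise ValueError(f"refusing to build a decoy of decoy {p.accession!r}")
        decoys.append(
            ProteinRecord(prefix + p.accession, p.description, p.sequence[::-1], is_decoy=True)
        )
    return decoys


def _cleavage_sites(sequence: str, enzyme: str) -> list[int]:
    """Cut points (index after which the chain is cleaved), excluding termini."""
    if enzyme == "strict-trypsin":
        # cleave after K/R at every occurrence, including before Pro
        return [i + 1 for i, aa in enumerate(sequence[:-1]) if aa in "KR"]
    if enzyme == "trypsin":
        return [
            i + 1
            for i, aa in enumerate(sequence[:-1])
            if aa in "KR" and sequence[i + 1] != "P"
        ]
    raise ValueError(f"unknown enzyme rule: {enzyme!r}")


def digest(
    protein: ProteinRecord,
    enzyme: str = "strict-trypsin",
    missed: int = 2,
    min_len: int = 7,
    max_len: int = 50,
    clip_met: bool = True,
    fixed_mods: Sequence[VariableMod] = (),
) -> list[PeptideEntry]:
    """Fully enzymatic digest with missed cleavages and optional N-term Met clip.

    ``fixed_mods`` are applied into the entry mass (sites never count toward
    variable-mod caps).
    """
    if missed < 0:
        raise ValueError("missed must be >= 0")
    seq = protein.sequence
    cuts = [0] + _cleavage_sites(seq, enzyme) + [len(seq)]
    entries: dict[tuple[str, bool], PeptideEntry] = {}

    def emit(pep: str, n_missed: int, clipped: bool) -> None:
        if not min_len <= len(pep) <= max_len:
            return
        key = (pep, clipped)
        if key in entries:
            entries[key].missed_cleavages = min(entries[key].missed_cleavages, n_missed)
            return
        mass = peptide_mass(pep)
        for fm in fixed_mods:
            mass += fm.delta * sum(pep.count(r) for r in fm.residues if r not in "[]")
            if "[" in fm.residues:
                mass += fm.delta
            if "]" in fm.residues:
                mass += fm.delta
        entries[key] = PeptideEntry(
            pep, frozenset({protein.accession}), n_missed, clipped, mass,
            is_decoy=protein.is_decoy,
        )

    for a in range(len(cuts) - 1):
        for b in range(a + 1, min(a + missed + 2, len(cuts))):
            pep = seq[cuts[a]: cuts[b]]
            n_missed = b - a - 1
            emit(pep, n_missed, False)
            if clip_met and cuts[a] == 0 and seq.startswith("M"):
                emit(pep[1:], n_missed, True)
    return list(entries.values())


def digest_database(
    proteins: Sequence[ProteinRecord], **kwargs
) -> list[PeptideEntry]:
    """Digest many proteins, merging shared peptides into one entry."""
    merged: dict[tuple[str, bool], PeptideEntry] = {}
    for protein in proteins:
        for entry in digest(protein, **kwargs):
            key = (entry.sequence, entry.is_decoy)
            if key in merged:
                prev = merged[key]
                prev.accessions = prev.accessions | entry.accessions
                prev.missed_cleavages = min(prev.missed_cleavages, entry.missed_cleavages)
            else:
                merged[key] = entry
    return list(merged.values())


def _placements(sequence: str, mod: VariableMod) -> list[int]:
    sites = [i + 1 for i, aa in enumerate(sequence) if aa in mod.residues]
    if "[" in mod.residues:
        sites.insert(0, 0)
    if "]" in mod.residues:
        sites.append(len(sequence))
    return sites


def enumerate_modforms(
    entry: PeptideEntry,
    var_mods: Sequence[VariableMod] = (),
    max_var: int = 3,
    labile_specs: Sequence = (),
    mode: str = "nonlabile",
    max_forms: int = 5000,
    total_mod_cap: int | None = None,
) -> list[ModForm]:
    """All candidate forms of a peptide for the given search mode.

    nonlabile: site placements of <= ``max_var`` variable mods, offset 0.
    labile: the same placements crossed with site-free offsets k*mass per
    labile spec (k <= spec max, subject to the total-mod cap); offset 0 is
    always included. hybrid additionally treats each labile spec as a
    variable mod so intact and lost forms of the same modification compete.
    """
    if mode not in ("nonlabile", "labile", "hybrid"):
        raise ValueError(f"unknown mode {mode!r}")
    if total_mod_cap is None:
        # no cross constraint unless configured: placements bounded by
        # max_var, offsets by the per-spec maxima
        total_mod_cap = max_var + sum(s.max_per_peptide for s in labile_specs)
    cap = total_mod_cap

    effective_var = list(var_mods)
    if mode == "hybrid":
        for spec in labile_specs:
            effective_var.append(
                VariableMod(spec.label, spec.offset, spec.residues, spec.max_per_peptide)
            )

    # Enumerate variable-mod placements (multiset of (mod, site) picks).
    placement_sets: list[tuple[tuple[int, float, str], ...]] = [()]
    site_lists = [(m, _placements(entry.sequence, m)) for m in effective_var]
    pool: list[tuple[VariableMod, int]] = [
        (m, s) for m, sites in site_lists for s in sites
    ]
    for r in range(1, max_var + 1):
        for combo in itertools.combinations(pool, r):
            positions = [s for _, s in combo]
            if len(set(positions)) != len(positions):
                continue
            per_mod: dict[str, int] = {}
            ok = True
            for m, _ in combo:
                per_mod[m.label] = per_mod.get(m.label, 0) + 1
                if per_mod[m.label] > m.max_per_peptide:
                    ok = False
                    break
            if ok:
                placement_sets.append(
                    tuple(sorted((s, m.delta, m.label) for m, s in combo))
                )
    placement_sets = list(dict.fromkeys(placement_sets))

    # Offset variants: per-spec counts, summed across specs.
    offset_variants: list[tuple[float, str, int]] = [(0.0, "", 0)]
    if mode in ("labile", "hybrid") and labile_specs:
        count_ranges = [range(0, spec.max_per_peptide + 1) for spec in labile_specs]
        for counts in itertools.product(*count_ranges):
            total = sum(counts)
            if total == 0 or total > cap:
                continue
            offset = sum(k * spec.offset for k, spec in zip(counts, labile_specs))
            label = "+".join(
                f"{spec.label}x{k}" for k, spec in zip(counts, labile_specs) if k
            )
            offset_variants.append((offset, label, total))

    forms: list[ModForm] = []
    for placements in placement_sets:
        for offset, label, count in offset_variants:
            if len(placements) + count > cap and count > 0:
                continue
            forms.append(ModForm(entry, placements, offset, label, count))
            if len(forms) > max_forms:
                warnings.warn(
                    f"peptide {entry.sequence} exceeds {max_forms} mod forms; skipped"
                )
                return []
    return forms


class PeptideMassIndex:
    """Sorted-array index over peptide entries for mass-window queries."""

    def __init__(self, entries: Sequence[PeptideEntry]):
        self.entries = sorted(entries, key=lambda e: e.neutral_mass)
        self._masses = np.array([e.neutral_mass for e in self.entries])

    def __len__(self) -> int:
        return len(self.entries)

    def query(self, lo: float, hi: float) -> list[PeptideEntry]:
        """All entries with lo <= mass <= hi."""
        i = int(np.searchsorted(self._masses, lo, side="left"))
        j = int(np.searchsorted(self._masses, hi, side="right"))
        return self.entries[i:j]

    def query_window(self, center: float, tol_ppm: float) -> list[PeptideEntry]:
        half = abs(center) * tol_ppm * 1e-6
        return self.query(center - half, center + half)


def build_index(entries: Sequence[PeptideEntry]) -> PeptideMassIndex:
    return PeptideMassIndex(entries)
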