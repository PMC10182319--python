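"""Synthetic labile-modification spectra with ground truth.

The simulator models the fragmentation phenomenology of a labile PTM: each
backbone fragment covering a modified site either retains the modification
or loses it (probability ``p_loss``), lost fragments may additionally leave
a remainder-mass peak, the intact peptide may emit peptide-remainder ions,
and the modification may emit low-mass diagnostic ions. Noise peaks and
ppm jitter are optional, so noise-free spectra are exactly explainable by
the theoretical ion set of the true form.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .chemmass import PROTON_MASS, mz_from_mass
from .fragments import theoretical_ions
from .protein_db import ModForm, PeptideEntry, ProteinRecord, digest_database
from .search_engine import LabileModSpec
from .spectra_io import Spectrum, write_mgf


@dataclass
class SimParams:
    p_loss: float = 1.0  # per covered fragment: modification absent
    fragment_remainder_prob: float = 0.0
    fragment_remainders: tuple[float, ...] = ()
    peptide_remainder_prob: float = 0.0
    peptide_remainders: tuple[float, ...] = ()
    diagnostic_prob: float = 0.0
    diagnostic_mzs: tuple[float, ...] = ()
    diagnostic_intensity: tuple[float, float] = (20.0, 100.0)
    detect_prob: float = 0.9  # per backbone fragment
    intensity_range: tuple[float, float] = (10.0, 100.0)  # log-uniform
    noise_peaks: int = 0
    noise_mz_range: tuple[float, float] = (100.0, 1500.0)
    noise_intensity_range: tuple[float, float] = (1.0, 20.0)
    jitter_ppm: float = 0.0
    charges: tuple[int, ...] = (2,)
    series: str = "by"

    def __post_init__(self) -> None:
        for name in ("p_loss", "fragment_remainder_prob", "peptide_remainder_prob",
                     "diagnostic_prob", "detect_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class GroundTruthRecord:
    scan_id: str
    peptide: str
    mod_label: str
    mod_count: int
    sites: tuple[int, ...]
    offset: float


def _rng_for(seed: int, scan_index: int) -> np.random.Generator:
    # one independent stream per spectrum for reproducible parallel generation
    return np.random.default_rng(np.random.SeedSequence((seed, scan_index)))


def sample_peptides(
    proteins: Sequence[ProteinRecord],
    spec: LabileModSpec,
    n: int,
    seed: int,
    mod_count: int = 1,
    digest_kwargs: dict | None = None,
) -> list[ModForm]:
    """Draw n modified peptides from a tryptic digest of the proteins.

    Each draw places ``mod_count`` copies of the labile modification on
    distinct allowed residues chosen uniformly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    entries = digest_database(list(proteins), **(digest_kwargs or {}))
    eligible = [
        e for e in entries if len(spec.allowed_sites(e.sequence)) >= mod_count
    ]
    if not eligible:
        raise ValueError(
            f"no digested peptide has >= {mod_count} site(s) for {spec.residues!r}"
        )
    forms = []
    for _ in range(n):
        entry = eligible[int(rng.integers(len(eligible)))]
        sites = spec.allowed_sites(entry.sequence)
        chosen = sorted(rng.choice(len(sites), size=mod_count, replace=False))
        placements = tuple((sites[i], spec.offset, spec.label) for i in chosen)
        # stored as placed mods so theoretical_ions gives the intact-mod pattern
        forms.append(ModForm(entry, placements, 0.0, spec.label, 0))
    return forms


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def simulate_spectrum(
    form: ModForm,
    params: SimParams,
    seed: int,
    scan_index: int = 0,
    scan_id: str | None = None,
) -> tuple[Spectrum, GroundTruthRecord]:
    """Emit one spectrum for a ModForm whose placed mods are the true sites."""
    rng = _rng_for(seed, scan_index)
    scan_id = scan_id or f"sim.{scan_index}"
    sites = tuple(pos for pos, _, _ in form.var_mods)
    mod_delta = form.var_mods[0][1] if form.var_mods else 0.0
    label = form.var_mods[0][2] if form.var_mods else ""

    z = int(params.charges[int(rng.integers(len(params.charges)))])
    precursor_mz = mz_from_mass(form.neutral_mass, z)

    intact = theoretical_ions(form, params.series, 1)
    lost_form = ModForm(form.entry, (), 0.0, "", 0)
    lost = theoretical_ions(lost_form, params.series, 1)
    lost_by_key = {(i.series, i.ordinal): i for i in lost}

    mz_list: list[float] = []
    int_list: list[float] = []
    n = len(form.sequence)
    for ion in intact:
        if rng.random() > params.detect_prob:
            continue
        inten = _loguniform(rng, *params.intensity_range)
        covered = [s for s in sites if ion.covers(s, n)]
        n_lost = sum(1 for _ in covered if rng.random() < params.p_loss)
        if n_lost:
            base = lost_by_key[(ion.series, ion.ordinal)]
            # retained covered sites keep their mod mass on the fragment
            extra = mod_delta * (len(covered) - n_lost)
            mz_list.append(base.mz + extra)
            int_list.append(inten)
            if (params.fragment_remainders
                    and rng.random() < params.fragment_remainder_prob):
                r = float(params.fragment_remainders[
                    int(rng.integers(len(params.fragment_remainders)))])
                mz_list.append(base.mz + extra + r)
                int_list.append(_loguniform(rng, *params.intensity_range))
        else:
            mz_list.append(ion.mz)
            int_list.append(inten)

    if params.peptide_remainders and rng.random() < params.peptide_remainder_prob:
        unmod_mass = form.entry.neutral_mass
        for r in params.peptide_remainders:
            for zz in range(1, z + 1):
                mz_list.append(mz_from_mass(unmod_mass + r, zz))
                int_list.append(_loguniform(rng, *params.intensity_range))

    for dmz in params.diagnostic_mzs:
        if rng.random() < params.diagnostic_prob:
            mz_list.append(float(dmz))
            int_list.append(float(rng.uniform(*params.diagnostic_intensity)))

    for _ in range(params.noise_peaks):
        mz_list.append(float(rng.uniform(*params.noise_mz_range)))
        int_list.append(float(rng.uniform(*params.noise_intensity_range)))

    mz_arr = np.array(mz_list)
    int_arr = np.array(int_list)
    if params.jitter_ppm > 0 and mz_arr.size:
        mz_arr = mz_arr * (1.0 + rng.normal(0.0, params.jitter_ppm * 1e-6, mz_arr.size))

    # sort and merge duplicates (within 1e-6) by intensity summation
    if mz_arr.size:
        order = np.argsort(mz_arr, kind="stable")
        mz_arr, int_arr = mz_arr[order], int_arr[order]
        keep_mz: list[float] = []
        keep_int: list[float] = []
        for m, i in zip(mz_arr, int_arr):
            if keep_mz and abs(m - keep_mz[-1]) < 1e-6:
                keep_int[-1] += i
            else:
                keep_mz.append(float(m))
                keep_int.append(float(i))
        mz_arr, int_arr = np.array(keep_mz), np.array(keep_int)

    spectrum = Spectrum(scan_id, precursor_mz, z, mz_arr, int_arr)
    truth = GroundTruthRecord(scan_id, form.sequence, label, len(sites), sites, mod_delta * len(sites))
    return spectrum, truth


TRUTH_COLUMNS = ["scan", "peptide", "site", "offset", "mod_label", "mod_count", "subset"]


def simulate_dataset(
    forms: Sequence[ModForm],
    params: SimParams,
    seed: int,
    mgf_path: str | Path | None = None,
    truth_path: str | Path | None = None,
    subset: str = "",
    scan_offset: int = 0,
) -> tuple[list[Spectrum], list[GroundTruthRecord]]:
    """Simulate one spectrum per form; optionally write MGF + truth TSV."""
    spectra, truths = [], []
    for i, form in enumerate(forms):
        idx = scan_offset + i
        s, t = simulate_spectrum(form, params, seed, idx, scan_id=f"sim.{idx}")
        spectra.append(s)
        truths.append(t)
    if mgf_path is not None:
        write_mgf(spectra, mgf_path)
    if truth_path is not None:
        write_truth(truths, truth_path, subset=subset)
    return spectra, truths


def write_truth(records: Sequence[GroundTruthRecord], path: str | Path,
                subset: str = "", append: bool = False) -> None:
    mode = "a" if append else "w"
    write_header = not (append and Path(path).exists() and Path(path).stat().st_size)
    with open(path, mode, newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t")
        if write_header:
            writer.writerow(TRUTH_COLUMNS)
        for r in records:
            writer.writerow([
                r.scan_id, r.peptide, ";".join(map(str, r.sites)),
                f"{r.offset:.5f}", r.mod_label, r.mod_count, subset,
            ])


def read_truth(path: str | Path) -> list[GroundTruthRecord]:
    out = []
    with open(path, encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            sites = tuple(int(x) for x in row["site"].split(";") if x)
            out.append(GroundTruthRecord(
                row["scan"], row["peptide"], row["mod_label"],
                int(row["mod_count"]), sites, float(row["offset"]),
            ))
    return out


def random_proteins(
    n: int, length: int, seed: int, alphabet: str = "ACDEFGHIKLMNPQRSTVWY"
) -> list[ProteinRecord]:
    """Random protein sequences with tryptic sites, for self-contained tests."""
    rng = np.random.default_rng(seed)
    letters = np.array(list(alphabet))
    proteins = []
    for i in range(n):
        seq = "".join(rng.choice(letters, size=length))
        proteins.append(ProteinRecord(f"sp|SIM{i:04d}|SIM{i:04d}", "synthetic", seq))
    return proteins
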