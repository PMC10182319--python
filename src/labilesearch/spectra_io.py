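"""Spectrum containers, MGF/mzML reading, MGF writing, and preprocessing.

Preprocessing mirrors the steps applied ahead of the search: removal of
neutral-loss peaks dominated by their parent peak, greedy deisotoping,
top-N peak selection and base-peak normalization.
"""

from __future__ import annotations

import base64
import struct
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence
from xml.etree import ElementTree

import numpy as np

from .chemmass import ISOTOPE_SPACING, PROTON_MASS, ppm_window

DEFAULT_NEUTRAL_LOSSES = (18.01056, 17.02655, 97.97690)  # H2O, NH3, H3PO4


@dataclass
class Spectrum:
    """A centroided MS2 scan."""

    scan_id: str
    precursor_mz: float
    precursor_charge: int
    mz: np.ndarray
    intensity: np.ndarray
    activation: str = ""
    rt_seconds: float | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]

    @property
    def precursor_neutral_mass(self) -> float:
        z = self.precursor_charge
        return z * self.precursor_mz - z * PROTON_MASS

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


@dataclass
class ProcessedSpectrum(Spectrum):
    """Spectrum after top-N filtering and base-peak normalization."""

    norm_ceiling: float = 100.0
    searchable: bool = True
    base_peak_intensity: float = 0.0


def _iter_mgf_blocks(path: Path) -> Iterator[list[str]]:
    block: list[str] = []
    inside = False
    with open(path, encoding="utf-8") as handle:
        for raw in handle:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                inside, block = True, []
            elif line == "END IONS":
                if inside:
                    yield block
                inside = False
            elif inside:
                block.append(line)


def _parse_mgf_block(block: list[str], index: int) -> tuple[dict, list[tuple[float, float]]]:
    meta: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    for line in block:
        if "=" in line and not line[0].isdigit():
            key, _, value = line.partition("=")
            meta[key.upper()] = value.strip()
        else:
            parts = line.split()
            if len(parts) < 2:
                raise IOError(f"unparseable peak line in MGF entry {index}: {line!r}")
            peaks.append((float(parts[0]), float(parts[1])))
    return meta, peaks


def read_mgf(path: str | Path, assumed_charges: Sequence[int] = (2, 3)) -> list[Spectrum]:
    """Read an MGF file. Entries without CHARGE are emitted once per assumed charge."""
    path = Path(path)
    spectra: list[Spectrum] = []
    for index, block in enumerate(_iter_mgf_blocks(path)):
        meta, peaks = _parse_mgf_block(block, index)
        title = meta.get("TITLE", f"index={index}")
        pepmass = float(meta.get("PEPMASS", "0").split()[0])
        rt = float(meta["RTINSECONDS"]) if "RTINSECONDS" in meta else None
        mz = np.array([p[0] for p in peaks])
        inten = np.array([p[1] for p in peaks])
        if "CHARGE" in meta:
            charge = int(meta["CHARGE"].rstrip("+").lstrip("-"))
            charges: Iterable[int] = (charge,)
        else:
            charges = assumed_charges
        for z in charges:
            spectra.append(
                Spectrum(title, pepmass, z, mz.copy(), inten.copy(), rt_seconds=rt)
            )
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra to MGF (TITLE/PEPMASS/CHARGE/RTINSECONDS keys)."""
    with open(path, "w", encoding="utf-8") as handle:
        for s in spectra:
            handle.write("BEGIN IONS\n")
            handle.write(f"TITLE={s.scan_id}\n")
            handle.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            handle.write(f"CHARGE={s.precursor_charge}+\n")
            if s.rt_seconds is not None:
                handle.write(f"RTINSECONDS={s.rt_seconds:.3f}\n")
            for mz, inten in zip(s.mz, s.intensity):
                handle.write(f"{mz:.6f} {inten:.4f}\n")
            handle.write("END IONS\n")


_MZML_NS = "{http://psi.hupo.org/ms/mzml}"


def _decode_binary(elem, n_expected: int) -> np.ndarray:
    """Decode one mzML <binaryDataArray>."""
    accessions = {cv.get("accession") for cv in elem.iter(f"{_MZML_NS}cvParam")}
    text = elem.findtext(f"{_MZML_NS}binary") or ""
    data = base64.b64decode(text)
    if "MS:1000574" in accessions:  # zlib compression
        data = zlib.decompress(data)
    fmt = "d" if "MS:1000523" in accessions else "f"
    values = struct.unpack(f"<{len(data) // struct.calcsize(fmt)}{fmt}", data)
    return np.asarray(values, dtype=np.float64)


def read_mzml(path: str | Path, assumed_charges: Sequence[int] = (2, 3)) -> list[Spectrum]:
    """Read MS2 spectra from an mzML file (MS1 scans are skipped).

    Supports 32/64-bit little-endian float arrays with optional zlib
    compression — the output of common converters with default settings.
    """
    path = Path(path)
    spectra: list[Spectrum] = []
    try:
        tree = ElementTree.parse(path)
    except ElementTree.ParseError as exc:
        raise IOError(f"cannot parse mzML file {path}: {exc}") from exc
    for spec_elem in tree.iter(f"{_MZML_NS}spectrum"):
        params = {
            cv.get("accession"): cv.get("value")
            for cv in spec_elem.findall(f"{_MZML_NS}cvParam")
        }
        if params.get("MS:1000511") != "2":  # ms level
            continue
        scan_id = spec_elem.get("id", f"index={spec_elem.get('index', '?')}")
        precursor_mz, charge = 0.0, None
        sel = spec_elem.find(
            f"{_MZML_NS}precursorList/{_MZML_NS}precursor/"
            f"{_MZML_NS}selectedIonList/{_MZML_NS}selectedIon"
        )
        if sel is not None:
            for cv in sel.findall(f"{_MZML_NS}cvParam"):
                if cv.get("accession") == "MS:1000744":
                    precursor_mz = float(cv.get("value"))
                elif cv.get("accession") == "MS:1000041":
                    charge = int(cv.get("value"))
        mz_arr = np.array([])
        int_arr = np.array([])
        n_pts = int(spec_elem.get("defaultArrayLength", 0))
        for bda in spec_elem.iter(f"{_MZML_NS}binaryDataArray"):
            accs = {cv.get("accession") for cv in bda.findall(f"{_MZML_NS}cvParam")}
            if "MS:1000514" in accs:
                mz_arr = _decode_binary(bda, n_pts)
            elif "MS:1000515" in accs:
                int_arr = _decode_binary(bda, n_pts)
        charges: Iterable[int] = (charge,) if charge else assumed_charges
        for z in charges:
            spectra.append(Spectrum(scan_id, precursor_mz, z, mz_arr.copy(), int_arr.copy()))
    return spectra


def read_spectra(path: str | Path, format: str | None = None,
                 assumed_charges: Sequence[int] = (2, 3)) -> list[Spectrum]:
    """Read spectra, dispatching on ``format`` or the file extension."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "mgf":
        return read_mgf(path, assumed_charges)
    if fmt == "mzml":
        return read_mzml(path, assumed_charges)
    raise ValueError(f"unsupported spectra format: {fmt!r}")


def remove_neutral_losses(
    s: Spectrum,
    losses: Sequence[float] = DEFAULT_NEUTRAL_LOSSES,
    tol_ppm: float = 20.0,
) -> Spectrum:
    """Drop peaks that are neutral-loss satellites of a more intense peak.

    A peak ``p`` is removed iff some peak ``q`` satisfies
    ``|q.mz - loss - p.mz| <= tol`` and ``p.intensity < q.intensity`` for a
    configured loss. Tolerance is ppm of the heavier peak. Idempotent.
    """
    if s.n_peaks == 0:
        return s
    keep = np.ones(s.n_peaks, dtype=bool)
    for loss in losses:
        expected = s.mz - loss  # position of a loss peak for each parent q
        for qi in range(s.n_peaks):
            if expected[qi] <= 0:
                continue
            tol = ppm_window(s.mz[qi], tol_ppm)
            lo = np.searchsorted(s.mz, expected[qi] - tol, side="left")
            hi = np.searchsorted(s.mz, expected[qi] + tol, side="right")
            for pi in range(lo, hi):
                if pi != qi and s.intensity[pi] < s.intensity[qi]:
                    keep[pi] = False
    return replace(s, mz=s.mz[keep], intensity=s.intensity[keep])


def deisotope(
    s: Spectrum,
    max_charge: int = 2,
    tol_ppm: float = 20.0,
    max_ratio: float = 1.0,
    depth: int = 2,
) -> Spectrum:
    """Greedy envelope collapse: remove +1.00336/z successors of stronger peaks.

    Scans peaks in descending intensity; for each, walks up to ``depth``
    isotope steps at each charge 1..max_charge and removes successors whose
    intensity ratio to the monoisotopic peak is below ``max_ratio``.
    """
    if max_charge < 1:
        raise ValueError("max_charge must be >= 1")
    if s.n_peaks == 0:
        return s
    keep = np.ones(s.n_peaks, dtype=bool)
    order = np.argsort(-s.intensity, kind="stable")
    for i in order:
        if not keep[i]:
            continue
        for z in range(1, max_charge + 1):
            ref_intensity = s.intensity[i]
            base_mz = s.mz[i]
            for step in range(1, depth + 1):
                target = base_mz + step * ISOTOPE_SPACING / z
                tol = ppm_window(target, tol_ppm)
                lo = np.searchsorted(s.mz, target - tol, side="left")
                hi = np.searchsorted(s.mz, target + tol, side="right")
                hit = None
                for j in range(lo, hi):
                    if keep[j] and j != i and s.intensity[j] < ref_intensity * max_ratio:
                        if hit is None or s.intensity[j] > s.intensity[hit]:
                            hit = j
                if hit is None:
                    break
                keep[hit] = False
    return replace(s, mz=s.mz[keep], intensity=s.intensity[keep])


def preprocess(
    s: Spectrum,
    n_max: int = 150,
    min_peaks: int = 5,
    norm_ceiling: float = 100.0,
) -> ProcessedSpectrum:
    """Keep the ``n_max`` most intense peaks and normalize the base peak."""
    if not n_max >= min_peaks >= 1:
        raise ValueError("require n_max >= min_peaks >= 1")
    mz, intensity = s.mz, s.intensity
    if mz.size > n_max:
        top = np.argsort(-intensity, kind="stable")[:n_max]
        top.sort()
        mz, intensity = mz[top], intensity[top]
    searchable = mz.size >= min_peaks
    base = float(intensity.max()) if intensity.size else 0.0
    if base > 0:
        intensity = intensity * (norm_ceiling / base)
    return ProcessedSpectrum(
        scan_id=s.scan_id,
        precursor_mz=s.precursor_mz,
        precursor_charge=s.precursor_charge,
        mz=mz,
        intensity=intensity,
        activation=s.activation,
        rt_seconds=s.rt_seconds,
        norm_ceiling=norm_ceiling,
        searchable=searchable,
        base_peak_intensity=base,
    )
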