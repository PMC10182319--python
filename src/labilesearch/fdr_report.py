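"""Target-decoy q-values, FDR filtering and the TSV PSM report."""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .search_engine import PSM, UNLOCALIZED

PSM_COLUMNS = [
    "scan", "peptide", "mods", "labile_offset", "offset_label", "charge",
    "precursor_delta_ppm", "hyperscore", "delta_score", "matched_b",
    "matched_y", "remainder_evidence", "localization_site",
    "localization_scores", "is_decoy", "q_value",
]


def qvalues(psms: Sequence[PSM], plus_one: bool = False) -> list[PSM]:
    """Assign concatenated target-decoy q-values in place.

    FDR(t) = (#decoys >= t [+1]) / max(1, #targets >= t); q is the running
    minimum of FDR over thresholds at or below each PSM's score, so q is
    non-increasing in score.
    """
    psms = list(psms)
    if not psms:
        return psms
    if not any(p.is_decoy for p in psms):
        warnings.warn("no decoy PSMs present; all q-values set to 0")
        for p in psms:
            p.q_value = 0.0
        return psms
    order = sorted(psms, key=lambda p: -p.hyperscore)
    n_targets = n_decoys = 0
    fdrs = []
    for p in order:
        if p.is_decoy:
            n_decoys += 1
        else:
            n_targets += 1
        fdrs.append((n_decoys + (1 if plus_one else 0)) / max(1, n_targets))
    # monotonize from the bottom: q = min FDR at this score or worse
    running = np.minimum.accumulate(np.array(fdrs)[::-1])[::-1]
    for p, q in zip(order, running):
        p.q_value = float(min(q, 1.0))
    return psms


def peptide_group_key(psm: PSM) -> tuple:
    return (psm.form.sequence, psm.form.var_mods,
            round(psm.form.labile_offset, 4), psm.is_decoy)


def filter_fdr(psms: Sequence[PSM], level: str = "psm", threshold: float = 0.01) -> list[PSM]:
    """Targets passing the q-value threshold; decoys are dropped.

    Peptide level keeps, per peptide group, the best PSM and admits the
    group if that PSM passes.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if level not in ("psm", "peptide"):
        raise ValueError(f"unknown FDR level {level!r}")
    targets = [p for p in psms if not p.is_decoy]
    if level == "psm":
        return [p for p in targets if p.q_value <= threshold]
    best: dict[tuple, PSM] = {}
    for p in targets:
        key = peptide_group_key(p)
        if key not in best or p.hyperscore > best[key].hyperscore:
            best[key] = p
    return [p for p in best.values() if p.q_value <= threshold]


def _mods_string(psm: PSM) -> str:
    return ";".join(f"{pos}:{label}{delta:+.5f}" for pos, delta, label in psm.form.var_mods)


def psm_table(psms: Sequence[PSM]) -> pd.DataFrame:
    rows = []
    for p in psms:
        loc = p.localization
        if loc is None:
            site, scores = "", ""
        elif loc.site == UNLOCALIZED:
            site = "unlocalized"
            scores = ";".join(f"{k}:{v:.4f}" for k, v in sorted(loc.site_scores.items()))
        else:
            site = str(loc.site)
            scores = ";".join(f"{k}:{v:.4f}" for k, v in sorted(loc.site_scores.items()))
        denom = p.form.neutral_mass if p.form.neutral_mass > 0 else 1.0
        rows.append({
            "scan": p.scan_id,
            "peptide": p.form.sequence,
            "mods": _mods_string(p),
            "labile_offset": round(p.form.labile_offset, 5),
            "offset_label": p.form.labile_label,
            "charge": p.charge,
            "precursor_delta_ppm": round(1e6 * p.precursor_delta / denom, 3),
            "hyperscore": round(p.hyperscore, 5),
            "delta_score": round(p.delta_score, 5),
            "matched_b": p.detail.n_prefix,
            "matched_y": p.detail.n_suffix,
            "remainder_evidence": round(
                p.detail.peptide_remainder_intensity + p.detail.n_remainder_ions, 4
            ),
            "localization_site": site,
            "localization_scores": scores,
            "is_decoy": p.is_decoy,
            "q_value": p.q_value,
        })
    return pd.DataFrame(rows, columns=PSM_COLUMNS)


def write_psm_table(psms: Sequence[PSM], path: str | Path) -> None:
    """TSV report with the fixed column order; UTF-8, '.' decimals."""
    df = psm_table(psms)
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")
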