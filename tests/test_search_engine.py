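import math

import numpy as np
import pytest

from labilesearch import protein_db, simulate
from labilesearch.chemmass import PROTON_MASS, peptide_mass
from labilesearch.fragments import theoretical_ions
from labilesearch.protein_db import ModForm, PeptideEntry, VariableMod, build_index
from labilesearch.search_engine import (
    LabileModSpec,
    SearchParams,
    candidates_for,
    diagnostic_gate,
    hyperscore,
    localize,
    score_labile,
    search_spectrum,
)
from labilesearch.spectra_io import preprocess

from conftest import processed
from oracles import oracle_hyperscore


def entry_of(seq):
    return PeptideEntry(seq, frozenset({"t"}), 0, False, peptide_mass(seq))


def spectrum_for(form, p_loss, seed=0, **sim_kw):
    params = simulate.SimParams(p_loss=p_loss, detect_prob=1.0, **sim_kw)
    s, _ = simulate.simulate_spectrum(form, params, seed)
    return preprocess(s, min_peaks=1)


class TestDiagnosticGate:
    def test_threshold_zero_always_true(self):
        spec = LabileModSpec("m", 100.0, "*", diagnostic_mzs=(136.06232,),
                             diagnostic_min_intensity=0.0)
        s = processed([(500.0, 1.0)])
        assert diagnostic_gate(s, spec, 10.0) is True

    def test_intensity_sum(self):
        spec = LabileModSpec("m", 100.0, "*",
                             diagnostic_mzs=(136.06232, 250.09401),
                             diagnostic_min_intensity=50.0)
        peaks = [(136.0623, 30.0), (250.0940, 40.0), (700.0, 100.0)]
        s = processed(peaks, **{})
        # preprocessing rescales; disable normalization effects by rebuilding
        s.intensity = np.array([30.0, 40.0, 100.0])
        assert diagnostic_gate(s, spec, 10.0) is True

    def test_threshold_above_sum(self):
        spec = LabileModSpec("m", 100.0, "*",
                             diagnostic_mzs=(136.06232, 250.09401),
                             diagnostic_min_intensity=80.0)
        s = processed([(136.0623, 30.0), (250.0940, 40.0), (700.0, 100.0)])
        s.intensity = np.array([30.0, 40.0, 100.0])
        assert diagnostic_gate(s, spec, 10.0) is False

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        spec_mzs = (136.06232, 250.09401)
        spectra = []
        for i in range(100):
            n = rng.integers(5, 30)
            mz = np.sort(rng.uniform(100, 1000, n))
            if rng.random() < 0.5:
                mz = np.append(mz, 136.06232)
            s = processed([(m, float(rng.uniform(1, 100))) for m in np.sort(mz)])
            spectra.append(s)
        passed_prev = None
        for threshold in (0.0, 10.0, 30.0, 60.0, 100.0):
            spec = LabileModSpec("m", 100.0, "*", diagnostic_mzs=spec_mzs,
                                 diagnostic_min_intensity=threshold)
            passed = {i for i, s in enumerate(spectra)
                      if diagnostic_gate(s, spec, 10.0)}
            if passed_prev is not None:
                assert passed <= passed_prev
            passed_prev = passed


class TestCandidatesFor:
    def make_index(self):
        e = entry_of("PEPTIDEK")
        return e, build_index([e])

    def test_offset_candidate(self):
        e, idx = self.make_index()
        spec = LabileModSpec("ADPR", 541.06111, "*")
        target = e.neutral_mass + 541.06111
        s = processed([(100.0, 1.0)], precursor_mz=(target + 2 * PROTON_MASS) / 2)
        cands = candidates_for(s, idx, [spec], "labile", 20.0, [True])
        assert any(abs(o - 541.06111) < 1e-6 for _, o, _, _, _ in cands)

    def test_zero_offset_candidate(self):
        e, idx = self.make_index()
        s = processed([(100.0, 1.0)],
                      precursor_mz=(e.neutral_mass + 2 * PROTON_MASS) / 2)
        cands = candidates_for(s, idx, [], "nonlabile", 20.0, [])
        assert [c[1] for c in cands] == [0.0]

    def test_gate_false_collapses_offsets(self):
        e, idx = self.make_index()
        spec = LabileModSpec("ADPR", 541.06111, "*")
        target = e.neutral_mass + 541.06111
        s = processed([(100.0, 1.0)], precursor_mz=(target + 2 * PROTON_MASS) / 2)
        cands = candidates_for(s, idx, [spec], "labile", 20.0, [False])
        assert cands == []


class TestHyperscore:
    def test_no_match_is_zero(self):
        f = ModForm(entry_of("PEPTIDEK"))
        ions = theoretical_ions(f, "by", 1)
        s = processed([(10.0, 5.0)])
        score, detail = hyperscore(s, ions, 10.0)
        assert score == 0.0
        assert detail.n_matched == 0

    def test_formula_example(self):
        # Nb=2 (100, 50), Ny=1 (200) -> log10(2! * 1! * 150 * 200)
        f = ModForm(entry_of("ASAK"))
        ions = theoretical_ions(f, "by", 1)
        b1, b2 = ions[0], ions[1]
        y1 = next(i for i in ions if i.series == "y" and i.ordinal == 1)
        s = processed([(b1.mz, 100.0), (b2.mz, 50.0), (y1.mz, 200.0)])
        order = np.argsort([b1.mz, b2.mz, y1.mz])
        s.mz = np.array([b1.mz, b2.mz, y1.mz])[order]
        s.intensity = np.array([100.0, 50.0, 200.0])[order]
        score, detail = hyperscore(s, ions, 10.0)
        assert detail.n_prefix == 2 and detail.n_suffix == 1
        assert score == pytest.approx(math.log10(2 * 150 * 200), abs=1e-9)

    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        seqs = ["SAMPLEK", "PEPTIDER", "GASPVTK", "LLNDQKEK", "EMHFRYWK"]
        for trial in range(200):
            seq = seqs[trial % len(seqs)]
            f = ModForm(entry_of(seq))
            ions = theoretical_ions(f, "by", 1 + trial % 2)
            n = int(rng.integers(3, 40))
            mz = np.sort(rng.uniform(100, 1200, n))
            # plant a few true ions so matches occur
            planted = [i.mz for i in ions if rng.random() < 0.4]
            mz = np.sort(np.concatenate([mz, planted]))
            inten = rng.uniform(1, 100, mz.size)
            s = processed(list(zip(mz, inten)))
            s.mz, s.intensity = mz, inten
            got, _ = hyperscore(s, ions, 10.0)
            want = oracle_hyperscore(
                list(mz), list(inten),
                [(i.series, i.ordinal, i.charge, i.mz) for i in ions], 10.0,
            )
            assert got == pytest.approx(want, abs=1e-9), f"trial {trial} {seq}"


def phospho_form(seq, site):
    entry = entry_of(seq)
    return ModForm(entry, ((site, 79.96633, "phospho"),), 0.0, "phospho", 0)


def labile_candidate(seq):
    return ModForm(entry_of(seq), (), 79.96633, "phosphox1", 1)


class TestScoreLabile:
    def setup_method(self):
        self.spec = LabileModSpec("phospho", 79.96633, "STY", max_per_peptide=1,
                                  fragment_remainders=(-18.01056,))
        self.params = SearchParams(mode="labile", labile_specs=(self.spec,))

    def test_remainder_variant_wins_when_planted(self):
        true = phospho_form("SAMSPLEK", 4)
        s = spectrum_for(true, p_loss=1.0, fragment_remainder_prob=1.0,
                         fragment_remainders=(-18.01056,), seed=3)
        psm = score_labile(s, labile_candidate("SAMSPLEK"), self.spec, self.params)
        assert psm.pathway.startswith("remainder")

    def test_complete_loss_tiebreak(self):
        true = phospho_form("SAMSPLEK", 4)
        s = spectrum_for(true, p_loss=1.0, seed=3)  # no remainder peaks emitted
        psm = score_labile(s, labile_candidate("SAMSPLEK"), self.spec, self.params)
        assert psm.pathway == "complete-loss"

    def test_no_remainders_configured(self):
        spec = LabileModSpec("phospho", 79.96633, "STY", max_per_peptide=1)
        params = SearchParams(mode="labile", labile_specs=(spec,))
        true = phospho_form("SAMSPLEK", 4)
        s = spectrum_for(true, p_loss=1.0, seed=3)
        a = score_labile(s, labile_candidate("SAMSPLEK"), spec, params)
        b = score_labile(s, labile_candidate("SAMSPLEK"), self.spec, self.params)
        assert a.hyperscore == pytest.approx(b.hyperscore)
        assert a.pathway == "complete-loss"


class TestSearchSpectrum:
    def _search(self, s, index, mode, spec):
        if mode == "nonlabile":
            params = SearchParams(
                mode=mode,
                variable_mods=(VariableMod("phospho", 79.96633, "STY", 1),),
                min_matched_fragments=3,
            )
        else:
            params = SearchParams(mode=mode, labile_specs=(spec,),
                                  min_matched_fragments=3)
        return search_spectrum(s, index, params), params

    def setup_method(self):
        self.spec = LabileModSpec("phospho", 79.96633, "STY", max_per_peptide=1,
                                  fragment_remainders=(-18.01056,))
        self.proteins = simulate.random_proteins(10, 100, seed=2)
        db = self.proteins + protein_db.make_decoys(self.proteins)
        self.index = build_index(protein_db.digest_database(db))
        self.forms = simulate.sample_peptides(self.proteins, self.spec, 12, seed=2)

    def test_hybrid_picks_variable_mod_at_lability_zero(self):
        wins = 0
        for i, f in enumerate(self.forms):
            s = spectrum_for(f, p_loss=0.0, seed=i)
            psm, _ = self._search(s, self.index, "hybrid", self.spec)
            if psm and psm.form.labile_count == 0 and psm.form.var_mods:
                wins += 1
        assert wins >= 10

    def test_hybrid_picks_offset_at_lability_one(self):
        wins = 0
        for i, f in enumerate(self.forms):
            s = spectrum_for(f, p_loss=1.0, seed=i)
            psm, _ = self._search(s, self.index, "hybrid", self.spec)
            if psm and psm.form.labile_count == 1:
                wins += 1
        assert wins >= 10

    def test_hybrid_score_dominates_modes(self):
        for i, f in enumerate(self.forms[:8]):
            for p_loss in (0.0, 0.5, 1.0):
                s = spectrum_for(f, p_loss=p_loss, seed=100 + i)
                best = {}
                for mode in ("nonlabile", "labile", "hybrid"):
                    psm, _ = self._search(s, self.index, mode, self.spec)
                    best[mode] = psm.hyperscore if psm else 0.0
                assert best["hybrid"] >= max(best["nonlabile"], best["labile"]) - 1e-9

    def test_runner_up_from_different_sequence(self):
        f = self.forms[0]
        s = spectrum_for(f, p_loss=1.0, seed=9)
        psm, _ = self._search(s, self.index, "labile", self.spec)
        assert psm is not None
        assert psm.next_best <= psm.hyperscore


class TestLocalize:
    def setup_method(self):
        self.spec = LabileModSpec("phospho", 79.96633, "STY", max_per_peptide=1,
                                  fragment_remainders=(-18.01056,))
        self.params = SearchParams(mode="labile", labile_specs=(self.spec,))

    def _psm_for(self, seq, site, **sim_kw):
        true = phospho_form(seq, site)
        s = spectrum_for(true, p_loss=1.0, seed=5, **sim_kw)
        psm = score_labile(s, labile_candidate(seq), self.spec, self.params)
        return psm, s

    def test_single_allowed_site_trivial(self):
        psm, s = self._psm_for("SAMPLEK", 1, fragment_remainder_prob=1.0,
                               fragment_remainders=(-18.01056,))
        loc = localize(psm, s, self.params)
        assert loc.site == 1

    def test_planted_site_recovered(self):
        psm, s = self._psm_for("SAMSK", 4, fragment_remainder_prob=1.0,
                               fragment_remainders=(-18.01056,))
        loc = localize(psm, s, self.params)
        assert loc.site == 4
        assert loc.site_scores[4] > loc.site_scores[1]

    def test_no_remainder_peaks_unlocalized(self):
        psm, s = self._psm_for("SAMSK", 4)  # no remainder emission
        loc = localize(psm, s, self.params)
        assert loc.site == -1

    def test_multi_labile_unlocalized(self):
        form = ModForm(entry_of("SSAMSK"), (), 2 * 79.96633, "phosphox2", 2)
        s = spectrum_for(phospho_form("SSAMSK", 1), p_loss=1.0, seed=5)
        psm = score_labile(s, form, self.spec, self.params)
        loc = localize(psm, s, self.params)
        assert loc.site == -1
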