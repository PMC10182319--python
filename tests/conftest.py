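import numpy as np
import pytest

from labilesearch import protein_db, simulate
from labilesearch.search_engine import LabileModSpec, SearchParams
from labilesearch.spectra_io import Spectrum, preprocess


@pytest.fixture
def phospho_spec():
    return LabileModSpec(
        "phospho", 79.96633, "STY", max_per_peptide=3,
        fragment_remainders=(-18.01056,),
    )


@pytest.fixture
def phospho_spec_single():
    return LabileModSpec(
        "phospho", 79.96633, "STY", max_per_peptide=1,
        fragment_remainders=(-18.01056,),
    )


@pytest.fixture
def adpr_spec():
    return LabileModSpec(
        "ADPR", 541.06111, "SRK", max_per_peptide=1,
        diagnostic_mzs=(136.06232, 250.09401, 348.07036, 428.03669),
        diagnostic_min_intensity=20.0,
        peptide_remainders=(114.03169, 193.99802, 291.97492, 406.00661),
    )


@pytest.fixture(scope="session")
def small_proteins():
    return simulate.random_proteins(20, 120, seed=42)


@pytest.fixture(scope="session")
def small_index(small_proteins):
    db = list(small_proteins) + protein_db.make_decoys(small_proteins)
    return protein_db.build_index(protein_db.digest_database(db))


def make_spectrum(peaks, precursor_mz=500.0, charge=2, scan="s1"):
    mz = np.array([p[0] for p in peaks], dtype=float)
    inten = np.array([p[1] for p in peaks], dtype=float)
    return Spectrum(scan, precursor_mz, charge, mz, inten)


def processed(peaks, precursor_mz=500.0, charge=2, scan="s1", **kw):
    return preprocess(make_spectrum(peaks, precursor_mz, charge, scan), **kw)


@pytest.fixture
def two_protein_fasta(tmp_path):
    path = tmp_path / "two.fasta"
    path.write_text(
        ">sp|P00001|TEST1 first test protein\n"
        "MAKRSTKPEPTIDESAMSKR\n"
        ">sp|P00002|TEST2 second test protein\n"
        "GASPVTKLLNDQKEMHFRYWK\n"
    )
    return path
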