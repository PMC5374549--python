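import pytest

from entrapfdr import (
    PSMRecord,
    SequenceEntry,
    SimConfig,
    build_search_db,
)


@pytest.fixture
def toy_db():
    """Two sample and three entrapment proteins with a decoy complement."""
    sample = [
        SequenceEntry("sampleA", "MKTAYIAKQRQISFVKSHFSR", "sample"),
        SequenceEntry("sampleB", "PEPTIDEKELVISLIVESKGGR", "sample"),
    ]
    trap = [
        SequenceEntry("B", "QWERTYKASDFGHKLZCVBNMR".replace("Z", "S"), "entrapment"),
        SequenceEntry("C", "LLLLLLLKMMMMMMMRNNNNNNNK", "entrapment"),
        SequenceEntry("D", "AAAAAAARCCCCCCCKDDDDDDDR", "entrapment"),
    ]
    return sample, trap


@pytest.fixture
def toy_index(toy_db):
    sample, trap = toy_db
    return build_search_db(sample, trap, with_decoys=True)


def make_psm(spectrum, label, score, engine="engine1", peptide="PEPTIDEK", q=None):
    """Minimal labeled PSM for ranking tests; accession matches the label."""
    acc = {"sample": "sampleA", "entrapment": "trap_B", "decoy": "rev_sampleA"}[label]
    return PSMRecord(
        spectrum_id=spectrum,
        engine_id=engine,
        peptide=peptide,
        accessions=(acc,),
        score=score,
        label=label,
        q_value=q,
    )


@pytest.fixture
def seven_row_fixture():
    """4 targets, then 1 decoy, then 2 targets in descending score order."""
    labels = ["sample"] * 4 + ["decoy"] + ["sample"] * 2
    return [make_psm(f"s{i}", lab, score=10.0 - i) for i, lab in enumerate(labels)]


@pytest.fixture
def small_sim_config():
    """Scaled-down study conditions for fast statistical checks."""
    return SimConfig(
        n_sample_proteins=40,
        n_trap_proteins=400,
        protein_length_mean=200.0,
        n_spectra=4000,
        seed=11,
    )
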