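"""Database assembly: digestion, entrapment expansion, decoys, overlap."""

from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from entrapfdr import (
    DatabaseError,
    DigestConfig,
    OverlapReport,
    SequenceEntry,
    build_entrapment_db,
    build_search_db,
    digest,
    overlap_report,
    read_fasta,
    reverse_decoys,
    write_fasta,
)


def brute_force_digest(residues: str, config: DigestConfig) -> set[str]:
    """Independent oracle: enumerate all substrings, keep valid peptides.

    A valid peptide starts at the N-terminus or right after a cleavage
    site, ends at a cleavage site or the C-terminus, contains at most
    ``max_missed`` internal cleavage sites, and meets the length floor.
    """
    n = len(residues)
    sites = {
        i
        for i in range(n)
        if residues[i] in config.cleavage_residues
        and not (config.proline_rule and i + 1 < n and residues[i + 1] == "P")
    }
    out = set()
    for start in range(n):
        if start != 0 and (start - 1) not in sites:
            continue
        for end in range(start, n):
            if end != n - 1 and end not in sites:
                continue
            internal = sum(1 for i in range(start, end) if i in sites)
            if internal > config.max_missed:
                continue
            if end - start + 1 >= config.min_length:
                out.add(residues[start : end + 1])
    return out


class TestDigest:
    def test_hand_enumerated_example(self):
        assert digest("ACDEFGHKLMNPQRSTVWY") == {
            "ACDEFGHK",
            "ACDEFGHKLMNPQR",
            "LMNPQRSTVWY",
        }

    def test_all_fragments_below_length_floor(self):
        assert digest("KK") == set()

    def test_empty_sequence_rejected(self):
        with pytest.raises(DatabaseError):
            digest("")

    @pytest.mark.parametrize("proline_rule", [False, True])
    @pytest.mark.parametrize("max_missed", [0, 1, 2])
    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30))
    def test_agrees_with_brute_force_enumeration(self, seq, max_missed, proline_rule):
        config = DigestConfig(max_missed=max_missed, min_length=3, proline_rule=proline_rule)
        assert digest(seq, config) == brute_force_digest(seq, config)

    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=7, max_size=60))
    def test_peptides_end_at_cleavage_or_terminus(self, seq):
        config = DigestConfig()
        for pep in digest(seq, config):
            assert pep in seq
            idx = seq.find(pep)
            while idx != -1:
                end = idx + len(pep) - 1
                if end == len(seq) - 1 or seq[end] in config.cleavage_residues:
                    internal = sum(1 for c in pep[:-1] if c in config.cleavage_residues)
                    assert internal <= config.max_missed
                    break
                idx = seq.find(pep, idx + 1)
            else:
                pytest.fail(f"{pep} has no valid end position in {seq}")


class TestEntrapmentExpansion:
    def _entries(self, n, length=40, seed=5):
        import numpy as np

        rng = np.random.default_rng(seed)
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        return [
            SequenceEntry(
                f"E{i}",
                "".join(alphabet[j] for j in rng.integers(0, 20, length)),
                "entrapment",
            )
            for i in range(n)
        ]

    def test_identity_for_single_copy(self):
        entries = self._entries(5)
        assert build_entrapment_db(entries, n_copies=1, seed=0) == entries

    def test_tenfold_count(self):
        entries = self._entries(12)
        out = build_entrapment_db(entries, n_copies=10, seed=0)
        assert len(out) == 120
        assert len({e.accession for e in out}) == 120

    def test_shuffle_preserves_residue_multiset(self):
        entries = self._entries(4)
        out = build_entrapment_db(entries, n_copies=3, seed=7)
        for copy_idx in range(3):
            for orig, new in zip(entries, out[copy_idx * 4 : (copy_idx + 1) * 4]):
                assert Counter(new.residues) == Counter(orig.residues)

    def test_deterministic_per_seed(self):
        entries = self._entries(3)
        a = build_entrapment_db(entries, n_copies=4, seed=42)
        b = build_entrapment_db(entries, n_copies=4, seed=42)
        c = build_entrapment_db(entries, n_copies=4, seed=43)
        assert a == b
        assert len(a) == 12
        assert a != c

    def test_rejects_bad_inputs(self):
        entries = self._entries(2)
        with pytest.raises(ValueError):
            build_entrapment_db(entries, n_copies=0, seed=0)
        sample = SequenceEntry("S", "PEPTIDEK", "sample")
        with pytest.raises(DatabaseError):
            build_entrapment_db([sample], n_copies=2, seed=0)


class TestDecoys:
    def test_reversal_and_involution(self, toy_db):
        sample, _ = toy_db
        decoys = reverse_decoys(sample)
        assert decoys[1].residues == sample[1].residues[::-1]
        assert all(d.is_decoy for d in decoys)
        assert all(d.accession.startswith("rev_") for d in decoys)
        again = [d.residues[::-1] for d in decoys]
        assert again == [s.residues for s in sample]

    def test_rejects_double_decoying(self, toy_db):
        sample, _ = toy_db
        with pytest.raises(DatabaseError):
            reverse_decoys(reverse_decoys(sample))


class TestSearchDb:
    def test_counts_with_decoys(self, toy_db):
        sample, trap = toy_db
        db = build_search_db(sample, trap, with_decoys=True)
        assert len(db.entries) == 2 * (len(sample) + len(trap))

    def test_no_entrapment_degenerates_to_target_decoy(self, toy_db):
        sample, _ = toy_db
        db = build_search_db(sample, [], with_decoys=True)
        assert len(db.entries) == 2 * len(sample)

    def test_index_roundtrip(self, toy_index):
        for entry in toy_index.entries:
            assert toy_index.lookup(entry.accession) == (entry.origin, entry.is_decoy)

    def test_duplicate_accessions_rejected(self):
        sample = [SequenceEntry("X", "PEPTIDEK", "sample")] * 2
        with pytest.raises(DatabaseError):
            build_search_db(sample, [], with_decoys=False)


class TestOverlapReport:
    def test_disjoint_alphabets(self):
        sample = [SequenceEntry("S", "AAAAAAAKGGGGGGGK", "sample")]
        trap = [SequenceEntry("T", "CCCCCCCKWWWWWWWK", "entrapment")]
        rep = overlap_report(sample, trap)
        assert rep.n_shared == 0 and rep.shared_pct == 0.0

    def test_identical_databases(self):
        sample = [SequenceEntry("S", "AAAAAAAKGGGGGGGK", "sample")]
        trap = [SequenceEntry("T", "AAAAAAAKGGGGGGGK", "entrapment")]
        rep = overlap_report(sample, trap)
        assert rep.n_shared == rep.n_sample_peptides
        assert rep.shared_pct == 100.0

    def test_denominator_is_sample_side(self):
        rep = OverlapReport(n_sample_peptides=1000, n_trap_peptides=50, n_shared=10)
        assert rep.shared_pct == 1.0
        flipped = OverlapReport(n_sample_peptides=50, n_trap_peptides=1000, n_shared=10)
        assert flipped.shared_pct == 20.0

    def test_empty_side_rejected(self, toy_db):
        sample, _ = toy_db
        with pytest.raises(DatabaseError):
            overlap_report(sample, [])


def test_fasta_roundtrip(tmp_path, toy_db):
    sample, _ = toy_db
    path = tmp_path / "sample.fasta"
    write_fasta(sample, path)
    back = read_fasta(path, "sample")
    assert [(e.accession, e.residues) for e in back] == [
        (e.accession, e.residues) for e in sample
    ]
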