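"""Alignment identity profiling and interface conservation mapping."""
from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xtalassoc.conservation import (
    column_identity,
    conserved_positions,
    interface_conservation,
    map_profile_to_chain,
    read_alignment,
)
from xtalassoc.model import StructureModel
from xtalassoc.synth import make_alignment

from conftest import make_atom


def _write_fasta(path, seqs):
    path.write_text("".join(f">s{i}\n{s}\n" for i, s in enumerate(seqs)))


class TestReadAlignment:
    def test_identical_ungapped(self, tmp_path):
        p = tmp_path / "a.fasta"
        _write_fasta(p, ["ACDEF"] * 3)
        aln = read_alignment(p)
        assert aln.get_alignment_length() == 5
        assert len(aln) == 3

    def test_ragged_is_error(self, tmp_path):
        p = tmp_path / "bad.fasta"
        _write_fasta(p, ["ACDEF", "ACD"])
        with pytest.raises(ValueError):
            read_alignment(p)

    def test_mixed_case_normalized(self, tmp_path):
        p = tmp_path / "mixed.fasta"
        _write_fasta(p, ["acDef", "ACdEF"])
        aln = read_alignment(p)
        assert str(aln[0].seq) == "ACDEF"

    def test_clustal_format(self, tmp_path):
        p = tmp_path / "a.aln"
        p.write_text(
            "CLUSTAL W multiple sequence alignment\n\n"
            "s1   ACDEF\ns2   ACDEF\n"
        )
        assert read_alignment(p).get_alignment_length() == 5


class TestColumnIdentity:
    def test_fully_identical_column(self, tmp_path):
        p = tmp_path / "a.fasta"
        _write_fasta(p, ["A"] * 10)
        prof = column_identity(read_alignment(p))
        assert prof.fractions == [1.0]

    def test_nine_of_ten(self, tmp_path):
        p = tmp_path / "a.fasta"
        _write_fasta(p, ["A"] * 9 + ["G"])
        prof = column_identity(read_alignment(p))
        assert prof.fractions == [0.9]

    def test_gaps_excluded_from_denominator(self, tmp_path):
        p = tmp_path / "a.fasta"
        _write_fasta(p, ["A", "A", "A", "-"])
        prof = column_identity(read_alignment(p))
        assert prof.fractions == [1.0]

    def test_all_gap_column_scores_zero(self, tmp_path):
        p = tmp_path / "a.fasta"
        _write_fasta(p, ["-A", "-A"])
        prof = column_identity(read_alignment(p))
        assert prof.fractions == [0.0, 1.0]
        assert prof.columns[0][3]  # low confidence flag

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1), st.integers(3, 12), st.integers(4, 20))
    def test_matches_counting_oracle(self, seed, width, n_seqs):
        from collections import Counter

        rng = np.random.default_rng(seed)
        alphabet = "ACDG-"
        seqs = ["".join(rng.choice(list(alphabet), width)) for _ in range(n_seqs)]
        from Bio.Align import MultipleSeqAlignment
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        aln = MultipleSeqAlignment(
            [SeqRecord(Seq(s), id=f"s{i}") for i, s in enumerate(seqs)]
        )
        prof = column_identity(aln)
        for j in range(width):
            col = [s[j] for s in seqs if s[j] != "-"]
            expect = Counter(col).most_common(1)[0][1] / len(col) if col else 0.0
            assert prof.fractions[j] == pytest.approx(expect)

    def test_invariant_under_sequence_reordering(self, tmp_path):
        seqs = ["ACDEF", "ACDFF", "AGDEF", "ACDEF"]
        p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        _write_fasta(p1, seqs)
        _write_fasta(p2, seqs[::-1])
        assert column_identity(read_alignment(p1)).fractions == \
            column_identity(read_alignment(p2)).fractions

    def test_duplicating_modal_sequence_never_lowers_identity(self, tmp_path):
        seqs = ["ACDEF", "ACDFF", "AGDEF"]
        p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        _write_fasta(p1, seqs)
        _write_fasta(p2, seqs + [seqs[0]])
        f1 = column_identity(read_alignment(p1)).fractions
        f2 = column_identity(read_alignment(p2)).fractions
        # seqs[0] carries the modal residue in every column here
        assert all(b >= a - 1e-12 for a, b in zip(f1, f2))


class TestConservedPositions:
    def test_strict_threshold_boundary(self, tmp_path):
        p = tmp_path / "a.fasta"
        _write_fasta(p, ["A"] * 9 + ["G"])  # exactly 0.90
        prof = column_identity(read_alignment(p))
        assert conserved_positions(prof, 0.90) == set()

    def test_full_identity_included(self, tmp_path):
        p = tmp_path / "a.fasta"
        _write_fasta(p, ["AG", "AG", "AC"])
        prof = column_identity(read_alignment(p))
        assert conserved_positions(prof, 0.90) == {0}

    def test_generator_truth_recovered(self):
        aln, truth = make_alignment(width=50, n_seqs=22,
                                    conserved_columns=[2, 9, 17, 33], seed=12)
        prof = column_identity(aln)
        assert conserved_positions(prof, 0.90) == truth

    def test_bad_threshold(self):
        aln, _ = make_alignment(width=5, n_seqs=4, seed=0)
        with pytest.raises(ValueError):
            conserved_positions(column_identity(aln), 0.0)


def _chain_model(seq3, chain="A"):
    atoms = []
    for i, rn in enumerate(seq3):
        atoms.append(make_atom(i + 1, "CA", "C", rn, i + 1, chain, [3.8 * i, 0, 0]))
    return StructureModel(atoms)


class TestStructureMapping:
    def test_exact_match_maps_all_columns(self, tmp_path):
        # master ACD with one gap column
        p = tmp_path / "a.fasta"
        _write_fasta(p, ["A-CD", "A-CD"])
        prof = column_identity(read_alignment(p))
        m = _chain_model(["ALA", "CYS", "ASP"])
        prof = map_profile_to_chain(prof, m, "A")
        assert prof.master_map == {0: ("A", 1, ""), 2: ("A", 2, ""), 3: ("A", 3, "")}

    def test_mismatch_shows_both_sequences(self, tmp_path):
        p = tmp_path / "a.fasta"
        _write_fasta(p, ["AAAA", "AAAA"])
        prof = column_identity(read_alignment(p))
        m = _chain_model(["GLY", "GLY", "GLY", "GLY"])
        with pytest.raises(ValueError, match="master"):
            map_profile_to_chain(prof, m, "A")

    def test_interface_ranking_by_design(self, tmp_path):
        """Contacts at conserved columns rank above contacts at variable ones."""
        # chain of 10 residues; columns 0-4 conserved, 5-9 variable
        n = 10
        master = "ADEFGHIKLM"
        variable = "ADEFGHWWWW"  # differs at positions 6-9
        p = tmp_path / "a.fasta"
        _write_fasta(p, [master] * 9 + [variable])
        prof = column_identity(read_alignment(p))
        resnames = ["ALA", "ASP", "GLU", "PHE", "GLY",
                    "HIS", "ILE", "LYS", "LEU", "MET"]
        m = _chain_model(resnames)
        prof = map_profile_to_chain(prof, m, "A")
        rec_cons = SimpleNamespace(
            classification="b4--b4", partner_a="A", partner_b="B",
            contact_residues_a=[("A", i, "") for i in (1, 2, 3)],
            contact_residues_b=[])
        rec_var = SimpleNamespace(
            classification="b2--b2", partner_a="A", partner_b="B",
            contact_residues_a=[("A", i, "") for i in (7, 8, 9)],
            contact_residues_b=[])
        reports = interface_conservation(prof, [rec_cons, rec_var], "A")
        assert reports[0].fraction_conserved_contact == 1.0
        assert reports[1].fraction_conserved_contact == 0.0
        assert reports[0].fraction_conserved_contact > reports[1].fraction_conserved_contact
        assert 0.0 <= reports[0].background_fraction <= 1.0

    def test_no_conserved_columns_all_zero(self, tmp_path):
        aln, _ = make_alignment(width=10, n_seqs=8, conserved_columns=[], seed=3)
        prof = column_identity(aln)
        assert conserved_positions(prof, 0.90) == set()
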