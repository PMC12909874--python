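"""Gap trimming, Shannon entropy profiles, logo matrices, center-star MSA."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from seqtriage import (
    Alignment,
    ProteinSequence,
    SequenceError,
    build_small_msa,
    column_entropy,
    global_align,
    logo_matrix,
    trim_high_gap_columns,
)
from seqtriage.conservation import MAX_ENTROPY_BITS

AAS = sorted("ACDEFGHIKLMNPQRSTVWY")


def aln(*rows):
    return Alignment(ids=[f"s{i}" for i in range(len(rows))], rows=list(rows))


class TestAlignmentType:
    def test_unequal_rows_rejected(self):
        with pytest.raises(SequenceError):
            aln("MK-", "MKVL")

    def test_fasta_roundtrip(self, tmp_path):
        a = aln("MK-V", "M-KV")
        path = tmp_path / "aln.fasta"
        a.to_fasta(path)
        back = Alignment.from_fasta(path)
        assert back.rows == a.rows and back.ids == a.ids


class TestTrim:
    def test_gap_free_alignment_unchanged(self):
        a = aln("MKV", "MAV")
        for threshold in (0.0, 0.5, 1.0):
            trimmed, removed = trim_high_gap_columns(a, threshold)
            assert trimmed.rows == a.rows and removed == []

    def test_all_gap_column_removed(self):
        a = aln("M-K", "M-V")
        trimmed, removed = trim_high_gap_columns(a, 0.5)
        assert trimmed.rows == ["MK", "MV"] and removed == [1]

    def test_counting_by_gap_fraction(self):
        # per-column gap fractions 0, .25, .5, .75; strictly-above-0.5
        # columns are removed, the exactly-0.5 column is kept
        a = aln("MKVL", "MKV-", "MK--", "M---")
        trimmed, removed = trim_high_gap_columns(a, 0.5)
        assert trimmed.n_columns == 3 and removed == [3]

    def test_idempotent(self):
        a = aln("MKVL", "MKV-", "MK--", "M---")
        once, _ = trim_high_gap_columns(a, 0.5)
        twice, removed = trim_high_gap_columns(once, 0.5)
        assert twice.rows == once.rows and removed == []

    def test_threshold_one_keeps_everything(self):
        # the rule removes columns with gap fraction STRICTLY above the
        # threshold, so 1.0 removes nothing (all-gap columns included)
        a = aln("M-K-", "M--V")
        trimmed, removed = trim_high_gap_columns(a, 1.0)
        assert removed == [] and trimmed.n_columns == 4

    def test_removing_every_column_errors(self):
        with pytest.raises(SequenceError):
            trim_high_gap_columns(aln("M-", "-M"), 0.4)


class TestEntropy:
    def test_closed_forms(self):
        # one conserved column, one 50/50 column
        a = aln("MK", "MV")
        profile = column_entropy(a)
        assert profile.entropy[0] == pytest.approx(0.0)
        assert profile.entropy[1] == pytest.approx(1.0)

    def test_uniform_20_column(self):
        a = Alignment(ids=[f"s{i}" for i in range(20)], rows=list(AAS))
        assert column_entropy(a).entropy[0] == pytest.approx(math.log2(20))

    def test_gaps_excluded_from_distribution(self):
        # first column K,K,-,- : distribution over residues only -> 0 bits
        a = aln("KM", "KM", "-M", "-M")
        profile = column_entropy(a)
        assert profile.entropy[0] == pytest.approx(0.0)
        assert profile.gap_fraction[0] == pytest.approx(0.5)

    def test_all_gap_column_reported_missing(self):
        a = aln("M-", "M-")
        assert np.isnan(column_entropy(a).entropy[1])

    @given(st.lists(st.sampled_from(AAS + ["-"]), min_size=2, max_size=12))
    def test_entropy_bounds_random_columns(self, column):
        # pad every row with a residue so no row degaps to empty
        rows = [c + "A" for c in column]
        a = Alignment(ids=[f"s{i}" for i in range(len(rows))], rows=rows)
        h = column_entropy(a).entropy[0]
        if all(c == "-" for c in column):
            assert np.isnan(h)
        else:
            assert -1e-9 <= h <= MAX_ENTROPY_BITS + 1e-9


class TestLogoMatrix:
    def test_single_sequence_frequency_one(self):
        a = aln("MKV")
        mat = logo_matrix(a)
        assert mat.loc[1, "M"] == 1.0 and mat.loc[2, "K"] == 1.0
        assert mat.to_numpy().sum(axis=1) == pytest.approx([1.0, 1.0, 1.0])

    def test_hand_counted_matrix(self):
        a = aln("MK", "MV", "AK")
        mat = logo_matrix(a)
        assert mat.loc[1, "M"] == pytest.approx(2 / 3)
        assert mat.loc[1, "A"] == pytest.approx(1 / 3)
        assert mat.loc[2, "K"] == pytest.approx(2 / 3)

    def test_information_content_complements_entropy(self):
        a = aln("MK", "MV", "AK")
        profile = column_entropy(a)
        ic_mat = logo_matrix(a, information_content=True)
        for col in (1, 2):
            ic = MAX_ENTROPY_BITS - profile.entropy[col - 1]
            assert ic_mat.loc[col].sum() == pytest.approx(ic)


class TestCenterStar:
    def test_identical_sequences_gap_free(self):
        seqs = [ProteinSequence(f"s{i}", "MKVLA") for i in range(4)]
        a = build_small_msa(seqs)
        assert a.rows == ["MKVLA"] * 4

    def test_two_sequences_reduce_to_pairwise(self):
        x, y = ProteinSequence("x", "MKVLAK"), ProteinSequence("y", "MVLK")
        a = build_small_msa([x, y])
        pair = global_align(x, y)
        assert sorted(a.rows) == sorted([pair.aligned_a, pair.aligned_b])

    def test_projections_consistent_with_star(self):
        # removing the all-gap columns of any two rows must reproduce the
        # center-pairwise alignment of those sequences (center-star property)
        seqs = [
            ProteinSequence("a", "MKVLAKGST"),
            ProteinSequence("b", "MKVAKGST"),
            ProteinSequence("c", "MKVLAKGSTQQ"),
        ]
        a = build_small_msa(seqs)
        assert len({len(r) for r in a.rows}) == 1
        for rid, row in zip(a.ids, a.rows):
            original = next(s for s in seqs if s.id == rid)
            assert row.replace("-", "") == original.residues

    def test_single_sequence_trivial(self):
        a = build_small_msa([ProteinSequence("x", "MK")])
        assert a.rows == ["MK"]
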