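import random

import pytest
from Bio.Align import substitution_matrices

from ssbkit.alignment import (
    SimilarityScheme,
    global_align,
    identity_similarity,
    shade_msa,
)

from .conftest import all_sequences, brute_force_global_score


class TestGlobalAlign:
    def test_self_alignment_is_perfect(self):
        res = global_align("ACDE", "ACDE")
        assert (res.identity_pct, res.similarity_pct) == (100, 100)
        assert res.aligned_a == res.aligned_b == "ACDE"

    def test_conservative_substitution_counts_as_similar(self):
        # K and R share the basic-residue similarity group
        res = global_align("KDE", "RDE")
        assert (res.identity_pct, res.similarity_pct) == (67, 100)

    def test_length_mismatch_forces_gap_columns(self):
        res = global_align("AAAA", "AA")
        assert len(res.aligned_a) == 4
        assert res.aligned_b.count("-") == 2
        # full-alignment-length denominator: 2 identities over 4 columns
        assert res.identity_pct == 50

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            global_align("", "ACD")

    def test_degapped_alignment_equals_inputs(self):
        res = global_align("MKVLWAAGH", "MKWAAH")
        assert res.aligned_a.replace("-", "") == "MKVLWAAGH"
        assert res.aligned_b.replace("-", "") == "MKWAAH"

    def test_matches_brute_force_on_random_pairs(self):
        matrix = substitution_matrices.load("BLOSUM62")
        rng = random.Random(7)
        for _ in range(15):
            a = "".join(rng.choices("ACDK", k=rng.randint(1, 5)))
            b = "".join(rng.choices("ACDK", k=rng.randint(1, 5)))
            expected = brute_force_global_score(a, b, matrix, 10.0, 0.5)
            assert global_align(a, b).score == pytest.approx(expected)


class TestIdentitySimilarity:
    def test_symmetric_under_swap(self):
        pairs = [("MKV-LW", "MR-VLW"), ("AAAA", "CC--")]
        for sa, sb in pairs:
            assert identity_similarity(sa, sb) == identity_similarity(sb, sa)

    def test_shorter_denominator(self):
        ident, simil = identity_similarity("AAAA", "--AA", denominator="shorter")
        assert (ident, simil) == (100, 100)

    def test_zero_denominator_errors(self):
        with pytest.raises(ValueError):
            identity_similarity("", "")

    def test_similarity_monotone_under_group_enlargement(self):
        base = SimilarityScheme()
        rng = random.Random(3)
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(20):
            n = rng.randint(4, 10)
            sa = "".join(rng.choices(alphabet, k=n))
            sb = "".join(rng.choices(alphabet, k=n))
            enlarged = SimilarityScheme(
                groups=base.groups + (frozenset(rng.choices(alphabet, k=6)),)
            )
            _, s_base = identity_similarity(sa, sb, base)
            _, s_big = identity_similarity(sa, sb, enlarged)
            assert s_big >= s_base

    def test_identity_bounded_by_similarity(self):
        rng = random.Random(11)
        for _ in range(30):
            sa = "".join(rng.choices("ACDEFKRW", k=8))
            sb = "".join(rng.choices("ACDEFKRW", k=8))
            ident, simil = identity_similarity(sa, sb)
            assert 0 <= ident <= simil <= 100


class TestShadeMsa:
    def test_fully_conserved_column(self):
        assert shade_msa(["W", "W", "W", "W", "W"]) == ["100%"]

    def test_similarity_cluster_at_80(self):
        # W,F co-group: cluster of 4 of 5 sequences
        assert shade_msa(["W", "W", "W", "F", "L"]) == [">=80%"]

    def test_unrelated_column(self):
        assert shade_msa(["A", "D", "K", "W", "G"]) == ["none"]

    def test_gaps_never_similar(self):
        assert shade_msa(["W", "W", "-", "-", "-"]) == ["none"]

    def test_ragged_msa_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            shade_msa(["AC", "A"])

    def test_multicolumn(self):
        msa = ["KDWA", "RDWA", "KEWC", "REYS", "KDFG"]
        # col0 K/R all similar (100%), col1 D/E all similar (100%),
        # col2 W/W/W/Y/F all co-group (100%), col3 A,A,C,S,G unrelated
        assert shade_msa(msa) == ["100%", "100%", "100%", "none"]
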