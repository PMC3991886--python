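from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssbkit.composition import (
    GroupScheme,
    ReconstructionError,
    ResidueCounts,
    arg_lys_ratio,
    count_residues,
    group_fractions,
    percentages,
    profile,
    reconstruct_counts,
)
from ssbkit.io import CANONICAL_ALPHABET, SequenceRecord
from ssbkit._util import round_half_up

# Integer counts realizing the printed DpsSSB composition row at length 142,
# frozen from a brute-force check that each count re-rounds to the printed
# percentage.
DPS_COUNTS = {
    "A": 10, "I": 9, "L": 7, "V": 5, "M": 4, "G": 16, "P": 6, "K": 6,
    "R": 10, "D": 7, "E": 11, "Q": 7, "N": 9, "S": 13, "T": 10, "H": 1,
    "W": 4, "F": 2, "Y": 4, "C": 1,
}

sequences = st.text(alphabet=CANONICAL_ALPHABET, min_size=1, max_size=500)


class TestCounting:
    def test_multiset_count(self):
        counts = count_residues(SequenceRecord(id="x", residues="MAGKK"))
        assert counts.counts == {"M": 1, "A": 1, "G": 1, "K": 2}
        assert counts.length == 5

    @given(sequences)
    @settings(max_examples=50, deadline=None)
    def test_counts_conserve_length(self, seq):
        counts = count_residues(SequenceRecord(id="x", residues=seq))
        assert sum(counts.counts.values()) == len(seq) == counts.length

    def test_counts_must_sum_to_length(self):
        with pytest.raises(ValueError, match="sum"):
            ResidueCounts(counts={"A": 3}, length=4)


class TestPercentages:
    def test_half_up_rounding_to_printed_value(self):
        counts = ResidueCounts(counts={"G": 16, "A": 126}, length=142)
        assert percentages(counts)["G"] == 11.3

    def test_simple_quarter(self):
        counts = ResidueCounts(counts={"A": 1, "G": 3}, length=4)
        assert percentages(counts)["A"] == 25.0

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            ResidueCounts(counts={}, length=0)


class TestReconstruction:
    def test_dps_row_realized_exactly(self, reference_table):
        counts = reconstruct_counts(reference_table.row("DpsSSB"), 142)
        assert counts.counts == DPS_COUNTS
        assert counts.mismatches == ()

    def test_eco_row_realized_with_known_thr_defect(self, reference_table):
        # the printed EcoSSB Thr 5.0% admits no integer count at length 178
        counts = reconstruct_counts(reference_table.row("EcoSSB"), 178)
        assert (counts.get("A"), counts.get("V"), counts.get("I"),
                counts.get("L")) == (13, 13, 5, 8)
        assert counts.mismatches == ("T",)
        with pytest.raises(ReconstructionError, match="T"):
            reconstruct_counts(reference_table.row("EcoSSB"), 178, strict=True)

    def test_single_residue_row(self):
        row = {r: 0.0 for r in CANONICAL_ALPHABET}
        row["W"] = 100.0
        counts = reconstruct_counts(row, 50)
        assert counts.get("W") == 50 and counts.length == 50

    @given(sequences)
    @settings(max_examples=100, deadline=None)
    def test_round_trip_from_any_sequence(self, seq):
        counts = count_residues(SequenceRecord(id="x", residues=seq))
        rebuilt = reconstruct_counts(percentages(counts), len(seq))
        assert dict(rebuilt.counts) == {
            r: counts.get(r) for r in CANONICAL_ALPHABET
        }
        assert rebuilt.mismatches == ()


# Group percentages quoted alongside the printed composition table.
GROUP_CASES = [
    ("DpsSSB", "charged", 24.5),
    ("FpsSSB", "charged", 29.3),
    ("PtoSSB", "charged", 30.4),
    ("EcoSSB", "charged", 19.7),
    ("DpsSSB", "polar", 30.2),
    ("FpsSSB", "polar", 31.5),
    ("PcrSSB", "polar", 37.4),
    ("DpsSSB", "hydrophobic", 44.2),
    ("FpsSSB", "hydrophobic", 39.9),
    ("ParSSB", "hydrophobic", 46.5),
    ("EcoSSB", "hydrophobic", 52.7),
    ("EcoSSB", "aromatic", 6.6),
    ("FpsSSB", "aromatic", 9.3),
    ("DpsSSB", "glycine", 11.3),
    ("FpsSSB", "proline", 2.1),
]


class TestGroupFractions:
    @pytest.mark.parametrize("protein,group,expected", GROUP_CASES)
    def test_quoted_group_percentages(self, reference_table, protein, group,
                                      expected):
        fractions = group_fractions(reference_table.row(protein))
        assert fractions[group] == expected

    def test_empty_group_scores_zero(self, reference_table):
        scheme = GroupScheme(groups={"nothing": frozenset()})
        assert group_fractions(reference_table.row("DpsSSB"), scheme) == {
            "nothing": 0.0
        }

    def test_unknown_group_name_errors(self):
        with pytest.raises(KeyError, match="unknown"):
            GroupScheme()["weird"]

    @given(sequences)
    @settings(max_examples=50, deadline=None)
    def test_partition_conserves_total(self, seq):
        # charged/polar/hydrophobic plus Cys partition the alphabet, so the
        # group values recover the row total (each of the 20 one-decimal
        # roundings may contribute up to 0.05 of drift)
        counts = count_residues(SequenceRecord(id="x", residues=seq))
        fractions = group_fractions(counts)
        total = (
            fractions["charged"] + fractions["polar"]
            + fractions["hydrophobic"] + percentages(counts)["C"]
        )
        assert total == pytest.approx(100.0, abs=1.0)

    @given(sequences)
    @settings(max_examples=50, deadline=None)
    def test_matches_per_character_tally(self, seq):
        # independent route: tally characters, round each member percentage
        # to printed precision, sum
        counts = count_residues(SequenceRecord(id="x", residues=seq))
        fractions = group_fractions(counts)
        tally = Counter(seq)
        for group, members in GroupScheme().groups.items():
            brute = round_half_up(
                sum(
                    round_half_up(100.0 * tally[r] / len(seq), 1)
                    for r in members
                ),
                1,
            )
            assert fractions[group] == brute


ARG_RATIO_CASES = [
    ("DpsSSB", 0.63), ("FpsSSB", 0.22), ("ParSSB", 0.53), ("PcrSSB", 0.55),
    ("PinSSB", 0.43), ("PprSSB", 0.54), ("PtoSSB", 0.20), ("EcoSSB", 0.62),
    ("TteSSB3", 0.53), ("TmaSSB", 0.75),
]


class TestArgLysRatio:
    @pytest.mark.parametrize("protein,expected", ARG_RATIO_CASES)
    def test_quoted_ratios(self, reference_table, protein, expected):
        assert arg_lys_ratio(reference_table.row(protein)) == expected

    def test_equal_counts_give_half(self):
        counts = ResidueCounts(counts={"R": 5, "K": 5, "G": 10}, length=20)
        assert arg_lys_ratio(counts) == 0.50

    def test_undefined_without_basic_residues(self):
        counts = ResidueCounts(counts={"G": 10}, length=10)
        assert arg_lys_ratio(counts) is None


def test_profile_bundles_consistent_pieces(reference_table):
    counts = reconstruct_counts(reference_table.row("DpsSSB"), 142)
    prof = profile(counts)
    assert prof.percent["G"] == 11.3
    assert prof.group_percent["charged"] == 24.5
    assert prof.arg_ratio == 0.63
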