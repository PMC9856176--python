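"""Consensus profiles, unique-residue calling, query scoring, span lengths."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cetzkit.consensus import (
    ChemistryClasses,
    build_consensus,
    call_unique_residues,
    region_lengths,
    shared_unique_residues,
    unique_residue_scores,
)
from cetzkit.io_formats import AlignedRecord, GroupedAlignment
from cetzkit.synthetic_data import (
    AlignmentSimSpec,
    plant_discriminating_columns,
    simulate_query_sequence,
    simulate_subfamily_alignment,
)

from conftest import consensus_oracle, random_alignment


class TestBuildConsensus:
    def test_single_sequence_group_is_identity(self):
        aln = GroupedAlignment(
            (AlignedRecord("s1", "G", "AC-DE"), AlignedRecord("x", "H", "AAAAA"))
        )
        profile = build_consensus(aln, "G")
        assert [c.residue for c in profile.columns] == ["A", "C", None, "D", "E"]
        assert all(c.score == 100.0 for c in profile.columns if c.residue)
        assert profile.columns[2].depth == 0 and profile.columns[2].score == 0.0

    def test_three_quarters_majority(self):
        aln = GroupedAlignment(
            tuple(AlignedRecord(f"s{i}", "G", ch) for i, ch in enumerate("AAAG"))
        )
        col = build_consensus(aln, "G").columns[0]
        assert col.residue == "A" and col.score == 75.0

    def test_gaps_excluded_from_score(self):
        aln = GroupedAlignment(
            tuple(AlignedRecord(f"s{i}", "G", ch) for i, ch in enumerate("AA--"))
        )
        col = build_consensus(aln, "G").columns[0]
        assert col.residue == "A" and col.score == 100.0
        assert col.depth == 2 and col.gap_fraction == 0.5

    def test_tie_breaks_alphabetically_and_flags(self):
        aln = GroupedAlignment(
            tuple(AlignedRecord(f"s{i}", "G", ch) for i, ch in enumerate("GGAA"))
        )
        col = build_consensus(aln, "G").columns[0]
        assert col.residue == "A" and col.tie

    def test_ambiguity_codes_count_in_depth_not_consensus(self):
        aln = GroupedAlignment(
            tuple(AlignedRecord(f"s{i}", "G", ch) for i, ch in enumerate("AXXX"))
        )
        col = build_consensus(aln, "G").columns[0]
        assert col.residue == "A" and col.depth == 4 and col.score == 25.0

    def test_unknown_group(self, tiny_alignment):
        with pytest.raises(KeyError, match="unknown group"):
            build_consensus(tiny_alignment, "nope")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        aln = random_alignment(rng, 10, 10, 50)
        for group in ("A", "B"):
            profile = build_consensus(aln, group)
            for got, (res, score, gapf, depth) in zip(
                profile.columns, consensus_oracle(aln, group)
            ):
                assert got.residue == res
                assert got.score == pytest.approx(score)
                assert got.gap_fraction == pytest.approx(gapf)
                assert got.depth == depth


class TestUniqueResidueScores:
    def test_mean_of_group_scores(self, tiny_alignment):
        table = unique_residue_scores(
            build_consensus(tiny_alignment, "A"), build_consensus(tiny_alignment, "B")
        )
        row = table.iloc[0]
        assert (row.residue_a, row.residue_b) == ("D", "K")
        assert row.unique_score == 100.0
        # column 3: A has L/I split (50%), B has L (100%) -> mean 75
        assert table.iloc[3].unique_score == 75.0

    def test_symmetric_in_argument_order(self, tiny_alignment):
        pa = build_consensus(tiny_alignment, "A")
        pb = build_consensus(tiny_alignment, "B")
        ab = unique_residue_scores(pa, pb)
        ba = unique_residue_scores(pb, pa)
        assert (ab["unique_score"] == ba["unique_score"]).all()
        assert (ab["residue_a"].fillna("") == ba["residue_b"].fillna("")).all()

    def test_identical_profiles_keep_common_score(self, tiny_alignment):
        pa = build_consensus(tiny_alignment, "A")
        table = unique_residue_scores(pa, pa)
        assert (table["unique_score"] == table["score_a"]).all()

    def test_column_mismatch(self, tiny_alignment):
        other = GroupedAlignment((AlignedRecord("q", "Q", "ACD"),))
        with pytest.raises(ValueError, match="mismatch"):
            unique_residue_scores(
                build_consensus(tiny_alignment, "A"), build_consensus(other, "Q")
            )


class TestCallUniqueResidues:
    def _table(self, aln):
        return unique_residue_scores(build_consensus(aln, "A"), build_consensus(aln, "B"))

    def test_chemistry_labels(self, tiny_alignment):
        calls = call_unique_residues(self._table(tiny_alignment), 90)
        by_col = {c.column: c for c in calls}
        assert by_col[0].chemistry == "different"  # D (negative) vs K (positive)
        assert 1 not in by_col  # same consensus residue, never called

    def test_similar_chemistry_pair(self):
        aln = GroupedAlignment(
            (AlignedRecord("a", "A", "L"), AlignedRecord("b", "B", "I"))
        )
        (call,) = call_unique_residues(self._table(aln), 90)
        assert call.chemistry == "similar"  # both nonpolar

    def test_strict_threshold_boundary(self):
        # two groups of 10: A all D; B 9 K + 1 D -> scores 100 and 90, mean 95
        records = [AlignedRecord(f"a{i}", "A", "D") for i in range(10)]
        records += [AlignedRecord(f"b{i}", "B", "K" if i else "D") for i in range(10)]
        table = self._table(GroupedAlignment(tuple(records)))
        assert table.iloc[0].unique_score == 95.0
        assert call_unique_residues(table, 95) == []  # strict >
        assert len(call_unique_residues(table, 95, strict=False)) == 1

    def test_majority_gap_column_excluded(self):
        records = [AlignedRecord(f"a{i}", "A", "D" if i < 2 else "-") for i in range(6)]
        records += [AlignedRecord(f"b{i}", "B", "K") for i in range(6)]
        table = self._table(GroupedAlignment(tuple(records)))
        assert call_unique_residues(table, 90) == []
        assert len(call_unique_residues(table, 90, max_gap_fraction=1.0)) == 1

    def test_planted_columns_recovered_with_chemistry_split(self):
        planted = plant_discriminating_columns(10, 16, 300, seed=11)
        aln, truth = simulate_subfamily_alignment(
            AlignmentSimSpec(length=300, planted_columns=planted, seed=3)
        )
        calls = call_unique_residues(self._table(aln), 90)
        assert sorted(c.column for c in calls) == sorted(p.column for p in truth)
        assert sum(c.chemistry == "different" for c in calls) == 10
        assert sum(c.chemistry == "similar" for c in calls) == 16

    @pytest.mark.parametrize("seed", range(3))
    def test_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        aln = random_alignment(rng, 15, 15, 80, gap_rate=0.05)
        table = self._table(aln)
        sets = [
            {c.column for c in call_unique_residues(table, t)} for t in (95, 90, 80)
        ]
        assert sets[0] <= sets[1] <= sets[2]


class TestChemistryClasses:
    def test_default_partitions_all_standard_residues(self):
        chem = ChemistryClasses.default()
        assert chem.relation("D", "E") == "similar"
        assert chem.relation("D", "K") == "different"

    def test_incomplete_partition_rejected(self):
        with pytest.raises(ValueError, match="not assigned"):
            ChemistryClasses({"only": ("A", "C")})

    def test_double_assignment_rejected(self):
        classes = dict(ChemistryClasses.default().classes)
        classes["extra"] = ("A",)
        with pytest.raises(ValueError, match="two classes"):
            ChemistryClasses(classes)

    def test_from_tsv_round_trip(self, tmp_path):
        lines = ["residue\tclass_label"]
        for label, residues in ChemistryClasses.default().classes.items():
            lines += [f"{r}\t{label}" for r in residues]
        p = tmp_path / "chem.tsv"
        p.write_text("\n".join(lines) + "\n")
        chem = ChemistryClasses.from_tsv(p)
        assert chem.relation("K", "R") == "similar"


class TestSharedUniqueResidues:
    def _calls(self, n=10, seed=5):
        planted = plant_discriminating_columns(n, 0, 200, seed=seed)
        aln, _ = simulate_subfamily_alignment(
            AlignmentSimSpec(length=200, planted_columns=planted, seed=seed)
        )
        table = unique_residue_scores(
            build_consensus(aln, "A"), build_consensus(aln, "B")
        )
        return aln, call_unique_residues(table, 90)

    def test_consensus_identical_query_shares_all(self):
        aln, calls = self._calls()
        aln2 = simulate_query_sequence(aln, calls, len(calls), seed=1)
        assert shared_unique_residues(aln2, "query", calls, "a") == (10, 10)

    def test_all_gap_query_shares_none(self):
        aln, calls = self._calls()
        gap_query = GroupedAlignment(
            aln.records + (AlignedRecord("query", "q", "-" * aln.length),)
        )
        assert shared_unique_residues(gap_query, "query", calls, "a") == (0, 10)

    def test_partial_affiliation_query(self):
        """A query built to share 5 of 10 discriminating residues scores (5, 10)."""
        aln, calls = self._calls()
        aln2 = simulate_query_sequence(aln, calls, 5, seed=2)
        assert shared_unique_residues(aln2, "query", calls, "a") == (5, 10)
        assert shared_unique_residues(aln2, "query", calls, "b") == (5, 10)

    def test_unknown_query(self, tiny_alignment):
        from cetzkit.consensus import UniqueResidueCall

        call = UniqueResidueCall(0, "D", "K", 100.0, 100.0, 100.0, "different")
        with pytest.raises(KeyError):
            shared_unique_residues(tiny_alignment, "nope", [call], "a")

    def test_empty_call_set_rejected(self, tiny_alignment):
        with pytest.raises(ValueError, match="non-empty"):
            shared_unique_residues(tiny_alignment, "a1", [], "a")


class TestRegionLengths:
    def test_counts_non_gap_in_span(self):
        aln = GroupedAlignment(
            (AlignedRecord("s1", "G", "AC--G"), AlignedRecord("s2", "H", "-----"))
        )
        per_seq, summary = region_lengths(aln, (1, 5))
        lengths = dict(zip(per_seq.sequence_id, per_seq.ungapped_length))
        assert lengths == {"s1": 3, "s2": 0}
        assert set(summary.group_label) == {"G", "H"}

    def test_span_out_of_range(self, tiny_alignment):
        with pytest.raises(ValueError, match="out of range"):
            region_lengths(tiny_alignment, (2, 9))

    def test_planted_loop_occupancy_ranges(self):
        """Span occupancies planted per group are recovered in the summaries."""
        rng = np.random.default_rng(8)
        span_cols = 30
        records = []
        for i in range(12):  # long-loop group: 14-26 residues in the span
            n = int(rng.integers(14, 27))
            chars = np.array(["-"] * span_cols)
            chars[rng.choice(span_cols, n, replace=False)] = "A"
            records.append(AlignedRecord(f"l{i}", "long", "".join(chars)))
        for i in range(12):  # short-loop group: 3-6 residues
            n = int(rng.integers(3, 7))
            chars = np.array(["-"] * span_cols)
            chars[rng.choice(span_cols, n, replace=False)] = "A"
            records.append(AlignedRecord(f"s{i}", "short", "".join(chars)))
        _, summary = region_lengths(GroupedAlignment(tuple(records)), (1, span_cols))
        row = summary.set_index("group_label")
        assert 14 <= row.loc["long", "min"] and row.loc["long", "max"] <= 26
        assert 3 <= row.loc["short", "min"] and row.loc["short", "max"] <= 6


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.integers(0, 10_000), st.integers(2, 12), st.integers(5, 40))
def test_consensus_frequency_invariants(seed, n, length):
    """Residue frequencies sum to depth; scores in (0, 100] wherever depth > 0."""
    rng = np.random.default_rng(seed)
    aln = random_alignment(rng, n, 2, length, gap_rate=0.2, ambiguity_rate=0.05)
    profile = build_consensus(aln, "A")
    for col, (res, score, gapf, depth) in zip(
        profile.columns, consensus_oracle(aln, "A")
    ):
        assert col.depth == depth
        if depth > 0 and col.residue is not None:
            assert 0 < col.score <= 100
        assert col.score == pytest.approx(score)
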