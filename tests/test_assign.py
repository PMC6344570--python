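"""Proteome screening, copy combination, decision rule and TSV report."""

import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from densitrace.align import AlignmentResult, CANDIDATE_TOO_SHORT, NO_SCORED_POSITIONS, Exclusion
from densitrace.assign import (
    AMBIGUOUS,
    ASSIGNED,
    NO_MATCH,
    CandidateRanking,
    CombineRefusal,
    DecisionPolicy,
    RankedRow,
    combine_copies,
    decide_assignment,
    screen_proteome,
    write_report,
)
from densitrace.errors import DensitraceError
from densitrace.sizecode import SizeTable
from densitrace.synthetic import NOISELESS, generate_proteome, simulate_trace
from densitrace.trace import Ambiguous, GapRegion, Observed

from conftest import make_trace


def rec(id_, seq):
    return SeqRecord(Seq(seq), id=id_, description="")


def ranking_from_scores(scores: dict, trace_id="t"):
    """Build a ranking from {candidate: mean score or None (excluded)}."""
    rows = []
    for cid, s in scores.items():
        if s is None:
            rows.append(RankedRow(cid, Exclusion(cid, "size_violation")))
        else:
            rows.append(RankedRow(cid, AlignmentResult(cid, 0, (), (0,), s, 10)))
    rows.sort(key=lambda r: (0, -r.score, r.candidate_id) if r.score is not None else (1, 0, r.candidate_id))
    return CandidateRanking(trace_id=trace_id, rows=tuple(rows))


class TestScreenProteome:
    def test_recovers_simulated_source(self):
        proteome = generate_proteome(20, (100, 200), seed=5)
        src = proteome[7]
        trace, truth = simulate_trace(str(src.seq), (10, 70), NOISELESS, seed=5, trace_id="sim")
        ranking = screen_proteome(trace, proteome)
        best = ranking.best()
        assert best.candidate_id == src.id
        assert best.result.mean_score == 1.0
        assert best.result.start_offset == 10

    def test_all_ambiguous_trace_excludes_everything(self):
        trace = make_trace([None, None, None])
        ranking = screen_proteome(trace, [rec("a", "GAWK"), rec("b", "PPPP")])
        assert ranking.survivors() == []
        assert all(r.result.reason == NO_SCORED_POSITIONS for r in ranking.rows)

    def test_short_proteome_rows_are_too_short(self):
        trace = make_trace([1] * 6)
        ranking = screen_proteome(trace, [rec("a", "GAW"), rec("b", "PP")])
        assert all(r.result.reason == CANDIDATE_TOO_SHORT for r in ranking.rows)

    def test_duplicate_ids_rejected(self):
        trace = make_trace([1])
        with pytest.raises(DensitraceError, match="duplicate"):
            screen_proteome(trace, [rec("a", "GAW"), rec("a", "PPP")])

    def test_empty_proteome_rejected(self):
        with pytest.raises(DensitraceError):
            screen_proteome(make_trace([1]), [])

    def test_fasta_path_input(self, tmp_path):
        from Bio import SeqIO

        p = tmp_path / "prot.fasta"
        SeqIO.write([rec("a", "GAWKRD"), rec("b", "PPPPPP")], p, "fasta")
        ranking = screen_proteome(make_trace([0, 1, 6]), str(p))
        assert ranking.best().candidate_id == "a"


class TestDecideAssignment:
    def test_single_survivor_assigned(self):
        r = ranking_from_scores({"A": 0.92, "B": None, "C": None})
        a = decide_assignment(r)
        assert a.status == ASSIGNED and a.winner == "A"

    def test_within_margin_is_ambiguous(self):
        a = decide_assignment(ranking_from_scores({"A": 0.90, "B": 0.85}))
        assert a.status == AMBIGUOUS
        assert set(a.contenders) == {"A", "B"}
        assert a.needs_secondary_structure_check

    def test_beyond_margin_is_assigned(self):
        a = decide_assignment(ranking_from_scores({"A": 0.95, "B": 0.80}))
        assert a.status == ASSIGNED and a.winner == "A"
        assert a.margin_over_runner_up == pytest.approx(0.15)

    def test_exactly_margin_is_ambiguous(self):
        # the rule demands strictly more than the margin
        a = decide_assignment(ranking_from_scores({"A": 0.90, "B": 0.80}))
        assert a.status == AMBIGUOUS

    def test_contenders_are_all_within_margin_of_top(self):
        a = decide_assignment(ranking_from_scores({"A": 0.90, "B": 0.85, "C": 0.82, "D": 0.70}))
        assert a.contenders == ("A", "B", "C")

    def test_all_excluded_is_no_match(self):
        a = decide_assignment(ranking_from_scores({"A": None, "B": None}))
        assert a.status == NO_MATCH

    def test_monotone_raising_top_never_unassigns(self):
        others = {"B": 0.70, "C": 0.65}
        assigned_seen = False
        for top in np.linspace(0.70, 1.0, 16):
            a = decide_assignment(ranking_from_scores({"A": float(top), **others}))
            if assigned_seen:
                assert a.status == ASSIGNED
            if a.status == ASSIGNED and a.winner == "A":
                assigned_seen = True
        assert assigned_seen


class TestCombineCopies:
    def two_copies(self):
        a = make_trace([3, None, (2, 1)], trace_id="c1", group_id="g")
        b = make_trace([3, 4, (2, 2)], trace_id="c2", group_id="g")
        return a, b

    def test_identical_copies_combine_to_themselves(self):
        a = make_trace([3, 2, 1], trace_id="c1", group_id="g")
        b = make_trace([3, 2, 1], trace_id="c2", group_id="g")
        combined = combine_copies([a, b])
        assert combined.segments == a.segments

    def test_observed_beats_ambiguous_and_bounds_intersect(self):
        a, b = self.two_copies()
        combined = combine_copies([a, b])
        el = combined.segments[0].elements
        assert el[0] == Observed(3)
        assert el[1] == Observed(4)  # ambiguous in copy a, observed in copy b
        # gap bounds: copy a [2,3], copy b [1,4] -> [2,3]
        assert el[2].bounds == (2, 3)

    def test_conflicting_sizes_take_maximum_with_warning(self, caplog):
        a = make_trace([3], trace_id="c1", group_id="g")
        b = make_trace([5], trace_id="c2", group_id="g")
        with caplog.at_level("WARNING"):
            combined = combine_copies([a, b])
        assert combined.segments[0].elements[0] == Observed(5)
        assert any("conflicting" in m for m in caplog.messages)

    def test_skeleton_mismatch_refused(self):
        a = make_trace([3, 2], trace_id="c1", group_id="g")
        b = make_trace([3, 2, 1], trace_id="c2", group_id="g")
        out = combine_copies([a, b])
        assert isinstance(out, CombineRefusal) and out.reason == "skeleton_mismatch"

    def test_best_match_disagreement_refused(self):
        a, b = self.two_copies()
        rankings = [
            ranking_from_scores({"P1": 0.9, "P2": 0.5}, trace_id="c1"),
            ranking_from_scores({"P1": 0.4, "P2": 0.8}, trace_id="c2"),
        ]
        out = combine_copies([a, b], rankings)
        assert isinstance(out, CombineRefusal) and out.reason == "best_match_disagrees"

    def test_agreeing_best_matches_combine(self):
        a, b = self.two_copies()
        rankings = [
            ranking_from_scores({"P1": 0.9, "P2": 0.5}, trace_id="c1"),
            ranking_from_scores({"P1": 0.8, "P2": 0.4}, trace_id="c2"),
        ]
        out = combine_copies([a, b], rankings)
        assert not isinstance(out, CombineRefusal)

    def test_combined_positions_at_least_as_constrained(self):
        a, b = self.two_copies()
        combined = combine_copies([a, b])
        for seg_c, seg_a, seg_b in zip(combined.segments, a.segments, b.segments):
            for ec, ea, eb in zip(seg_c.elements, seg_a.elements, seg_b.elements):
                if isinstance(ec, GapRegion):
                    assert ec.min_len >= max(ea.min_len, eb.min_len)
                    assert ec.max_len <= min(ea.max_len, eb.max_len)
                elif isinstance(ec, Ambiguous):
                    assert isinstance(ea, Ambiguous) and isinstance(eb, Ambiguous)

    def test_single_trace_refused(self):
        a = make_trace([1], trace_id="c1", group_id="g")
        assert combine_copies([a]).reason == "need_two_copies"


class TestReport:
    def make_results(self):
        proteome = [rec("a", "GAWKRD"), rec("b", "PPPPPP"), rec("c", "GG")]
        trace = make_trace([0, 1, 6], trace_id="tr1")
        ranking = screen_proteome(trace, proteome)
        return [(ranking, decide_assignment(ranking))]

    def test_row_arithmetic(self, tmp_path):
        p = tmp_path / "r.tsv"
        write_report(self.make_results(), p)
        lines = [l for l in p.read_text().splitlines() if not l.startswith("#")]
        header, *rows = lines
        assert header.split("\t")[0] == "row_type"
        assert sum(1 for r in rows if r.startswith("detail")) == 3
        assert sum(1 for r in rows if r.startswith("summary")) == 1

    def test_empty_results_header_only(self, tmp_path):
        p = tmp_path / "r.tsv"
        write_report([], p)
        lines = p.read_text().splitlines()
        assert lines[-1].split("\t")[0] == "row_type"

    def test_rerun_is_byte_identical(self, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_report(self.make_results(), p1)
        write_report(self.make_results(), p2)
        assert p1.read_bytes() == p2.read_bytes()
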