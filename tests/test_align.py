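"""Constrained trace alignment: examples, exclusions, oracle equivalence."""

import numpy as np
import pytest

from densitrace.align import (
    CANDIDATE_TOO_SHORT,
    NO_SCORED_POSITIONS,
    SIZE_VIOLATION,
    AlignmentResult,
    Exclusion,
    align_trace,
    align_trace_oracle,
    verify_alignment,
)
from densitrace.errors import DensitraceError
from densitrace.sizecode import ScoreTable, SizeTable, encode_sequence

from conftest import make_trace, random_sequence, random_trace


def encode(seq, seq_id="cand"):
    return encode_sequence(seq, seq_id=seq_id)


class TestExamples:
    def test_exact_self_match_scores_one(self):
        seq = "GAWPKDNTRF"
        table = SizeTable()
        trace = make_trace([table[aa] for aa in seq])
        r = align_trace(trace, encode(seq))
        assert isinstance(r, AlignmentResult)
        assert r.mean_score == 1.0
        assert r.start_offset == 0
        assert r.n_scored == len(seq)

    def test_candidate_shorter_than_trace_is_excluded(self):
        trace = make_trace([1, 1, 1, 1, 1])
        r = align_trace(trace, encode("GAGA"))
        assert isinstance(r, Exclusion) and r.reason == CANDIDATE_TOO_SHORT

    def test_gap_length_chosen_to_fit_spacer(self):
        # trace [obs3, gap(n=2,x=1), obs0, obs6] on a candidate where the
        # true spacer is 3 residues; gap bounds are [2, 3]
        trace = make_trace([3, (2, 1), 0, 6])
        cand = encode("ATAAAGWAAAAA")  # classes 1,3,1,1,1,0,6,...
        r = align_trace(trace, cand)
        ro = align_trace_oracle(trace, cand)
        assert isinstance(r, AlignmentResult)
        assert r.gap_lengths == (3,)
        assert r.start_offset == 1
        assert r.mean_score == 1.0
        assert (r.mean_score, r.start_offset, r.gap_lengths) == (
            ro.mean_score, ro.start_offset, ro.gap_lengths,
        )

    def test_tie_broken_to_smallest_offset(self):
        trace = make_trace([0])
        r = align_trace(trace, encode("GGG"))
        ro = align_trace_oracle(trace, encode("GGG"))
        assert r.start_offset == ro.start_offset == 0
        assert r.mean_score == 1.0

    def test_big_observation_on_tiny_candidate_is_size_violation(self):
        trace = make_trace([6])
        r = align_trace(trace, encode("GGG"))
        assert isinstance(r, Exclusion) and r.reason == SIZE_VIOLATION
        ro = align_trace_oracle(trace, encode("GGG"))
        assert ro.reason == SIZE_VIOLATION

    def test_all_ambiguous_trace_has_no_scoreable_positions(self):
        trace = make_trace([None, None, None])
        r = align_trace(trace, encode("GAWKR"))
        assert isinstance(r, Exclusion) and r.reason == NO_SCORED_POSITIONS

    def test_interior_window_is_admissible(self):
        # trace matches the middle of the candidate; both termini unmodeled
        trace = make_trace([4, 5, 6])
        r = align_trace(trace, encode("GGGDKWGGG"))
        assert r.start_offset == 3 and r.mean_score == 1.0

    def test_empty_candidate_raises(self):
        from densitrace.sizecode import EncodedSequence

        trace = make_trace([1])
        with pytest.raises(DensitraceError):
            align_trace(trace, EncodedSequence(id="x", classes=()))


class TestMultiSegment:
    def test_segments_stay_ordered_and_disjoint(self):
        trace = make_trace([0, 1], [6, 6])
        cand = encode("GAKKKWWG")  # 0 1 5 5 5 6 6 0
        r = align_trace(trace, cand)
        ro = align_trace_oracle(trace, cand)
        assert isinstance(r, AlignmentResult)
        assert r.segment_offsets == ro.segment_offsets == (0, 5)
        assert r.mean_score == 1.0
        verify_alignment(trace, cand, r)

    def test_segments_may_abut(self):
        trace = make_trace([0], [1])
        cand = encode("GA")
        r = align_trace(trace, cand)
        assert r.segment_offsets == (0, 1)
        assert r.mean_score == 1.0


class TestProperties:
    def test_translation_invariance(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            trace = random_trace(rng, max_positions=6, max_segments=1)
            seq = random_sequence(rng, 25)
            r0 = align_trace(trace, encode(seq))
            r1 = align_trace(trace, encode("G" * 4 + seq))
            if isinstance(r0, Exclusion):
                # prepending glycines can only add placements, never remove;
                # a scored result may appear, but an exclusion reason of
                # too-short must disappear once long enough
                continue
            assert isinstance(r1, AlignmentResult)
            assert r1.mean_score >= r0.mean_score
            if r1.mean_score == r0.mean_score:
                assert r1.start_offset <= r0.start_offset + 4

    def test_ambiguous_positions_do_not_change_the_score_of_a_placement(self):
        # scoring a trace with ambiguous positions removed, at the same
        # placement, gives the same mean
        trace = make_trace([3, None, 2, None, 5])
        stripped = make_trace([3, 2, 5])
        seq = "TPSAK"  # classes 3 3 2 1 5
        r = align_trace(trace, encode(seq))
        assert r.start_offset == 0 and r.n_scored == 3
        # same pairs scored: positions 0, 2, 4 of the candidate
        table = ScoreTable()
        expected = (table.score[3, 3] + table.score[2, 2] + table.score[5, 5]) / 3
        assert r.mean_score == expected

    def test_mean_score_within_table_range(self):
        rng = np.random.default_rng(11)
        table = ScoreTable()
        for _ in range(30):
            trace = random_trace(rng, max_positions=6)
            seq = random_sequence(rng, 30, p_wildcard=0.1)
            r = align_trace(trace, encode(seq), table)
            if isinstance(r, AlignmentResult):
                assert table.min_score() <= r.mean_score <= 1.0

    def test_returned_alignments_verify_posthoc(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            trace = random_trace(rng, max_positions=7)
            cand = encode(random_sequence(rng, 30, p_wildcard=0.05))
            r = align_trace(trace, cand)
            if isinstance(r, AlignmentResult):
                verify_alignment(trace, cand, r)


class TestOracleEquivalence:
    def test_randomized_small_instances(self):
        rng = np.random.default_rng(42)
        n_scored_results = 0
        for _ in range(200):
            trace = random_trace(rng, max_positions=6, max_segments=2)
            cand = encode(random_sequence(rng, int(rng.integers(3, 35)), p_wildcard=0.05))
            r = align_trace(trace, cand)
            ro = align_trace_oracle(trace, cand)
            assert type(r) is type(ro)
            if isinstance(r, AlignmentResult):
                n_scored_results += 1
                assert r.mean_score == ro.mean_score
                assert r.start_offset == ro.start_offset
                assert r.gap_lengths == ro.gap_lengths
                assert r.segment_offsets == ro.segment_offsets
                assert r.n_scored == ro.n_scored
            else:
                assert r.reason == ro.reason
        assert n_scored_results > 50  # the suite must exercise real alignments

    def test_oracle_guard(self):
        trace = make_trace([1] * 25)
        with pytest.raises(DensitraceError):
            align_trace_oracle(trace, encode("A" * 30))
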