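"""Constrained alignment of a density trace onto one candidate sequence.

The trace is slid along the candidate.  Within a segment, observed and
ambiguous elements each consume exactly one candidate residue; a gap
region consumes any number of residues within its bounds.  Segments are
placed in chain order without overlap, with unconstrained (>= 0)
spacing across missing regions.  The trace may map to any interior
window — both candidate termini may be unmodeled.

Each aligned (observed, candidate) pair is scored from the score table;
the alignment score is the mean over scored pairs.  Ambiguous trace
positions and wildcard candidate positions consume a residue but enter
neither numerator nor denominator.  A trial placement is inadmissible if
any observation exceeds its candidate residue by ``exclusion_delta`` or
more.  The search is exact: every admissible placement is considered.

Exclusion reasons for a whole candidate:

* ``candidate_too_short`` — the sequence is shorter than the minimum
  chain length the trace demands;
* ``size_violation`` — every placement hits the exclusion rule;
* ``no_scored_positions`` — admissible placements exist but none has a
  single scoreable pair (the mean is undefined).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DensitraceError
from .sizecode import (
    EXCLUDED,
    N_CLASSES,
    NEUTRAL,
    EncodedSequence,
    ScoreTable,
    score_pair,
)
from .trace import Ambiguous, DensityTrace, GapRegion, Observed, trace_length_bounds

CANDIDATE_TOO_SHORT = "candidate_too_short"
SIZE_VIOLATION = "size_violation"
NO_SCORED_POSITIONS = "no_scored_positions"

#: Above this estimated number of enumerated placements a warning is
#: emitted; the search still runs (it is exact by design).
DEFAULT_PLACEMENT_BUDGET = 10_000_000


@dataclass(frozen=True)
class AlignmentResult:
    """Best admissible placement of a trace on one candidate.

    ``gap_lengths`` concatenates the chosen length of every gap region
    in trace order; ``segment_offsets`` gives each segment's candidate
    start; ``start_offset`` is the first segment's start.
    """

    candidate_id: str
    start_offset: int
    gap_lengths: tuple
    segment_offsets: tuple
    mean_score: float
    n_scored: int


@dataclass(frozen=True)
class Exclusion:
    """Why a candidate has no admissible scored alignment."""

    candidate_id: str
    reason: str
    detail: str = ""


def _tie_key(segment_offsets: tuple, gap_lengths: tuple) -> tuple:
    # documented tie-break: smaller start offset, then lexicographically
    # smallest gap-length tuple, then smallest segment offsets
    return (segment_offsets[0], gap_lengths, segment_offsets)


# ---------------------------------------------------------------------------
# segment compilation (shared vocabulary for the fast path)

def _wildcard_int(classes) -> np.ndarray:
    """Candidate classes as ints with wildcard mapped to index 7."""
    return np.asarray([N_CLASSES if c is None else c for c in classes], dtype=np.intp)


def _segment_variants(segment):
    """All gap-length choices of a segment.

    Yields ``(gap_tuple, seg_len, scored, n_consuming)`` where ``scored``
    is a list of (relative offset, observed class) pairs in element
    order.
    """
    gaps = [e for e in segment.elements if isinstance(e, GapRegion)]
    ranges = [range(g.min_len, g.max_len + 1) for g in gaps]
    for choice in itertools.product(*ranges):
        rel = 0
        gi = 0
        scored = []
        for e in segment.elements:
            if isinstance(e, Observed):
                scored.append((rel, e.size))
                rel += 1
            elif isinstance(e, Ambiguous):
                rel += 1
            else:
                rel += choice[gi]
                gi += 1
        yield (choice, rel, scored)


def _variant_tables(variant, cand: np.ndarray, table: ScoreTable):
    """Score every start offset of one segment variant at once.

    Returns (num, den, ok) arrays indexed by start offset, or None if
    the variant does not fit the candidate at any offset.  Accumulation
    runs in element order so that tied means are bit-identical with a
    scalar left-to-right walk (all default table entries are dyadic).
    """
    gap_tuple, seg_len, scored = variant
    n_starts = len(cand) - seg_len + 1
    if n_starts <= 0:
        return None
    # lookup tables extended with a wildcard column 7
    sm = np.zeros((N_CLASSES, N_CLASSES + 1))
    sm[:, :N_CLASSES] = table.score
    weight = np.ones(N_CLASSES + 1, dtype=np.intp)
    weight[N_CLASSES] = 0
    excl = np.zeros((N_CLASSES, N_CLASSES + 1), dtype=bool)
    for o in range(N_CLASSES):
        for c in range(N_CLASSES):
            excl[o, c] = o - c >= table.exclusion_delta

    num = np.zeros(n_starts)
    den = np.zeros(n_starts, dtype=np.intp)
    ok = np.ones(n_starts, dtype=bool)
    for rel, obs in scored:
        window = cand[rel : rel + n_starts]
        num += sm[obs][window]
        den += weight[window]
        ok &= ~excl[obs][window]
    return num, den, ok


def align_trace(
    trace: DensityTrace,
    candidate: EncodedSequence,
    scores: ScoreTable | None = None,
    placement_budget: int = DEFAULT_PLACEMENT_BUDGET,
):
    """Best-scoring admissible alignment, or an :class:`Exclusion`.

    Exact enumeration over start offsets, gap-length tuples and segment
    placements; ties resolved deterministically (smaller start offset,
    then smaller gap-length tuple, then smaller segment offsets).
    """
    if scores is None:
        scores = ScoreTable()
    L = len(candidate)
    if L == 0:
        raise DensitraceError(f"candidate {candidate.id!r} is empty")
    min_len = trace_length_bounds(trace).min_len
    if L < min_len:
        return Exclusion(
            candidate.id,
            CANDIDATE_TOO_SHORT,
            f"candidate length {L} < trace minimum length {min_len}",
        )

    cand = _wildcard_int(candidate.classes)
    seg_variants = [list(_segment_variants(s)) for s in trace.segments]

    est = 1
    for variants in seg_variants:
        est *= max(1, sum(max(0, L - v[1] + 1) for v in variants))
    if est > placement_budget:
        warnings.warn(
            f"trace {trace.trace_id!r} vs candidate {candidate.id!r}: "
            f"~{est:.2g} placements exceed the budget of {placement_budget}",
            RuntimeWarning,
            stacklevel=2,
        )

    tables = [
        [(v, _variant_tables(v, cand, scores)) for v in variants]
        for variants in seg_variants
    ]

    if len(trace.segments) == 1:
        outcome = _best_single_segment(tables[0])
    else:
        outcome = _best_multi_segment(tables, L)

    best, any_admissible = outcome
    if best is not None:
        mean, key, seg_offsets, gap_lengths, n_scored = best
        return AlignmentResult(
            candidate_id=candidate.id,
            start_offset=seg_offsets[0],
            gap_lengths=gap_lengths,
            segment_offsets=seg_offsets,
            mean_score=float(mean),
            n_scored=int(n_scored),
        )
    if any_admissible:
        return Exclusion(candidate.id, NO_SCORED_POSITIONS, "no aligned pair carries side-chain evidence")
    return Exclusion(
        candidate.id,
        SIZE_VIOLATION,
        "every placement has an observation exceeding the candidate residue by "
        f">= {scores.exclusion_delta}",
    )


def _best_single_segment(variant_tables):
    best = None
    any_admissible = False
    for (gap_tuple, _seg_len, _scored), tab in variant_tables:
        if tab is None:
            continue
        num, den, ok = tab
        if ok.any():
            any_admissible = True
        valid = ok & (den > 0)
        if not valid.any():
            continue
        means = np.where(valid, num / np.maximum(den, 1), -np.inf)
        m = means.max()
        s = int(np.argmax(means))  # first (= smallest) start at the max
        key = _tie_key((s,), gap_tuple)
        cand_best = (m, key, (s,), gap_tuple, int(den[s]))
        if best is None or m > best[0] or (m == best[0] and key < best[1]):
            best = cand_best
    return best, any_admissible


def _best_multi_segment(tables, L):
    n_seg = len(tables)
    min_len = [min((v[1] for v, t in tables[i]), default=0) for i in range(n_seg)]
    rem_min = [0] * (n_seg + 1)
    for i in range(n_seg - 1, -1, -1):
        rem_min[i] = rem_min[i + 1] + min_len[i]

    best = None
    any_admissible = False

    def rec(i, min_start, num, den, seg_offsets, gaps):
        nonlocal best, any_admissible
        if i == n_seg:
            any_admissible = True
            if den == 0:
                return
            mean = num / den
            key = _tie_key(tuple(seg_offsets), tuple(gaps))
            cand = (mean, key, tuple(seg_offsets), tuple(gaps), den)
            if best is None or mean > best[0] or (mean == best[0] and key < best[1]):
                best = cand
            return
        for (gap_tuple, seg_len, _scored), tab in tables[i]:
            if tab is None:
                continue
            v_num, v_den, v_ok = tab
            last = L - seg_len - rem_min[i + 1]
            for p in range(min_start, last + 1):
                if not v_ok[p]:
                    continue
                rec(
                    i + 1,
                    p + seg_len,
                    num + v_num[p],
                    den + int(v_den[p]),
                    seg_offsets + [p],
                    gaps + list(gap_tuple),
                )

    rec(0, 0, 0.0, 0, [], [])
    return best, any_admissible


# ---------------------------------------------------------------------------
# independent reference implementation

def align_trace_oracle(
    trace: DensityTrace,
    candidate: EncodedSequence,
    scores: ScoreTable | None = None,
    max_positions: int = 20,
    max_candidate: int = 60,
):
    """Exhaustive scalar enumeration of every placement (reference).

    Semantically identical to :func:`align_trace` by construction, kept
    deliberately naive; guarded to small instances.
    """
    if scores is None:
        scores = ScoreTable()
    if trace.n_positions() > max_positions:
        raise DensitraceError(f"oracle guard: trace has more than {max_positions} positions")
    if len(candidate) > max_candidate:
        raise DensitraceError(f"oracle guard: candidate longer than {max_candidate} residues")
    L = len(candidate)
    if L == 0:
        raise DensitraceError(f"candidate {candidate.id!r} is empty")
    if L < trace_length_bounds(trace).min_len:
        return Exclusion(
            candidate.id,
            CANDIDATE_TOO_SHORT,
            f"candidate length {L} < trace minimum length {trace_length_bounds(trace).min_len}",
        )

    placements = []  # (seg_offsets, gaps) fully enumerated

    def seg_placements(elements, start):
        """All (gap choice, end) walks of one segment from ``start``."""
        gaps = [e for e in elements if isinstance(e, GapRegion)]
        n_fixed = sum(1 for e in elements if not isinstance(e, GapRegion))
        out = []
        for choice in itertools.product(*[range(g.min_len, g.max_len + 1) for g in gaps]):
            end = start + n_fixed + sum(choice)
            if end <= L:
                out.append((choice, end))
        return out

    def enumerate_from(i, min_start, seg_offsets, gaps):
        if i == len(trace.segments):
            placements.append((tuple(seg_offsets), tuple(gaps)))
            return
        for start in range(min_start, L + 1):
            for choice, end in seg_placements(trace.segments[i].elements, start):
                enumerate_from(i + 1, end, seg_offsets + [start], gaps + list(choice))

    enumerate_from(0, 0, [], [])

    scored_placements = []
    any_admissible = False
    for seg_offsets, gap_choice in placements:
        num, den = 0.0, 0
        admissible = True
        gi = 0
        for seg, start in zip(trace.segments, seg_offsets):
            pos = start
            for e in seg.elements:
                if isinstance(e, Observed):
                    s = score_pair(e.size, candidate.classes[pos], scores)
                    if s is EXCLUDED or s == EXCLUDED:
                        admissible = False
                        break
                    if s != NEUTRAL:
                        num += s
                        den += 1
                    pos += 1
                elif isinstance(e, Ambiguous):
                    pos += 1
                else:
                    pos += gap_choice[gi]
                    gi += 1
            else:
                continue
            break
        if not admissible:
            continue
        any_admissible = True
        if den > 0:
            scored_placements.append((num / den, _tie_key(seg_offsets, gap_choice), seg_offsets, gap_choice, den))

    if scored_placements:
        best = scored_placements[0]
        for p in scored_placements[1:]:
            if p[0] > best[0] or (p[0] == best[0] and p[1] < best[1]):
                best = p
        mean, _key, seg_offsets, gap_choice, den = best
        return AlignmentResult(
            candidate_id=candidate.id,
            start_offset=seg_offsets[0],
            gap_lengths=tuple(gap_choice),
            segment_offsets=tuple(seg_offsets),
            mean_score=float(mean),
            n_scored=int(den),
        )
    if any_admissible:
        return Exclusion(candidate.id, NO_SCORED_POSITIONS, "no aligned pair carries side-chain evidence")
    return Exclusion(candidate.id, SIZE_VIOLATION, "every placement violates the size-exclusion rule")


# ---------------------------------------------------------------------------
# post-hoc verification

def verify_alignment(
    trace: DensityTrace,
    candidate: EncodedSequence,
    result: AlignmentResult,
    scores: ScoreTable | None = None,
) -> None:
    """Independently re-check a returned alignment.

    Walks the claimed placement and asserts: gap lengths within bounds,
    order-preserving non-overlapping segments, no aligned pair violating
    the exclusion rule, and the reported mean/n_scored.  Raises
    :class:`DensitraceError` on any violation.
    """
    if scores is None:
        scores = ScoreTable()
    if len(result.segment_offsets) != len(trace.segments):
        raise DensitraceError("segment offset count mismatch")
    gi = 0
    num, den = 0.0, 0
    prev_end = 0
    for seg, start in zip(trace.segments, result.segment_offsets):
        if start < prev_end:
            raise DensitraceError(f"segment at {start} overlaps previous (ends at {prev_end})")
        pos = start
        for e in seg.elements:
            if isinstance(e, GapRegion):
                g = result.gap_lengths[gi]
                gi += 1
                if not (e.min_len <= g <= e.max_len):
                    raise DensitraceError(f"gap length {g} outside bounds [{e.min_len}, {e.max_len}]")
                pos += g
            else:
                if pos >= len(candidate):
                    raise DensitraceError("placement runs off the candidate")
                if isinstance(e, Observed):
                    c = candidate.classes[pos]
                    if c is not None:
                        if e.size - c >= scores.exclusion_delta:
                            raise DensitraceError(
                                f"exclusion violated at candidate position {pos}: observed {e.size} vs {c}"
                            )
                        num += float(scores.score[e.size, c])
                        den += 1
                pos += 1
        prev_end = pos
    if gi != len(result.gap_lengths):
        raise DensitraceError("gap length count mismatch")
    if den != result.n_scored or den == 0:
        raise DensitraceError(f"n_scored mismatch: recomputed {den}, reported {result.n_scored}")
    if abs(num / den - result.mean_score) > 1e-12:
        raise DensitraceError(f"mean mismatch: recomputed {num / den}, reported {result.mean_score}")
    if result.start_offset != result.segment_offsets[0]:
        raise DensitraceError("start_offset disagrees with first segment offset")
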