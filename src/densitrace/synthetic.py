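"""Synthetic proteomes and noisy density traces with known ground truth.

The generator emulates what a model builder reads out of a real map:
most residues give a clean size class, some give only a C-alpha
(ambiguous), short stretches lose reliable C-alpha placement (gap
regions with an estimated residue count), and occasionally density
vanishes entirely (segment breaks).  Under-classing noise only ever
*depresses* an observed size — real disorder truncates side-chain
density, it does not inflate it — which keeps simulated traces
consistent with the one-sided exclusion rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import AlignmentResult
from .assign import ASSIGNED, DecisionPolicy, decide_assignment, screen_proteome
from .errors import DensitraceError
from .sizecode import STANDARD_AA, ScoreTable, SizeTable
from .trace import Ambiguous, DensityTrace, GapRegion, Observed, TraceSegment


@dataclass(frozen=True)
class NoiseModel:
    """Observation-quality model for simulated traces.

    p_ambiguous      probability a residue keeps only its C-alpha
    p_underclass     probability an observed size is depressed by one
                     class (floored at 0)
    gap_rate         expected gap regions per 100 residues (2.0 = one
                     per 50 residues)
    gap_x            maximum residue-count error attached to each gap
    gap_span         (min, max) true residues a gap region replaces
    missing_rate     expected completely-missing breaks per trace
    missing_span     (min, max) true residues lost per break
    """

    p_ambiguous: float = 0.10
    p_underclass: float = 0.05
    gap_rate: float = 2.0
    gap_x: int = 2
    gap_span: tuple = (3, 6)
    missing_rate: float = 0.0
    missing_span: tuple = (4, 8)

    def __post_init__(self):
        for p in (self.p_ambiguous, self.p_underclass):
            if not 0 <= p <= 1:
                raise DensitraceError(f"probability out of [0,1]: {p}")
        if self.gap_rate < 0 or self.missing_rate < 0 or self.gap_x < 0:
            raise DensitraceError("rates and gap_x must be >= 0")


NOISELESS = NoiseModel(p_ambiguous=0.0, p_underclass=0.0, gap_rate=0.0, missing_rate=0.0)


@dataclass(frozen=True)
class GroundTruth:
    """Everything needed to verify a recovered alignment."""

    source_id: str
    span: tuple  # (start, end) 0-based half-open on the source sequence
    true_classes: tuple  # size class of every residue in the span
    segment_spans: tuple  # (start, end) per emitted segment, source coords
    gap_true_lengths: tuple  # actual residue count of each gap region


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_proteome(
    n_seqs: int,
    length_range: tuple = (100, 400),
    seed=0,
    prefix: str = "prot",
) -> list:
    """Random decoy proteome: uniform residue usage, seeded, reproducible."""
    if n_seqs < 1:
        raise DensitraceError("n_seqs must be >= 1")
    lo, hi = length_range
    if not (1 <= lo <= hi):
        raise DensitraceError(f"invalid length range {length_range}")
    rng = _rng(seed)
    letters = np.array(list(STANDARD_AA))
    width = len(str(n_seqs))
    records = []
    for i in range(n_seqs):
        n = int(rng.integers(lo, hi + 1))
        seq = "".join(letters[rng.integers(0, 20, size=n)])
        records.append(
            SeqRecord(Seq(seq), id=f"{prefix}_{i + 1:0{width}d}", description="")
        )
    return records


def simulate_trace(
    seq: str,
    span: tuple,
    noise: NoiseModel = NoiseModel(),
    seed=0,
    size_table: SizeTable | None = None,
    trace_id: str = "sim",
    group_id: str | None = None,
) -> tuple:
    """Simulate the density trace a builder would produce for ``span``.

    ``span`` is 0-based half-open on ``seq``.  With zero noise the trace
    is the exact size-class encoding of the span in a single segment.
    Gap-region estimates are perturbed around the true length but
    clamped so the truth always stays within the admissible bounds.
    Returns ``(DensityTrace, GroundTruth)``.
    """
    size_table = size_table or SizeTable()
    start, end = span
    if not (0 <= start < end <= len(seq)):
        raise DensitraceError(f"span {span} outside sequence of length {len(seq)}")
    rng = _rng(seed)
    true_classes = tuple(size_table[aa] for aa in seq[start:end])
    span_len = end - start

    # structural noise first: completely-missing breaks, then gap regions
    missing = np.zeros(span_len, dtype=bool)
    n_breaks = int(rng.poisson(noise.missing_rate))
    for _ in range(n_breaks):
        m = int(rng.integers(noise.missing_span[0], noise.missing_span[1] + 1))
        if span_len - m <= 4:
            continue
        at = int(rng.integers(2, span_len - m - 2))
        missing[at : at + m] = True

    segments = []
    segment_spans = []
    gap_true_lengths = []
    i = 0
    while i < span_len:
        if missing[i]:
            i += 1
            continue
        j = i
        while j < span_len and not missing[j]:
            j += 1
        elements = []
        k = i
        while k < j:
            remaining = j - k
            lo_g, hi_g = noise.gap_span
            if (
                noise.gap_rate > 0
                and remaining > hi_g  # keep >= 1 residue after the gap
                and elements  # never open a segment on a gap
                and rng.random() < noise.gap_rate / 100.0
            ):
                m = int(rng.integers(lo_g, hi_g + 1))
                n_est = m + int(round(rng.normal(0.0, 1.0)))
                # clamp so the true length stays admissible:
                # n - floor(x/2) <= m <= n + x
                n_est = min(max(n_est, m - noise.gap_x, 1), m + noise.gap_x // 2)
                elements.append(GapRegion(n_est=n_est, x_err=noise.gap_x))
                gap_true_lengths.append(m)
                k += m
                continue
            true = true_classes[k]
            if rng.random() < noise.p_ambiguous:
                elements.append(Ambiguous())
            else:
                obs = true
                if obs is None:
                    elements.append(Ambiguous())
                    k += 1
                    continue
                if rng.random() < noise.p_underclass:
                    obs = max(0, obs - 1)
                elements.append(Observed(obs))
            k += 1
        segments.append(TraceSegment(elements))
        segment_spans.append((start + i, start + j))
        i = j

    trace = DensityTrace(trace_id=trace_id, group_id=group_id, segments=segments)
    truth = GroundTruth(
        source_id=trace_id,
        span=(start, end),
        true_classes=true_classes,
        segment_spans=tuple(segment_spans),
        gap_true_lengths=tuple(gap_true_lengths),
    )
    return trace, truth


# ---------------------------------------------------------------------------
# end-to-end recovery benchmark

@dataclass(frozen=True)
class RunRecord:
    run: int
    source_id: str
    span: tuple
    true_rank: int | None  # 1-based rank of the source, None if excluded
    best_score: float | None  # mean score of the rank-1 candidate
    correct_offset: bool
    assigned_correctly: bool
    margin: float | None  # top - runner-up score, None with < 2 survivors


@dataclass(frozen=True)
class HarnessSummary:
    n_runs: int
    rank1_rate: float
    assignment_rate: float
    mean_margin: float | None
    runs: tuple


def recovery_harness(
    n_runs: int = 100,
    n_seqs: int = 20,
    length_range: tuple = (100, 400),
    trace_length: int = 60,
    noise: NoiseModel = NoiseModel(),
    margin: float = 0.1,
    master_seed: int = 0,
    size_table: SizeTable | None = None,
    score_table: ScoreTable | None = None,
) -> HarnessSummary:
    """Repeated simulate -> screen -> decide cycles with known truth.

    Each run draws a fresh decoy proteome, picks a source protein and a
    window of ``trace_length`` residues, simulates a trace under
    ``noise`` and screens it back against the proteome.  Reports the
    rank-1 recovery rate, the rate of correct margin-rule assignments
    and the mean top-vs-runner-up margin.  Fully determined by
    ``master_seed``.
    """
    size_table = size_table or SizeTable()
    score_table = score_table or ScoreTable()
    policy = DecisionPolicy(margin=margin)
    children = np.random.SeedSequence(master_seed).spawn(n_runs)
    records = []
    for run, child in enumerate(children):
        rng = np.random.default_rng(child)
        proteome = generate_proteome(n_seqs, length_range, seed=rng)
        src = proteome[int(rng.integers(len(proteome)))]
        seq = str(src.seq)
        span_len = min(trace_length, len(seq))
        s0 = int(rng.integers(0, len(seq) - span_len + 1))
        trace, truth = simulate_trace(
            seq, (s0, s0 + span_len), noise, seed=rng,
            size_table=size_table, trace_id=f"run{run}",
        )
        ranking = screen_proteome(trace, proteome, size_table, score_table)
        rank = None
        for pos, row in enumerate(ranking.survivors(), start=1):
            if row.candidate_id == src.id:
                rank = pos
                break
        best = ranking.best()
        correct_offset = (
            best is not None
            and best.candidate_id == src.id
            and best.result.start_offset == truth.segment_spans[0][0]
        )
        assignment = decide_assignment(ranking, policy)
        assigned_correctly = assignment.status == ASSIGNED and assignment.winner == src.id
        survivors = ranking.survivors()
        run_margin = (
            survivors[0].score - survivors[1].score if len(survivors) >= 2 else None
        )
        records.append(RunRecord(
            run, src.id, (s0, s0 + span_len), rank,
            best.score if best is not None else None,
            correct_offset, assigned_correctly, run_margin,
        ))

    rank1 = sum(1 for r in records if r.true_rank == 1) / n_runs
    assigned = sum(1 for r in records if r.assigned_correctly) / n_runs
    margins = [r.margin for r in records if r.margin is not None]
    return HarnessSummary(
        n_runs=n_runs,
        rank1_rate=rank1,
        assignment_rate=assigned,
        mean_margin=float(np.mean(margins)) if margins else None,
        runs=tuple(records),
    )
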