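"""Proteome screening, multi-copy evidence combination and final assignment.

A trace is aligned against every candidate in a proteome and the
candidates are ranked by best mean score.  When several traced chains
are believed to be copies of the same polypeptide (same main-chain
conformation, marked by a shared ``group_id``), their density evidence
can be merged position-wise into a single better-constrained trace.
The final call follows two situations: a lone surviving candidate is
assigned outright; otherwise the top candidate is assigned only if it
beats every other survivor by more than the decision margin (0.1 on the
[0, 1] score scale).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from . import __version__
from .align import AlignmentResult, Exclusion, align_trace
from .errors import DensitraceError
from .sizecode import ScoreTable, SizeTable, config_digest, encode_sequence
from .trace import Ambiguous, DensityTrace, GapRegion, Observed, TraceSegment

logger = logging.getLogger(__name__)

ASSIGNED = "assigned"
AMBIGUOUS = "ambiguous"
NO_MATCH = "no_match"


@dataclass(frozen=True)
class DecisionPolicy:
    """Final-assignment rule: win by more than ``margin`` (default 0.1)."""

    margin: float = 0.1

    def __post_init__(self):
        if self.margin < 0:
            raise DensitraceError("decision margin must be >= 0")


@dataclass(frozen=True)
class RankedRow:
    candidate_id: str
    result: AlignmentResult | Exclusion

    @property
    def score(self) -> float | None:
        return self.result.mean_score if isinstance(self.result, AlignmentResult) else None


@dataclass(frozen=True)
class CandidateRanking:
    """One row per candidate, best score first, exclusions last."""

    trace_id: str
    rows: tuple

    def survivors(self) -> list[RankedRow]:
        return [r for r in self.rows if isinstance(r.result, AlignmentResult)]

    def best(self) -> RankedRow | None:
        s = self.survivors()
        return s[0] if s else None


@dataclass(frozen=True)
class Assignment:
    """Outcome of the two-situation decision rule for one trace.

    ``needs_secondary_structure_check`` flags ambiguous outcomes where
    the runner-ups would have to be rejected by external secondary-
    structure prediction (not computed here).
    """

    trace_id: str
    status: str
    winner: str | None = None
    contenders: tuple = ()
    margin_over_runner_up: float | None = None
    needs_secondary_structure_check: bool = False


@dataclass(frozen=True)
class CombineRefusal:
    reason: str
    detail: str = ""


def load_proteome(proteome) -> list:
    """Accept a FASTA path or a list of SeqRecords; enforce unique ids."""
    if isinstance(proteome, (str, Path)):
        try:
            records = list(SeqIO.parse(str(proteome), "fasta"))
        except (OSError, ValueError) as exc:
            raise DensitraceError(f"cannot read proteome FASTA {proteome}: {exc}") from exc
    else:
        records = list(proteome)
    if not records:
        raise DensitraceError("proteome is empty")
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise DensitraceError(f"duplicate sequence id in proteome: {rec.id!r}")
        seen.add(rec.id)
    return records


def screen_proteome(
    trace: DensityTrace,
    proteome,
    size_table: SizeTable | None = None,
    score_table: ScoreTable | None = None,
) -> CandidateRanking:
    """Align a trace against every sequence of a proteome and rank them.

    ``proteome`` is a FASTA path or a list of Bio.SeqRecords.  Survivors
    sort by mean score descending (ties by id); excluded candidates come
    last, sorted by id, each carrying its exclusion reason.
    """
    size_table = size_table or SizeTable()
    score_table = score_table or ScoreTable()
    records = load_proteome(proteome)
    rows = []
    for rec in records:
        encoded = encode_sequence(str(rec.seq), size_table, seq_id=rec.id)
        rows.append(RankedRow(rec.id, align_trace(trace, encoded, score_table)))
    rows.sort(
        key=lambda r: (0, -r.score, r.candidate_id) if r.score is not None else (1, 0, r.candidate_id)
    )
    return CandidateRanking(trace_id=trace.trace_id, rows=tuple(rows))


def decide_assignment(ranking: CandidateRanking, policy: DecisionPolicy | None = None) -> Assignment:
    """Apply the two-situation rule to a ranking.

    A single surviving candidate is assigned.  With several survivors
    the best is assigned only when it exceeds the runner-up by more than
    the margin; otherwise the decision is ambiguous and lists every
    candidate within the margin of the top score.
    """
    policy = policy or DecisionPolicy()
    survivors = ranking.survivors()
    if not survivors:
        return Assignment(ranking.trace_id, NO_MATCH)
    if len(survivors) == 1:
        return Assignment(ranking.trace_id, ASSIGNED, winner=survivors[0].candidate_id)
    top, second = survivors[0], survivors[1]
    gap = top.score - second.score
    if gap > policy.margin:
        return Assignment(
            ranking.trace_id, ASSIGNED, winner=top.candidate_id, margin_over_runner_up=gap
        )
    contenders = tuple(
        r.candidate_id for r in survivors if top.score - r.score <= policy.margin
    )
    return Assignment(
        ranking.trace_id,
        AMBIGUOUS,
        contenders=contenders,
        margin_over_runner_up=gap,
        needs_secondary_structure_check=True,
    )


# ---------------------------------------------------------------------------
# multi-copy combination

def _skeleton(trace: DensityTrace) -> tuple:
    # observed and ambiguous are the same positional kind: both stand for
    # exactly one residue with a placed C-alpha
    return tuple(
        tuple("gap" if isinstance(e, GapRegion) else "pos" for e in seg.elements)
        for seg in trace.segments
    )


def combine_copies(traces: list, rankings: list | None = None):
    """Merge the density evidence of several copies of one polypeptide.

    Preconditions: at least two traces sharing a ``group_id`` and an
    identical element skeleton (the proxy for similar main-chain
    conformations).  When ``rankings`` are supplied, every copy must
    have its best match on the same candidate; ``rankings=None`` skips
    that check for copies grouped purely by conformation and capsomer
    contacts (short chains whose individual rankings are uninformative).

    Per position, an observation beats ambiguity; conflicting observed
    sizes combine by maximum (the fullest density) with a logged
    warning.  Gap regions combine by intersecting their length bounds.
    Returns the combined :class:`DensityTrace` or a
    :class:`CombineRefusal`.
    """
    if len(traces) < 2:
        return CombineRefusal("need_two_copies", f"got {len(traces)} trace(s)")
    gids = {t.group_id for t in traces}
    if len(gids) != 1 or None in gids:
        return CombineRefusal("group_id_mismatch", f"group ids {sorted(map(str, gids))}")
    skel = _skeleton(traces[0])
    for t in traces[1:]:
        if _skeleton(t) != skel:
            return CombineRefusal(
                "skeleton_mismatch", f"{traces[0].trace_id!r} vs {t.trace_id!r}"
            )
    if rankings is not None:
        bests = []
        for t, r in zip(traces, rankings):
            b = r.best()
            if b is None:
                return CombineRefusal("no_best_match", f"trace {t.trace_id!r} has no surviving candidate")
            bests.append(b.candidate_id)
        if len(set(bests)) != 1:
            return CombineRefusal("best_match_disagrees", f"best matches {sorted(set(bests))}")

    gid = traces[0].group_id
    segments = []
    for si in range(len(traces[0].segments)):
        elements = []
        for ei in range(len(traces[0].segments[si].elements)):
            copies = [t.segments[si].elements[ei] for t in traces]
            if isinstance(copies[0], GapRegion):
                lo = max(g.min_len for g in copies)
                hi = min(g.max_len for g in copies)
                if lo > hi:
                    return CombineRefusal(
                        "gap_bounds_disjoint", f"segment {si}, element {ei}: [{lo}, {hi}]"
                    )
                elements.append(GapRegion(min_len=lo, max_len=hi))
            else:
                observed = [e for e in copies if isinstance(e, Observed)]
                if not observed:
                    elements.append(Ambiguous())
                else:
                    sizes = {e.size for e in observed}
                    if len(sizes) > 1:
                        logger.warning(
                            "group %r segment %d element %d: conflicting observed sizes %s; taking max",
                            gid, si, ei, sorted(sizes),
                        )
                    elements.append(Observed(max(sizes)))
        segments.append(TraceSegment(elements))
    return DensityTrace(trace_id=f"group:{gid}", group_id=gid, segments=segments)


# ---------------------------------------------------------------------------
# TSV report

REPORT_COLUMNS = [
    "row_type", "trace_id", "candidate_id", "mean_score", "n_scored",
    "start_offset", "segment_offsets", "gap_lengths", "exclusion_reason",
    "status", "winner", "contenders", "needs_secondary_structure_check",
]


def write_report(
    results: list,
    path: str | Path,
    size_table: SizeTable | None = None,
    score_table: ScoreTable | None = None,
) -> None:
    """Write a deterministic TSV report.

    ``results`` is a list of (CandidateRanking, Assignment) pairs; one
    detail row per candidate plus one summary row per trace.  The header
    records the tool version and the configuration hash so reruns are
    byte-identical and auditable.
    """
    size_table = size_table or SizeTable()
    score_table = score_table or ScoreTable()
    lines = [
        f"# densitrace {__version__}",
        f"# config_sha256 {config_digest(size_table, score_table)}",
        "\t".join(REPORT_COLUMNS),
    ]
    for ranking, assignment in results:
        for row in ranking.rows:
            if isinstance(row.result, AlignmentResult):
                r = row.result
                lines.append("\t".join([
                    "detail", ranking.trace_id, row.candidate_id,
                    f"{r.mean_score:.6f}", str(r.n_scored), str(r.start_offset),
                    ",".join(map(str, r.segment_offsets)),
                    ",".join(map(str, r.gap_lengths)) or "-",
                    "-", "-", "-", "-", "-",
                ]))
            else:
                lines.append("\t".join([
                    "detail", ranking.trace_id, row.candidate_id,
                    "-", "-", "-", "-", "-", row.result.reason,
                    "-", "-", "-", "-",
                ]))
        lines.append("\t".join([
            "summary", assignment.trace_id, "-", "-", "-", "-", "-", "-", "-",
            assignment.status,
            assignment.winner or "-",
            ",".join(assignment.contenders) or "-",
            "yes" if assignment.needs_secondary_structure_check else "no",
        ]))
    Path(path).write_text("\n".join(lines) + "\n")
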