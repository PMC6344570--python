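"""Density traces: ordered side-chain size observations from a cryo-EM map.

A trace records what a model builder could read off the density for one
polypeptide, position by position.  Three qualities of density occur:

* ``Observed`` — good side-chain density, reduced to a size class 0-6;
* ``Ambiguous`` — a reliable C-alpha but no usable side-chain density
  (the residue could be any of the 20 amino acids);
* ``GapRegion`` — connected main chain with unreliable C-alpha placement;
  only the residue count is estimated: with ``n`` placed C-alphas and a
  maximum error ``x``, the region holds between n - x/2 and n + x
  residues (lower bound rounded outward, never below 0).

Where density is completely missing the trace breaks into separate
``TraceSegment``s; the missing region's length is unconstrained, so a
trace with two or more segments has no upper length bound.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import TraceValidationError


@dataclass(frozen=True)
class Observed:
    """One residue with good side-chain density, reduced to a size class."""

    size: int

    def __post_init__(self):
        if not (isinstance(self.size, int) and 0 <= self.size <= 6):
            raise TraceValidationError(f"observed size must be an integer in [0, 6], got {self.size!r}")


@dataclass(frozen=True)
class Ambiguous:
    """A reliable C-alpha whose side chain could be any amino acid."""


@dataclass(frozen=True)
class GapRegion:
    """A connected stretch with only an estimated residue count.

    Either built from an estimate ``(n_est, x_err)``, giving bounds
    [max(0, ceil(n - x/2)), n + x], or from explicit bounds (the form
    produced when combining copies, whose intersected bounds need not be
    representable as any (n, x) pair).
    """

    n_est: int | None = None
    x_err: int | None = None
    min_len: int | None = None
    max_len: int | None = None

    def __post_init__(self):
        if self.n_est is not None:
            if not (isinstance(self.n_est, int) and self.n_est >= 1):
                raise TraceValidationError(f"gap n_est must be a positive integer, got {self.n_est!r}")
            if not (isinstance(self.x_err, int) and self.x_err >= 0):
                raise TraceValidationError(f"gap x_err must be a non-negative integer, got {self.x_err!r}")
            # ceil(n - x/2) == n - floor(x/2) for integer n, x
            lo = max(0, self.n_est - self.x_err // 2)
            hi = self.n_est + self.x_err
            object.__setattr__(self, "min_len", lo)
            object.__setattr__(self, "max_len", hi)
        else:
            if self.min_len is None or self.max_len is None:
                raise TraceValidationError("gap needs either (n_est, x_err) or explicit (min_len, max_len)")
            if not (isinstance(self.min_len, int) and self.min_len >= 0):
                raise TraceValidationError(f"gap min_len must be a non-negative integer, got {self.min_len!r}")
            if not (isinstance(self.max_len, int) and self.max_len >= self.min_len):
                raise TraceValidationError(
                    f"gap max_len must be an integer >= min_len, got {self.max_len!r} < {self.min_len!r}"
                )

    @property
    def bounds(self) -> tuple[int, int]:
        return (self.min_len, self.max_len)


TraceElement = Observed | Ambiguous | GapRegion


@dataclass(frozen=True)
class LengthBounds:
    """Admissible total residue count; ``max_len=None`` means unbounded."""

    min_len: int
    max_len: int | None

    def __post_init__(self):
        if self.max_len is not None and self.max_len < self.min_len:
            raise TraceValidationError(f"length bounds inverted: {self.min_len} > {self.max_len}")


@dataclass(frozen=True)
class TraceSegment:
    """A maximal stretch of connected density (no missing regions inside)."""

    elements: tuple

    def __post_init__(self):
        object.__setattr__(self, "elements", tuple(self.elements))
        if not self.elements:
            raise TraceValidationError("segment has no elements")
        if not any(isinstance(e, (Observed, Ambiguous)) for e in self.elements):
            raise TraceValidationError("segment must contain at least one observed or ambiguous residue")
        for e in self.elements:
            if not isinstance(e, (Observed, Ambiguous, GapRegion)):
                raise TraceValidationError(f"not a trace element: {e!r}")

    def length_bounds(self) -> LengthBounds:
        lo = hi = 0
        for e in self.elements:
            if isinstance(e, GapRegion):
                lo += e.min_len
                hi += e.max_len
            else:
                lo += 1
                hi += 1
        return LengthBounds(lo, hi)


@dataclass(frozen=True)
class DensityTrace:
    """One traced polypeptide: ordered segments in chain direction.

    ``group_id`` marks copies believed to be the same polypeptide
    (similar main-chain conformations) for evidence combination.
    """

    trace_id: str
    segments: tuple
    group_id: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "segments", tuple(self.segments))
        if not self.trace_id:
            raise TraceValidationError("trace_id must be non-empty")
        if not self.segments:
            raise TraceValidationError(f"trace {self.trace_id!r} has no segments")
        for s in self.segments:
            if not isinstance(s, TraceSegment):
                raise TraceValidationError(f"trace {self.trace_id!r}: not a TraceSegment: {s!r}")

    def n_positions(self) -> int:
        """Count of observed + ambiguous elements (gap estimates excluded)."""
        return sum(
            1 for s in self.segments for e in s.elements if isinstance(e, (Observed, Ambiguous))
        )


def trace_length_bounds(trace: DensityTrace) -> LengthBounds:
    """Admissible total residue count spanned by the trace.

    Within one segment the gap estimates bound the total; across two or
    more segments the missing regions have no stated upper bound, so the
    maximum is unbounded.
    """
    lo = sum(s.length_bounds().min_len for s in trace.segments)
    if len(trace.segments) > 1:
        return LengthBounds(lo, None)
    return LengthBounds(lo, trace.segments[0].length_bounds().max_len)


# ---------------------------------------------------------------------------
# JSON trace-file dialect
#
# Top-level list of {trace_id, group_id?, segments:[{elements:[...]}]};
# elements are {"kind":"obs","size":int} | {"kind":"ambig"} |
# {"kind":"gap","n":int,"x":int} | {"kind":"gap","min":int,"max":int}.
# Coordinates reported in errors are 0-based (trace, segment, element).

FORMAT_VERSION = 1


def _element_from_json(obj, where) -> TraceElement:
    if not isinstance(obj, dict) or "kind" not in obj:
        raise TraceValidationError(f"element must be an object with a 'kind': {obj!r}", where)
    kind = obj["kind"]
    try:
        if kind == "obs":
            return Observed(size=obj["size"])
        if kind == "ambig":
            return Ambiguous()
        if kind == "gap":
            if "n" in obj:
                return GapRegion(n_est=obj["n"], x_err=obj.get("x", 0))
            return GapRegion(min_len=obj["min"], max_len=obj["max"])
    except KeyError as exc:
        raise TraceValidationError(f"gap element missing key {exc}", where) from exc
    except TraceValidationError as exc:
        raise TraceValidationError(str(exc.args[0]).split(" (at ")[0], where) from exc
    raise TraceValidationError(f"unknown element kind {kind!r}", where)


def _element_to_json(e: TraceElement) -> dict:
    if isinstance(e, Observed):
        return {"kind": "obs", "size": e.size}
    if isinstance(e, Ambiguous):
        return {"kind": "ambig"}
    if e.n_est is not None:
        return {"kind": "gap", "n": e.n_est, "x": e.x_err}
    return {"kind": "gap", "min": e.min_len, "max": e.max_len}


def parse_trace(path: str | Path) -> list[DensityTrace]:
    """Read and validate a trace file; errors carry element coordinates."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise TraceValidationError(f"cannot read trace file {path}: {exc}") from exc
    if isinstance(doc, dict):  # headered form written by write_trace
        traces_json = doc.get("traces")
        if traces_json is None:
            raise TraceValidationError(f"{path}: object form must have a 'traces' key")
    elif isinstance(doc, list):
        traces_json = doc
    else:
        raise TraceValidationError(f"{path}: top level must be a list or object")

    traces: list[DensityTrace] = []
    seen_ids: set[str] = set()
    for ti, tj in enumerate(traces_json):
        if not isinstance(tj, dict) or "trace_id" not in tj or "segments" not in tj:
            raise TraceValidationError("trace must be an object with trace_id and segments", (ti,))
        tid = tj["trace_id"]
        if tid in seen_ids:
            raise TraceValidationError(f"duplicate trace_id {tid!r}", (ti,))
        seen_ids.add(tid)
        segments = []
        for si, sj in enumerate(tj["segments"]):
            if not isinstance(sj, dict) or "elements" not in sj:
                raise TraceValidationError("segment must be an object with elements", (tid, si))
            elements = [
                _element_from_json(ej, (tid, si, ei)) for ei, ej in enumerate(sj["elements"])
            ]
            try:
                segments.append(TraceSegment(elements))
            except TraceValidationError as exc:
                raise TraceValidationError(str(exc.args[0]).split(" (at ")[0], (tid, si)) from exc
        try:
            traces.append(DensityTrace(trace_id=tid, group_id=tj.get("group_id"), segments=segments))
        except TraceValidationError as exc:
            raise TraceValidationError(str(exc.args[0]).split(" (at ")[0], (ti,)) from exc
    return traces


def write_trace(traces: list[DensityTrace], path: str | Path, metadata: dict | None = None) -> None:
    """Write traces so that :func:`parse_trace` round-trips them exactly."""
    doc = {
        "format": "densitrace",
        "version": FORMAT_VERSION,
        **({"metadata": metadata} if metadata else {}),
        "traces": [
            {
                "trace_id": t.trace_id,
                **({"group_id": t.group_id} if t.group_id is not None else {}),
                "segments": [
                    {"elements": [_element_to_json(e) for e in s.elements]} for s in t.segments
                ],
            }
            for t in traces
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, ensure_ascii=False) + "\n")
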