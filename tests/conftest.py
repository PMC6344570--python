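import numpy as np
import pytest

from densitrace.sizecode import ScoreTable, SizeTable
from densitrace.trace import Ambiguous, DensityTrace, GapRegion, Observed, TraceSegment


@pytest.fixture(scope="session")
def size_table():
    return SizeTable()


@pytest.fixture(scope="session")
def score_table():
    return ScoreTable()


def make_trace(*segments, trace_id="t", group_id=None):
    """Terse trace builder: each segment is a list whose items are an int
    (observed size), None (ambiguous) or a (n, x) tuple (gap region)."""
    segs = []
    for elements in segments:
        out = []
        for e in elements:
            if e is None:
                out.append(Ambiguous())
            elif isinstance(e, tuple):
                out.append(GapRegion(n_est=e[0], x_err=e[1]))
            else:
                out.append(Observed(e))
        segs.append(TraceSegment(out))
    return DensityTrace(trace_id=trace_id, group_id=group_id, segments=segs)


def random_trace(rng: np.random.Generator, max_positions=8, max_segments=2, p_gap=0.2):
    """Random small trace for randomized oracle-equivalence suites."""
    n_segments = int(rng.integers(1, max_segments + 1))
    budget = int(rng.integers(n_segments, max_positions + 1))
    segments = []
    for si in range(n_segments):
        take = max(1, budget // (n_segments - si))
        budget -= take
        elements = []
        placed_position = False
        for _ in range(take):
            r = rng.random()
            if r < p_gap:
                n = int(rng.integers(1, 4))
                x = int(rng.integers(0, 3))
                elements.append((n, x))
            elif r < p_gap + 0.2:
                elements.append(None)
                placed_position = True
            else:
                elements.append(int(rng.integers(0, 7)))
                placed_position = True
        if not placed_position:
            elements.append(int(rng.integers(0, 7)))
        segments.append(elements)
    return make_trace(*segments, trace_id=f"rnd{rng.integers(1 << 30)}")


def random_sequence(rng: np.random.Generator, length: int, p_wildcard=0.0) -> str:
    from densitrace.sizecode import STANDARD_AA

    letters = []
    for _ in range(length):
        if rng.random() < p_wildcard:
            letters.append("X")
        else:
            letters.append(STANDARD_AA[int(rng.integers(20))])
    return "".join(letters)
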