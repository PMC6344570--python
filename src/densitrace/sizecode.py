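"""Side-chain size-class alphabet, amino-acid mapping and pair scoring.

Residues seen in a cryo-EM map are summarised by an integer size class
0-6 (0 = glycine, no side chain; 6 = the bulkiest side chains).  Candidate
sequences are reduced to the same alphabet, and each aligned
(observed, candidate) pair is scored from a 7x7 table.  An observation
that is *larger* than the candidate residue by ``exclusion_delta`` (=2)
or more is physically impossible (density cannot exceed the side chain
that produced it) and excludes the whole trial alignment.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError

N_CLASSES = 7

#: The 20 standard one-letter amino-acid codes.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Letters accepted in input sequences but carrying no size information
#: (ambiguity codes and rare residues).  They encode to the wildcard.
WILDCARD_AA = frozenset("XBZJUO")

#: Default amino-acid -> size-class map, binned by side-chain heavy-atom
#: count so the classes are monotone in physical bulk and span 0-6.
DEFAULT_SIZE_MAP: dict[str, int] = {
    "G": 0,
    "A": 1,
    "S": 2, "C": 2,
    "P": 3, "T": 3, "V": 3,
    "D": 4, "N": 4, "I": 4, "L": 4, "M": 4,
    "E": 5, "Q": 5, "K": 5, "H": 5,
    "R": 6, "F": 6, "Y": 6, "W": 6,
}

#: Sentinel for a wildcard (uninformative) position in an encoded sequence.
WILDCARD = None

#: Marker returned by :func:`score_pair` when the pair violates the
#: exclusion rule (observed exceeds candidate by >= exclusion_delta).
EXCLUDED = "excluded"

#: Marker returned by :func:`score_pair` for a wildcard candidate:
#: the pair contributes to neither numerator nor denominator of the mean.
NEUTRAL = "neutral"


def _default_score_matrix() -> np.ndarray:
    """Asymmetric default score table.

    Exact match scores 1.  A candidate one class bigger than observed
    scores 0.5 and two or more bigger scores 0.25 (flexible side chains
    are often partially disordered, so density under-represents them).
    An observation one class bigger than the candidate scores 0.5;
    two or more bigger is excluded, not scored.
    """
    m = np.zeros((N_CLASSES, N_CLASSES))
    for obs in range(N_CLASSES):
        for cand in range(N_CLASSES):
            d = cand - obs
            if d == 0:
                m[obs, cand] = 1.0
            elif d == 1:
                m[obs, cand] = 0.5
            elif d >= 2:
                m[obs, cand] = 0.25
            elif d == -1:
                m[obs, cand] = 0.5
            # d <= -2: excluded by rule; value never used
    return m


@dataclass(frozen=True)
class SizeTable:
    """Amino acid -> size class 0-6, with a wildcard policy for X/B/Z/J/U/O."""

    mapping: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_SIZE_MAP))

    def __post_init__(self):
        missing = sorted(set(STANDARD_AA) - set(self.mapping))
        if missing:
            raise ConfigError(
                f"size table is missing standard residue(s): {', '.join(missing)}"
            )
        for aa, cls in self.mapping.items():
            if not (isinstance(cls, int) and 0 <= cls <= 6):
                raise ConfigError(f"size class for {aa!r} must be an integer in [0, 6], got {cls!r}")
        values = set(self.mapping.values())
        if 0 not in values or 6 not in values:
            raise ConfigError("size table must use the full dynamic range (some residue at 0 and at 6)")

    def __getitem__(self, aa: str) -> int | None:
        """Size class of ``aa``; WILDCARD for ambiguity codes."""
        aa = aa.upper()
        if aa in self.mapping:
            return self.mapping[aa]
        if aa in WILDCARD_AA:
            return WILDCARD
        raise ConfigError(f"{aa!r} is not an IUPAC amino-acid code")


@dataclass(frozen=True)
class ScoreTable:
    """7x7 per-pair score matrix plus the one-sided exclusion threshold.

    ``score[observed, candidate]`` in [0, 1]; diagonal is 1 (exact match
    is maximal).  Pairs with observed - candidate >= ``exclusion_delta``
    are excluded rather than scored, regardless of the matrix contents.
    """

    score: np.ndarray = field(default_factory=_default_score_matrix)
    exclusion_delta: int = 2

    def __post_init__(self):
        s = np.asarray(self.score, dtype=float)
        if s.shape != (N_CLASSES, N_CLASSES):
            raise ConfigError(f"score table must be {N_CLASSES}x{N_CLASSES}, got {s.shape}")
        if np.any(s < 0) or np.any(s > 1):
            raise ConfigError("score table entries must lie in [0, 1]")
        if not np.all(np.diag(s) == 1.0):
            bad = int(np.argmax(np.diag(s) != 1.0))
            raise ConfigError(f"score[{bad}][{bad}] must be 1 (exact match is maximal)")
        if not (isinstance(self.exclusion_delta, int) and self.exclusion_delta >= 1):
            raise ConfigError("exclusion_delta must be a positive integer")
        object.__setattr__(self, "score", s)

    def min_score(self) -> float:
        """Smallest score reachable by a non-excluded pair."""
        vals = [
            self.score[o, c]
            for o in range(N_CLASSES)
            for c in range(N_CLASSES)
            if o - c < self.exclusion_delta
        ]
        return float(min(vals))


@dataclass(frozen=True)
class EncodedSequence:
    """A sequence reduced to size classes; wildcards are ``None``."""

    id: str
    classes: tuple

    def __len__(self) -> int:
        return len(self.classes)


def encode_sequence(seq: str, table: SizeTable | None = None, seq_id: str = "") -> EncodedSequence:
    """Reduce an amino-acid string to size classes 0-6.

    Non-standard IUPAC letters (X/B/Z/J/U/O) become wildcards that match
    any observation without contributing to alignment scores.
    """
    if table is None:
        table = SizeTable()
    if not seq:
        raise ConfigError("cannot encode an empty sequence")
    return EncodedSequence(id=seq_id, classes=tuple(table[aa] for aa in seq))


def score_pair(observed: int, candidate: int | None, table: ScoreTable | None = None):
    """Score one aligned (observed, candidate) size-class pair.

    Returns the table score, ``EXCLUDED`` if the observation exceeds the
    candidate by ``exclusion_delta`` or more, or ``NEUTRAL`` for a
    wildcard candidate (no contribution to the mean).
    """
    if table is None:
        table = ScoreTable()
    if not (isinstance(observed, int) and 0 <= observed <= 6):
        raise ValueError(f"observed size class must be an integer in [0, 6], got {observed!r}")
    if candidate is WILDCARD:
        return NEUTRAL
    if not (isinstance(candidate, int) and 0 <= candidate <= 6):
        raise ValueError(f"candidate size class must be an integer in [0, 6] or wildcard, got {candidate!r}")
    if observed - candidate >= table.exclusion_delta:
        return EXCLUDED
    return float(table.score[observed, candidate])


# ---------------------------------------------------------------------------
# configuration files

def load_config(path: str | Path | None = None) -> tuple[SizeTable, ScoreTable]:
    """Load (SizeTable, ScoreTable) from a YAML/JSON config file.

    Recognised keys: ``size_table`` (one-letter code -> int),
    ``score_table`` (7x7 row-major list, rows = observed class) and
    ``exclusion_delta``.  Absent keys fall back to the documented
    defaults; ``path=None`` returns the defaults outright.
    """
    if path is None:
        return SizeTable(), ScoreTable()
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config {path} must be a mapping, got {type(data).__name__}")
    unknown = set(data) - {"size_table", "score_table", "exclusion_delta"}
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")

    size_map = data.get("size_table")
    size_table = SizeTable() if size_map is None else SizeTable({str(k).upper(): v for k, v in size_map.items()})

    delta = data.get("exclusion_delta", 2)
    matrix = data.get("score_table")
    if matrix is None:
        score_table = ScoreTable(exclusion_delta=delta)
    else:
        score_table = ScoreTable(score=np.asarray(matrix, dtype=float), exclusion_delta=delta)
    return size_table, score_table


def save_config(size_table: SizeTable, score_table: ScoreTable, path: str | Path) -> None:
    """Write a config file that :func:`load_config` reproduces exactly."""
    doc = {
        "size_table": {aa: int(c) for aa, c in sorted(size_table.mapping.items())},
        "score_table": [[float(x) for x in row] for row in score_table.score],
        "exclusion_delta": int(score_table.exclusion_delta),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def config_digest(size_table: SizeTable, score_table: ScoreTable) -> str:
    """Short stable hash of the active configuration, for report headers."""
    doc = {
        "size_table": {aa: int(c) for aa, c in sorted(size_table.mapping.items())},
        "score_table": [[float(x) for x in row] for row in score_table.score],
        "exclusion_delta": int(score_table.exclusion_delta),
    }
    return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:12]
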