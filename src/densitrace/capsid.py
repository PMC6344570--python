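"""Icosahedral capsid bookkeeping for large dsDNA viruses.

Copy-number census over the 60 icosahedral asymmetric units (AU),
Caspar-Klug triangulation arithmetic, symmetron capsomer counts,
tape-measure protein length scaling, and N-glycosylation sequon
scanning.  Defaults describe the PBCV-1 capsid: 28 pseudo-hexameric
capsomers per AU (three major-capsid-protein chains each), one penton
chain per AU, and 13 minor capsid proteins totalling 30 chains per AU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import DensitraceError

N_ASYMMETRIC_UNITS = 60
CHAINS_PER_HEXAMERIC_CAPSOMER = 3

#: Minor-capsid-protein copies per icosahedral asymmetric unit (PBCV-1).
DEFAULT_MINOR_COPIES = {
    "P2": 1, "P3": 3, "P4": 4, "P5": 1, "P6": 1, "P7": 1, "P8": 1,
    "P9": 1, "P10": 2, "P11": 12, "P12": 1, "P13": 1, "P14": 1,
}


@dataclass(frozen=True)
class CensusTable:
    """Per-AU copy numbers of the capsid's building blocks."""

    minor_copies: dict = field(default_factory=lambda: dict(DEFAULT_MINOR_COPIES))
    capsomers_per_au: int = 28
    penton_chains_per_au: int = 1

    def __post_init__(self):
        for pid, c in self.minor_copies.items():
            if not (isinstance(c, int) and c >= 1):
                raise DensitraceError(f"copy number for {pid!r} must be a positive integer, got {c!r}")
        if self.capsomers_per_au < 0 or self.penton_chains_per_au < 0:
            raise DensitraceError("per-AU counts must be >= 0")


@dataclass(frozen=True)
class CensusTotals:
    mcp_chains: int
    penton_chains: int
    minor_chains: dict
    minor_total: int
    grand_total: int


def capsid_census(table: CensusTable | None = None) -> CensusTotals:
    """Whole-virion chain counts from per-AU copy numbers (x60).

    With the default table: 5040 major-capsid-protein chains
    (28 capsomers x 3 chains x 60), 60 penton chains, 1800 minor
    capsid protein chains, 6900 polypeptides in all.
    """
    table = table or CensusTable()
    mcp = N_ASYMMETRIC_UNITS * table.capsomers_per_au * CHAINS_PER_HEXAMERIC_CAPSOMER
    penton = N_ASYMMETRIC_UNITS * table.penton_chains_per_au
    minors = {pid: N_ASYMMETRIC_UNITS * c for pid, c in sorted(table.minor_copies.items())}
    minor_total = sum(minors.values())
    return CensusTotals(
        mcp_chains=mcp,
        penton_chains=penton,
        minor_chains=minors,
        minor_total=minor_total,
        grand_total=mcp + penton + minor_total,
    )


def t_number_from_chains(
    n_mcp_chains: int,
    n_penton_chains: int,
    rolls_per_mcp: int = 2,
    rolls_per_penton: int = 1,
) -> int:
    """Triangulation number from chain stoichiometry.

    Every jelly-roll domain occupies one lattice position; a capsid with
    triangulation number T has 60T of them.  The PBCV-1 major capsid
    protein carries two sequential jelly rolls per chain, the penton
    protein one, so (2 x 5040 + 1 x 60) / 60 = 169.
    """
    total = rolls_per_mcp * n_mcp_chains + rolls_per_penton * n_penton_chains
    if total <= 0:
        raise DensitraceError("no jelly-roll domains: empty capsid")
    if total % N_ASYMMETRIC_UNITS != 0:
        raise DensitraceError(
            f"{total} jelly-roll domains is not a multiple of 60: inconsistent icosahedral lattice"
        )
    return total // N_ASYMMETRIC_UNITS


@dataclass(frozen=True)
class HKPair:
    h: int
    k: int

    @property
    def skew(self) -> bool:
        """True for h != k != 0 lattices, which come in laevo/dextro mirror forms."""
        return self.h != self.k and self.k != 0

    @property
    def t(self) -> int:
        return self.h * self.h + self.h * self.k + self.k * self.k


def hk_candidates(T: int) -> list:
    """All Caspar-Klug lattice vectors (h, k), h >= k >= 0, with h^2+hk+k^2 = T.

    Skew solutions (h != k, k != 0) exist in mirror-image laevo/dextro
    forms; only the canonical h >= k representative is returned, with
    ``skew`` flagging the handedness ambiguity.  May be empty (e.g. T=2
    has no representation).
    """
    if T < 1:
        raise DensitraceError("T must be >= 1")
    out = []
    for h in range(math.isqrt(T), 0, -1):
        for k in range(0, h + 1):
            if h * h + h * k + k * k == T:
                out.append(HKPair(h, k))
    return sorted(out, key=lambda p: (p.h, p.k))


def triangular_count(edge: int) -> int:
    """Capsomers in a triangular array with ``edge`` capsomers per edge."""
    if edge < 1:
        raise DensitraceError("edge must be >= 1")
    return edge * (edge + 1) // 2


@dataclass(frozen=True)
class SymmetronSpec:
    """Per-AU capsomer split between the two symmetron types (PBCV-1: 22 + 6)."""

    capsomers_per_au_trisymmetron: int = 22
    capsomers_per_au_pentasymmetron: int = 6
    pentamer_per_pentasymmetron: int = 1

    def __post_init__(self):
        if min(
            self.capsomers_per_au_trisymmetron,
            self.capsomers_per_au_pentasymmetron,
            self.pentamer_per_pentasymmetron,
        ) < 0:
            raise DensitraceError("symmetron counts must be >= 0")


def symmetron_capsomer_count(spec: SymmetronSpec | None = None) -> tuple:
    """(capsomers per trisymmetron, capsomers per pentasymmetron).

    A trisymmetron sits on a 3-fold axis and collects 3 AU shares; a
    pentasymmetron sits on a 5-fold axis, collects 5 AU shares plus its
    central pentamer.  PBCV-1: (3 x 22, 5 x 6 + 1) = (66, 31).
    """
    spec = spec or SymmetronSpec()
    tri = 3 * spec.capsomers_per_au_trisymmetron
    penta = 5 * spec.capsomers_per_au_pentasymmetron + spec.pentamer_per_pentasymmetron
    return (tri, penta)


# ---------------------------------------------------------------------------
# tape-measure scaling

@dataclass(frozen=True)
class TapeMeasureModel:
    """Linear size scaling anchored on the PBCV-1 tape-measure protein.

    The capsid-contacting span of the tape-measure protein P2 (residues
    94-566, 473 aa) runs along the face of a ~190 nm capsid in a fully
    extended conformation, so homolog length scales linearly with
    capsid diameter.
    """

    ref_span_aa: int = 473
    ref_diameter_nm: float = 190.0
    rolls_per_mcp_chain: int = 2
    rolls_per_penton_chain: int = 1

    def __post_init__(self):
        if self.ref_span_aa <= 0 or self.ref_diameter_nm <= 0:
            raise DensitraceError("reference span and diameter must be positive")


@dataclass(frozen=True)
class TapeMeasureEstimate:
    residues: float
    rounded: int | None


def tape_measure_estimate(
    model: TapeMeasureModel | None = None,
    target_diameter_nm: float = 190.0,
    rounding: int | None = 50,
) -> TapeMeasureEstimate:
    """Predicted tape-measure protein length for a capsid of given diameter.

    ``rounding`` rounds to the nearest multiple (default 50, the
    granularity at which such predictions are meaningfully reported);
    the unrounded value is always returned alongside.
    """
    model = model or TapeMeasureModel()
    if target_diameter_nm <= 0:
        raise DensitraceError("target diameter must be positive")
    est = model.ref_span_aa * target_diameter_nm / model.ref_diameter_nm
    rounded = None if rounding is None else int(round(est / rounding)) * rounding
    return TapeMeasureEstimate(residues=est, rounded=rounded)


def residue_range_length(start: int, end: int) -> int:
    """Length of a 1-based inclusive residue range (94-566 -> 473)."""
    if end < start:
        raise DensitraceError(f"inverted residue range {start}-{end}")
    return end - start + 1


# ---------------------------------------------------------------------------
# N-glycosylation sequons

@dataclass(frozen=True)
class SequonSite:
    """One Asn position: canonical iff T/S two residues downstream
    (N-X-(T/S)); ``small_preceded`` iff Ala or Gly immediately before."""

    position: int  # 1-based position of the N
    canonical: bool
    small_preceded: bool
    context: str  # 5-residue window N-1 .. N+3, '-' padded


def sequon_scan(seq: str) -> list:
    """Scan a sequence for potential N-glycosylation sites (every Asn)."""
    seq = seq.upper()
    sites = []
    for i, aa in enumerate(seq):
        if aa != "N":
            continue
        canonical = i + 2 < len(seq) and seq[i + 2] in "TS"
        small = i >= 1 and seq[i - 1] in "AG"
        lo, hi = i - 1, i + 4
        context = "".join(
            seq[j] if 0 <= j < len(seq) else "-" for j in range(lo, hi)
        )
        sites.append(SequonSite(position=i + 1, canonical=canonical, small_preceded=small, context=context))
    return sites
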