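# Methods

## Model

A *density trace* is the machine-readable form of what a model builder
reads off a cryo-EM map for one polypeptide: an ordered list of
elements, grouped into segments. Observed elements carry a side-chain
size class `s ∈ {0..6}`; ambiguous elements carry no size information
but fix one Cα; a gap region with estimate `(n, x)` stands for between
`max(0, ⌈n − x/2⌉)` and `n + x` residues (the lower bound is rounded
*outward* — `n − ⌊x/2⌋` for integers — so no length the interval admits
is ever excluded). Completely missing density is not an element: it is
the boundary between segments, and its length is unconstrained below by
0 and unbounded above.

Candidate sequences are reduced to the same alphabet with a configurable
amino-acid → class map. The default bins residues by side-chain
heavy-atom count:

| class | residues |
|---|---|
| 0 | G |
| 1 | A |
| 2 | S, C |
| 3 | P, T, V |
| 4 | D, N, I, L, M |
| 5 | E, Q, K, H |
| 6 | R, F, Y, W |

This default is a stand-in chosen to be monotone in physical bulk and to
span the full 0–6 range; any other mapping (and score table) can be
supplied verbatim through the YAML/JSON config (`size_table`,
`score_table`, `exclusion_delta`). Ambiguity codes (X/B/Z/J/U/O) on the
sequence side become wildcards: compatible with any observation,
contributing nothing to scores.

## Alignment and scoring

A placement assigns each segment a start on the candidate
(order-preserving, non-overlapping, spacing ≥ 0 — segments may abut)
and each gap region a length within its bounds. Observed and ambiguous
elements consume one candidate residue each. The placement score is the
mean of the per-pair table scores over *scored* pairs only: ambiguous
elements and wildcard candidate positions consume a residue but enter
neither numerator nor denominator — averaging over uninformative
positions would dilute real evidence.

Default score table (rows = observed, asymmetric by design): 1.0 at an
exact match; 0.5 when the candidate is one class bigger; 0.25 when two
or more bigger (flexible side chains are often partially disordered, so
density under-represents them); 0.5 when the observation is one class
bigger; and an observation **two or more classes bigger than the
candidate excludes the placement** — density cannot exceed the side
chain that produced it. Scores are constrained to [0, 1] so the mean and
the 0.1 decision margin live on a fixed scale.

A candidate as a whole is excluded as `candidate_too_short` when its
length is below the trace's minimum length, `size_violation` when no
placement avoids the exclusion rule, or `no_scored_positions` when
admissible placements exist but none has a single scoreable pair (a mean
over zero terms is undefined). The trace may map to any interior window
of the candidate: both termini may be unmodeled, as is routine for
capsid proteins whose termini are disordered.

The search is an exact enumeration, not a heuristic: per segment and
gap-length tuple, all start offsets are scored in one vectorised pass
(numpy), and segment placements are composed left-to-right. Its
complexity is the product of the per-gap ranges times the offset count —
acceptable for traces of tens to hundreds of residues with a few gaps;
a configurable placement budget (default 10⁷) triggers a warning, never
an approximation. Insertions or deletions inside observed runs are not
modelled: only gap regions and missing regions absorb length
uncertainty. Ties between equal-scoring placements resolve
deterministically to the smallest start offset, then the
lexicographically smallest gap-length tuple, then the smallest segment
offsets. An independently written scalar brute-force implementation
(`align_trace_oracle`, guarded to ≤ 20 trace positions and ≤ 60-residue
candidates) serves as the reference in tests; with the default table all
scores are dyadic rationals, so both routes produce bit-identical means
and tie-breaking is exact.

## Combination and decision

Copies of one polypeptide traced at several sites may be combined when
they share a `group_id` and an identical element skeleton (gap/position
pattern per segment) — the operational proxy for "similar main-chain
conformation"; no structural superposition is attempted, since
coordinates are not among this package's inputs. When per-copy rankings
are supplied, all copies must agree on their best-matching candidate;
passing `rankings=None` skips that check for the case of many short
copies grouped purely by conformation and capsomer contacts, whose
individual rankings are uninformative. Per position, an observation
beats ambiguity; conflicting observed sizes combine by maximum (the
larger class reflects the fullest density) with a logged warning rather
than a refusal. Gap bounds intersect; a combined gap is stored with
explicit bounds because an intersection need not be representable as any
`(n, x)` estimate. Disjoint bounds refuse the combination.

The decision rule has two situations: a sole surviving candidate is
assigned; among several survivors the top is assigned only when its best
mean score exceeds the runner-up's by *strictly more than* the margin
(default 0.1). Ambiguous outcomes list every candidate within the margin
of the top — the most informative superset — and are flagged as needing
an external secondary-structure check, which is how runner-ups would be
rejected in practice; secondary-structure prediction itself is outside
this package's scope. Whether the margin is applied to per-copy or
combined-trace scores is the caller's choice: the rule operates on
whatever evidence level was screened.

## Synthetic data

The generator produces decoy proteomes (uniform residue usage, lengths
uniform in a range, default 20 sequences of 100–400 aa) and simulates
traces from a chosen span. Defaults for the noise model are the
conditions the recovery benchmark runs under: 10% ambiguous positions,
5% under-classing, one gap region per 50 residues (`gap_rate=2` per 100)
replacing 3–6 true residues with `x = 2`, and no missing-region breaks.
Under-classing only ever *depresses* a size by one class (floored at 0):
real disorder truncates side-chain density, it does not inflate it, and
this keeps simulated traces consistent with the one-sided exclusion
rule. Gap estimates are perturbed by a rounded zero-mean Gaussian but
clamped so the true length always stays within the admissible bounds.
The default trace span is 60 residues — the threshold above which traced
chains carry enough side-chain information to be worth searching.

What the generator does **not** emulate: spatially correlated density
quality (noise here is i.i.d. per position), systematic size
misestimation by the human builder beyond one class, non-uniform residue
composition, homologous or repetitive decoys, and conformation-dependent
disorder. Passing recovery benchmarks therefore shows the search and
decision machinery is correct and well-calibrated under the stated noise
— not that real maps of arbitrary quality will yield unambiguous
assignments. The benchmark (100 seeded runs, fresh 20-protein proteome
per run, spans of 60 residues) is fully determined by a master seed via
spawned child seeds.

## Capsid arithmetic

All whole-virion counts are per-asymmetric-unit copy numbers × 60. The
default census encodes the PBCV-1-type capsid: 28 pseudo-hexameric
capsomers per AU × 3 MCP chains = 5040 MCP chains; one penton chain per
AU = 60; minor proteins 9×1 + 3 + 4 + 2 + 12 = 30 per AU = 1800; 6900
polypeptides in all. The triangulation number counts jelly-roll domains
(two per MCP chain, one per penton chain) divided by 60; a
non-divisible total is rejected as an inconsistent lattice. `hk_candidates`
enumerates all `h ≥ k ≥ 0` with `h² + hk + k² = T` exhaustively up to
`⌊√T⌋` and flags skew (`h ≠ k, k ≠ 0`) lattices, which occur in
laevo/dextro mirror forms. Tape-measure scaling is linear in diameter
from the 473-aa / 190-nm reference; predictions are reported rounded to
the nearest 50 residues (the honest granularity of such an estimate)
with the unrounded value always returned alongside. Residue ranges are
1-based inclusive throughout. The sequon scanner reports every Asn,
marking the canonical N-X-(T/S) pattern with X unrestricted (the common
X ≠ P refinement is deliberately not applied) and whether an Ala/Gly
precedes the site.

## Numerical and interface choices

* Trace files are JSON (schema in `trace.py`): a top-level list of
  `{trace_id, group_id?, segments: [{elements: [...]}]}` with elements
  `{"kind":"obs","size"}`, `{"kind":"ambig"}`, `{"kind":"gap","n","x"}`
  or `{"kind":"gap","min","max"}`. Coordinates in error messages are
  0-based within a segment.
* Reports are TSV with a version + config-hash header; reruns with the
  same inputs are byte-identical.
* Rankings sort survivors by mean score descending with candidate id as
  the deterministic tiebreak; exclusions follow, sorted by id.
* All randomness flows through numpy Generators seeded explicitly;
  nothing reads global RNG state.

## Known limitations

The aligner's exhaustive search can become expensive for traces with
many wide gap regions (exponential in the gap count); the placement
budget warns but the answer remains exact. Size classes are the only
evidence used — charge, aromaticity, rotamer shape and local chemical
environment are not modelled, which is precisely why ambiguous calls
defer to external secondary-structure checks. Traces are assumed to be
in the correct chain direction; reverse-direction matching must be done
by the caller reversing the trace.
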