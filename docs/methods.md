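# Methods

## Model and formalism

A biochemical network is an integer stoichiometric matrix `S` (m components ×
n reactions) with per-reaction roles: *internal*, *exchange-input* (source)
or *exchange-output* (sink). Consumption is −1/−k, production +1/+k; input
exchanges carry +1, output exchanges −1. Under the steady-state hypothesis
the feasible fluxes form the cone `C = {v ≥ 0 : S v = 0}` once every
reversible internal reaction is split into a forward/backward pair of
irreversible columns (`split_reversible`). The extreme pathways are the
extreme rays of `C`; for an all-irreversible network these are exactly the
support-minimal nonzero solutions (elementary flux modes), which is the
characterization both our algorithms use.

Regulatory models are qualitative instances of the same formalism. Each
component contributes two rows — a presence state and an absence state, with
no built-in constraint linking them; mutual exclusivity of a stimulus's two
states is a property of *environments*, not of single reactions, and is
enforced by the pathway-level feasibility filter described below. Each
Boolean rule is expanded to disjunctive normal form; each conjunction becomes
a reaction consuming its literal state rows and producing the target's
presence row. The converse — the DNF of the negation of the OR of all the
target's rules — produces the absence row, so "gene off" is an explicitly
producible state rather than a default. Every non-stimulus state receives one
output exchange. Contradictory conjunctions (`x AND NOT x`) are compiled,
not pruned: they can never carry pathway flux, and surfacing them in the
unused-reaction report is how rule-curation errors are detected.

## Enumeration

`enumerate_extreme_pathways` is the classical tableau / double-description
algorithm: start from the identity tableau (one candidate per reaction),
process one matrix row at a time, keep candidates with zero residual, combine
every positive/negative residual pair with positive integer weights, and
prune any combination whose support strictly contains another tableau row's
support. Everything is exact Python-integer arithmetic; candidate vectors are
gcd-normalized at every step, so no overflow or floating-point tolerance
questions arise. Rows are processed in ascending #positive×#negative order (a
standard fill-reduction heuristic); the result is provably order-independent
and the test suite checks natural, reversed and heuristic orders agree.
Output order is deterministic: lexicographic by support, then by vector.

Forward/backward two-cycles created by reversible splitting are artifacts
and are removed before the result is returned. Classification keeps only
pathways with nonzero exchange flux; a pathway touching no exchange column is
an internal cycle (class III), thermodynamically infeasible, and excluded
with a count in the log. We do not subdivide exchange-active pathways
further (the classical class I/II distinction needs currency-metabolite
annotations these models do not carry), so `expa_class` takes values `I` and
`III` only.

`brute_force_elementary_modes` is the deliberately independent oracle used
throughout the tests: enumerate all reaction subsets (guarded at 14
reactions), discard any subset where some row has nonzero entries of only one
sign, and keep a subset iff the kernel of `S` restricted to it is
one-dimensional with a strictly positive generator — computed by exact
`fractions.Fraction` Gaussian elimination. The two implementations share the
normalization helpers and nothing else.

`decompose_flux` answers whether a given steady-state vector lies in the
cone spanned by a pathway set. Membership in the *contract* (`S v = 0`,
`v ≥ 0`) is checked exactly with rationals; the nonnegative witness `α` is
then found by linear programming (HiGHS) with a residual acceptance of
`1e-7` relative to the vector's magnitude. The LP is a feasibility check, so
float arithmetic is adequate; the exact contract check prevents silently
"decomposing" a non-steady-state vector.

## The single-matrix regulatory pipeline

`R*_new = [R | E_new]` appends two unit input columns per stimulus: column e
feeds the presence row of stimulus e, column n+e its absence row. One
enumeration of `R*_new` covers all 2ⁿ environments, at the cost of spurious
rays that draw both inputs of one stimulus. `filter_conflicting_inputs`
removes exactly the vectors with `v_presence · v_absence ≠ 0` for some
stimulus; the removed and retained parts partition the input, and both are
reported. Filtering runs after class III removal; the two filters commute
(conflict status and exchange activity are independent coordinates of a
fixed vector), the order is fixed only to make logs reproducible.

The validation oracle enumerates each environment's matrix `R*_i = [R | E_i]`
(one input column per stimulus, aimed at the presence or absence row as the
environment dictates), removes class III, then *normalizes* each pathway by
expanding its n input entries to 2n slots — flux moves to the presence slot
if the stimulus is present in that environment, to the absence slot if
absent, zeros stay zero — and unions the results with set semantics.
Input fluxes are not rescaled during normalization: they carry the integer
demand of the downstream conjunctions, which gcd normalization preserves
consistently on both routes. `verify_equivalence` asserts the filtered
direct set equals the union; `transform_ri_hat` exposes the structural half
of the argument (zeroing the environment-incompatible input columns of
`R*_new`, with those fluxes pinned to zero, yields a sub-network whose
pathway set is contained in `R*_new`'s).

Column layout: internal reactions, then output exchanges, then the input
blocks. Putting inputs last lets per-environment pathways expand in place;
all operations nevertheless resolve columns through role metadata, never
fixed offsets. The environment sweep is guarded at n ≤ 12 stimuli (4096
enumerations) — beyond that the sweep stops being a desk-scale oracle and
the direct method is the point of the package.

## Metrics

All metrics derive from the binary participation matrix (pathway × reaction).

* **P/R** — pathway count over total reaction count (all columns, exchanges
  included).
* **Length** — support size, exchanges included; the shortest possible
  regulatory pathway is therefore 3 (input + rule + export). Summary tables
  round the mean half-up to an integer; L/R is reported as a percentage,
  `100·mean/#reactions`. The histogram mode breaks ties toward the smaller
  length.
* **RPR** — percentage of pathways using a reaction; descending sort with
  ties broken by reaction id (stable), internal and exchange reactions
  rankable separately.
* **Unused reactions** — RPR = 0, tagged type II when compiled from a
  contradictory conjunction (or an exchange whose state is produced only by
  contradictory reactions), type I otherwise (dead-end wiring: a required
  producer or consumer is missing).
* **CoSets** — maximal groups (≥ 2) of reactions with identical nonzero
  participation signatures. A CoSet is *trivial* when the graph over its
  members — edge iff two reactions share a species with nonzero coefficient,
  taken from the post-split network, exchanges participating like any other
  reaction — is connected; the adjacent ratio is the percentage of trivial
  CoSets (undefined, reported as None, when there are no CoSets).
* **Crosstalk** — every pathway pair classified by the relation of its
  active input-reaction sets and output-reaction sets: identical / overlapped
  / disjoint, a 3×3 matrix of counts and percentages. Before classification
  the top `⌈f·#exchange reactions⌉` exchange reactions by RPR are removed
  from all sets (default f = 0.20): ubiquitous currency-like exchanges
  otherwise make nearly every pair "overlapped". The fraction is a parameter
  (0 disables the exclusion) because the cutoff convention is genuinely
  ambiguous in the field; we exclude top exchange *reactions*, not pathway
  pairs. Empty-set conventions keep the classification total: empty vs empty
  counts as identical, empty vs nonempty as disjoint. For regulatory models
  both presence and absence inputs count as inputs.

## Synthetic data

`toy_trn` is the canonical four-stimulus example (P1 ← A AND B; P2 ← C OR D)
whose compiled form has 6 internal reactions, 4 output exchanges and 8 input
columns. `random_trn(GeneratorConfig)` draws layered models — stimuli → TFs →
genes, one rule per non-stimulus component, geometric OR-branching (default
p = 0.3), per-literal negation probability (default 0.3), conjunction arity
≤ 2 — mirroring the flat hierarchy of real transcriptional networks: most
targets are one or two rule steps from the environment. Defaults (4 stimuli,
2 TFs, 2 genes; 6 stimuli/2 TFs/3 genes for the larger validation draws)
keep the 2ⁿ sweep oracle cheap while still producing models with OR-branch
redundancy, negation, and occasional contradictions. `random_network` draws
small integer stoichiometric networks (4–5 species, ≤ 12 columns, mixed-sign
internal columns, unit exchanges) sized for the brute-force oracle.

What the generators do *not* emulate: genome-scale degree distributions,
curated rule depth (real TRN rules nest deeper), quantitative stoichiometry
in regulation, or reversible regulatory logic. Passing tests therefore
demonstrate algorithmic correctness (enumeration, filtering, equivalence,
metric identities) on the class of structures these generators produce, not
biological fidelity of any particular genome-scale reconstruction; published
genome-scale counts are reachable only with the corresponding external model
files.

## Numerical and design choices

* Exact integers everywhere in enumeration; gcd normalization (the minimum
  positive entry need not be 1). No tolerances exist to tune.
* Deduplication key is the normalized integer vector, at every elimination
  step and in the union of the environment sweep.
* Degenerate inputs: empty networks enumerate to empty sets; an empty
  pathway set yields flagged (not crashing) metric reports; zero stimuli
  make `E_new` an empty block and the sweep a single environment.
* `metrics_report` percentages are rounded to 2 decimals only at
  serialization; TSV outputs use tabs, LF endings and deterministic row
  order so reruns are byte-identical.
* Problem sizes in the test-suite and acceptance script (networks ≤ 14
  reactions for oracle comparisons, regulatory models with ≤ 6 stimuli for
  the sweep, 36 networks / 21 models / 100-vector property samples) were
  chosen so the full validation battery completes in seconds while keeping
  every check at or above the sizes where the algorithms' combinatorics are
  actually exercised.

## Known limitations

* The enumerator is a clean tableau implementation without bit-pattern or
  rank-test accelerations; it is meant for models up to a few hundred
  columns, not genome-scale reconstructions.
* Class II pathways are not distinguished from class I (no currency
  annotations).
* `decompose_flux` returns *a* witness, not a canonical one; the witness is
  float-valued.
* SBML import maps boundary reactions to exchange roles by stoichiometric
  sign and rationalizes fractional coefficients per column; models relying
  on fancier SBML semantics (rules, events) are out of scope.
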