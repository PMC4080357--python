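# expanet

Extreme-pathway analysis of constraint-based biochemical networks — with
first-class support for Boolean transcriptional regulatory networks (TRNs).

## The problem

A constraint-based (COBRA) model represents a biochemical network as an
integer stoichiometric matrix **S** (rows = components, columns = reactions).
At steady state, every feasible flux distribution satisfies

```
S v = 0,   v ≥ 0   (after splitting reversible reactions),
```

so the feasible set is a convex polyhedral cone. The **extreme pathways
(ExPas)** are the edges of that cone: the unique minimal set of flux vectors
`p_i` such that every steady state decomposes as `v = Σ αᵢ pᵢ` with `αᵢ ≥ 0`.
For an all-irreversible network they coincide with the elementary flux modes:
the support-minimal steady-state routes. ExPa analysis characterizes what a
network *can do* — its redundancy, route lengths, load-bearing reactions and
pathway interdependence — independent of kinetics.

A TRN is a set of Boolean rules (`Protein1 <- A AND B`) rather than a
metabolic map, but it compiles into the same formalism: each component's
presence and absence become independent matrix rows, each DNF conjunction of
a rule becomes a qualitative reaction, and each non-stimulus state gets an
output exchange. An ExPa of the compiled matrix is then one *transcriptional
state*: which stimuli are present/absent, which rules fire, which products
are expressed.

The classical approach enumerates ExPas once per environment — all 2ⁿ
presence/absence combinations of the n stimuli. `expanet` implements the
single-matrix alternative: append **two** input columns per stimulus (one
feeding its presence row, one its absence row), giving the augmented matrix
`R*_new = [R | E_new]` that covers every environment in one enumeration.
The price is a post-hoc filter: any enumerated pathway that draws both the
presence *and* absence input of the same stimulus (`v_{k+e} · v_{k+n+e} ≠ 0`)
describes an impossible environment and is removed. The package also ships
the per-environment sweep as an independent oracle and a validator that
checks the two routes produce identical normalized pathway sets.

Intended users: systems-biology researchers analyzing small-to-medium
constraint-based models, and method developers who need an exactly-arithmetic,
oracle-validated ExPa enumerator to build on.

## What's inside

| module | contents |
|---|---|
| `expanet.boolexpr` | Boolean rule expressions, parser, DNF conversion (contradictions retained and flagged) |
| `expanet.regulatory` | rule files → compiled qualitative matrix, `E_new`, `R*_new`, per-environment `R*_i` |
| `expanet.cone` | exact-integer tableau enumeration of extreme rays, class III (internal cycle) removal, brute-force subset-scan oracle, flux decomposition |
| `expanet.trn` | the regulatory pipeline: direct enumeration, conflicting-input filter, pathway normalization, environment sweep, equivalence validation |
| `expanet.metrics` | P/R, length statistics, reaction participation (RPR), CoSets + adjacent ratio, crosstalk matrix, unused-reaction report |
| `expanet.synth` | deterministic generators: the worked-example model, seeded random TRNs, small fixture networks |
| `expanet.cli` | thin `expanet` command with `compile`, `enumerate`, `trn-expa`, `metrics`, `validate`, `toy`, `generate` |

All pathway arithmetic is exact (Python integers / fractions); every returned
pathway satisfies `S·p = 0` identically and is gcd-normalized, so pathway
sets from different routes compare as plain sets.

## Worked example

```python
import expanet as ex

model = ex.toy_trn()          # stimuli A–D; P1 <- A AND B; P2 <- C OR D
universe = ex.compute_trn_expa_set(model)
print(universe.summary())
```

prints

```
{'provenance': 'direct', 'raw': 6, 'class3_removed': 0,
 'conflicting_removed': 0, 'feasible': 6}
```

— one enumeration over the 18-column `R*_new` finds all 6 transcriptional
states, e.g. `In_A + In_B + Protein1_1 + Ex_Protein1` (A and B present, the
rule fires, Protein1 is expressed) and `In_NOT_C + In_NOT_D + NOT_Protein2_1
+ Ex_NOT_Protein2` (neither C nor D present, so Protein2 stays off). The
validator confirms the 16-environment sweep finds exactly the same set:

```python
ex.verify_equivalence(model).summary()
# {'equal': True, 'direct_feasible': 6, 'union_feasible': 6,
#  'only_direct': 0, 'only_union': 0}
```

and the metric suite summarizes the set:

```python
report = ex.metrics_report(universe.as_expa_set(), exclude_top_exchange_fraction=0.0)
# pathways: 6, reactions: 18, P/R = 0.333
# length avg 3.33 (min 3, max 4, mode 3)
# CoSets: 6, adjacent ratio 100%
# crosstalk: 86.7% of pairs disjoint-inputs/disjoint-outputs
```

The minimum length 3 is the shortest possible regulatory route — one stimulus
input, one rule, one product export — and the dominant disjoint/disjoint
crosstalk cell reflects how specific the toy's rules are. See `examples/` for
runnable scripts covering each capability.

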