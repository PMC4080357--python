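"""Boolean regulatory models and their compilation to qualitative matrices.

A transcriptional regulatory network (TRN) is a set of Boolean rules mapping
environmental stimuli and transcription factors to target products.  Each
component has two first-class states — presence and absence — which become
independent matrix rows.  Every DNF conjunction of a rule becomes one
qualitative reaction consuming the literal state rows (−1 each) and producing
the target's presence row (+1); the converse of each target's combined rule
produces its absence row.  Non-stimulus states each get one output exchange
reaction, so a steady state can "export" the expression pattern.

Environmental inputs can be attached in two ways:

* one input column per stimulus fixing a single environment (``assemble_ri``,
  the regulatory state matrix R*_i for environment i), or
* two input columns per stimulus — one feeding its presence row, one its
  absence row — covering all environments at once (``assemble_rnew``, the
  augmented matrix R*_new = [R | E_new]).

The second form enumerates every environment's extreme pathways in a single
run; contradictory presence+absence usage is filtered afterwards (see
:mod:`expanet.trn`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .boolexpr import (
    BoolExpr,
    Conjunction,
    Not,
    Or,
    RuleSyntaxError,
    format_expression,
    free_variables,
    parse_expression,
    to_dnf,
)
from .network import ROLE_INPUT, ROLE_INTERNAL, ROLE_OUTPUT, Reaction, StoichiometricNetwork

KIND_STIMULUS = "stimulus"
KIND_INTERNAL = "internal"  # rule target that also appears as a literal elsewhere
KIND_PRODUCT = "product"


@dataclass(frozen=True)
class Component:
    id: str
    kind: str

    @property
    def presence_label(self) -> str:
        return self.id

    @property
    def absence_label(self) -> str:
        return f"NOT_{self.id}"


@dataclass(frozen=True)
class RegulatoryRule:
    target: str
    expression: BoolExpr
    provenance: str = ""


# Environment assignment: stimulus id -> True (present) / False (absent).
EnvironmentAssignment = dict[str, bool]


@dataclass
class RegulatoryModel:
    """Declared stimuli plus Boolean rules; compiles to a qualitative matrix."""

    components: list[Component]
    rules: list[RegulatoryRule]
    compiled: StoichiometricNetwork | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.components]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate component ids")

    @property
    def stimuli(self) -> list[str]:
        return [c.id for c in self.components if c.kind == KIND_STIMULUS]

    @property
    def non_stimulus_components(self) -> list[Component]:
        return [c for c in self.components if c.kind != KIND_STIMULUS]

    @property
    def n_stimuli(self) -> int:
        return len(self.stimuli)

    def component(self, cid: str) -> Component:
        for c in self.components:
            if c.id == cid:
                return c
        raise KeyError(f"no component {cid!r}")

    def validate_environment(self, env: EnvironmentAssignment) -> None:
        missing = set(self.stimuli) - set(env)
        extra = set(env) - set(self.stimuli)
        if missing:
            raise ValueError(f"environment assignment missing stimuli {sorted(missing)}")
        if extra:
            raise ValueError(f"environment assignment has undeclared stimuli {sorted(extra)}")

    def to_rule_text(self) -> str:
        lines = [f"stimuli: {', '.join(self.stimuli)}"]
        lines += [f"{r.target} <- {format_expression(r.expression)}" for r in self.rules]
        return "\n".join(lines) + "\n"


# -- parsing ----------------------------------------------------------------


def parse_rule_text(text: str) -> RegulatoryModel:
    """Parse the rule-file dialect: a ``stimuli:`` header then ``T <- EXPR`` lines."""
    stimuli: list[str] = []
    raw_rules: list[tuple[str, BoolExpr, str, int]] = []
    saw_header = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower().startswith("stimuli:"):
            if saw_header:
                raise RuleSyntaxError("duplicate stimuli header", lineno)
            saw_header = True
            names = [s.strip() for s in line.split(":", 1)[1].split(",") if s.strip()]
            stimuli.extend(names)
            continue
        if "<-" not in line:
            raise RuleSyntaxError("expected 'TARGET <- EXPR'", lineno)
        target, expr_text = (part.strip() for part in line.split("<-", 1))
        if not target or " " in target:
            raise RuleSyntaxError(f"invalid rule target {target!r}", lineno)
        expr = parse_expression(expr_text, line=lineno)
        raw_rules.append((target, expr, line, lineno))
    if not saw_header:
        raise RuleSyntaxError("missing 'stimuli:' header line")
    return _build_model(stimuli, raw_rules)


def parse_rule_json(payload: dict) -> RegulatoryModel:
    """JSON dialect: {"stimuli": [...], "rules": [{"target": ..., "expr": ...}]}."""
    raw_rules = [
        (r["target"], parse_expression(r["expr"]), f'{r["target"]} <- {r["expr"]}', i + 1)
        for i, r in enumerate(payload.get("rules", []))
    ]
    return _build_model(list(payload.get("stimuli", [])), raw_rules)


def parse_rule_file(path: str | Path) -> RegulatoryModel:
    """Read a rule file (text dialect, or JSON when the suffix is .json)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return parse_rule_json(json.loads(path.read_text()))
    return parse_rule_text(path.read_text())


def _build_model(stimuli, raw_rules) -> RegulatoryModel:
    if len(set(stimuli)) != len(stimuli):
        raise RuleSyntaxError("duplicate stimulus declaration")
    targets: list[str] = []
    for target, _, _, _ in raw_rules:
        # a stimulus-targeting rule is kept and rejected at compile time with
        # a specific error; it must not create a duplicate component here
        if target not in targets and target not in stimuli:
            targets.append(target)
    declared = set(stimuli) | set(targets)
    seen: set[tuple[str, str]] = set()
    literal_use: set[str] = set()
    for target, expr, prov, lineno in raw_rules:
        for name in sorted(free_variables(expr)):
            if name not in declared:
                raise RuleSyntaxError(
                    f"rule for {target!r} references undeclared component {name!r}", lineno
                )
            literal_use.add(name)
        key = (target, format_expression(expr))
        if key in seen:
            raise RuleSyntaxError(f"duplicate rule {prov!r}", lineno)
        seen.add(key)
    components = [Component(s, KIND_STIMULUS) for s in stimuli]
    components += [
        Component(t, KIND_INTERNAL if t in literal_use else KIND_PRODUCT) for t in targets
    ]
    rules = [RegulatoryRule(t, e, prov) for t, e, prov, _ in raw_rules]
    return RegulatoryModel(components, rules)


# -- compilation ------------------------------------------------------------


def state_rows(model: RegulatoryModel) -> list[str]:
    """Row order: all presence states (component order), then all absence states."""
    return [c.presence_label for c in model.components] + [
        c.absence_label for c in model.components
    ]


def compile_model(model: RegulatoryModel) -> StoichiometricNetwork:
    """Compile rules into the qualitative reaction matrix R (plus output exchanges).

    Columns: one internal reaction per DNF conjunction of each rule (named
    ``<target>_<j>``), one per converse conjunction (``NOT_<target>_<j>``,
    derived from the negation of the OR of all the target's rules), then one
    output exchange per non-stimulus component state. Coefficients are
    qualitative ±1. The result is cached on ``model.compiled``.
    """
    stim = set(model.stimuli)
    for rule in model.rules:
        if rule.target in stim:
            raise ValueError(f"rule target {rule.target!r} is a stimulus (stimuli are inputs only)")

    rows = state_rows(model)
    ridx = {r: i for i, r in enumerate(rows)}
    m = len(rows)

    def state_row(name: str, negated: bool) -> int:
        comp = model.component(name)
        return ridx[comp.absence_label if negated else comp.presence_label]

    cols: list[np.ndarray] = []
    reactions: list[Reaction] = []

    def add_reaction(rid: str, conj: Conjunction, product_row: int, prov: str) -> None:
        col = np.zeros(m, dtype=np.int64)
        for name, negated in sorted(conj.literals):
            col[state_row(name, negated)] = -1
        col[product_row] += 1  # contradictory conj may consume the product row too
        cols.append(col)
        reactions.append(
            Reaction(id=rid, role=ROLE_INTERNAL, provenance=prov, contradictory=conj.contradictory)
        )

    # forward reactions: per rule, per DNF conjunction, in rule order
    by_target: dict[str, list[RegulatoryRule]] = {}
    for rule in model.rules:
        by_target.setdefault(rule.target, []).append(rule)

    for target, rules in by_target.items():
        comp = model.component(target)
        counter = 0
        for rule in rules:
            for conj in to_dnf(rule.expression):
                counter += 1
                add_reaction(f"{target}_{counter}", conj, ridx[comp.presence_label], rule.provenance)
        combined = rules[0].expression if len(rules) == 1 else Or(tuple(r.expression for r in rules))
        for j, conj in enumerate(to_dnf(Not(combined)), start=1):
            add_reaction(
                f"NOT_{target}_{j}", conj, ridx[comp.absence_label],
                f"converse of: {format_expression(combined)}",
            )

    for comp in model.non_stimulus_components:
        for label in (comp.presence_label, comp.absence_label):
            col = np.zeros(m, dtype=np.int64)
            col[ridx[label]] = -1
            cols.append(col)
            reactions.append(Reaction(id=f"Ex_{label}", role=ROLE_OUTPUT, provenance=f"export {label}"))

    S = np.column_stack(cols) if cols else np.zeros((m, 0), dtype=np.int64)
    net = StoichiometricNetwork(S, rows, reactions)
    model.compiled = net
    return net


def _compiled(model: RegulatoryModel) -> StoichiometricNetwork:
    return model.compiled if model.compiled is not None else compile_model(model)


def build_env_matrix_new(model: RegulatoryModel) -> np.ndarray:
    """The two-column environment block E_new: shape (#states, 2n).

    Column e is the unit vector of stimulus e's presence row; column n+e of its
    absence row. Construction is O(n).
    """
    rows = state_rows(model)
    ridx = {r: i for i, r in enumerate(rows)}
    n = model.n_stimuli
    E = np.zeros((len(rows), 2 * n), dtype=np.int64)
    for e, sid in enumerate(model.stimuli):
        comp = model.component(sid)
        E[ridx[comp.presence_label], e] = 1
        E[ridx[comp.absence_label], n + e] = 1
    return E


def assemble_rnew(model: RegulatoryModel) -> StoichiometricNetwork:
    """R*_new = [R | E_new]: the compiled matrix plus presence/absence input pairs.

    Input columns come last (presence block then absence block) so pathway
    vectors from single-environment matrices expand in place during
    normalization.
    """
    base = _compiled(model)
    E = build_env_matrix_new(model)
    n = model.n_stimuli
    reactions = list(base.reactions)
    for e, sid in enumerate(model.stimuli):
        reactions.append(Reaction(id=f"In_{sid}", role=ROLE_INPUT, stimulus=sid, state="present",
                                  provenance=f"presence input of {sid}"))
    for e, sid in enumerate(model.stimuli):
        reactions.append(Reaction(id=f"In_NOT_{sid}", role=ROLE_INPUT, stimulus=sid, state="absent",
                                  provenance=f"absence input of {sid}"))
    S = np.hstack([base.S, E]) if n else base.S
    return StoichiometricNetwork(S, list(base.species), reactions)


def assemble_ri(model: RegulatoryModel, env: EnvironmentAssignment) -> StoichiometricNetwork:
    """R*_i = [R | E_i]: one input column per stimulus for a fixed environment."""
    model.validate_environment(env)
    base = _compiled(model)
    rows = base.species
    ridx = {r: i for i, r in enumerate(rows)}
    cols, reactions = [np.asarray(base.S)], list(base.reactions)
    Ei = np.zeros((len(rows), model.n_stimuli), dtype=np.int64)
    for e, sid in enumerate(model.stimuli):
        comp = model.component(sid)
        present = env[sid]
        Ei[ridx[comp.presence_label if present else comp.absence_label], e] = 1
        reactions.append(Reaction(id=f"In_{sid}", role=ROLE_INPUT, stimulus=sid,
                                  state="present" if present else "absent",
                                  provenance=f"input of {sid} ({'present' if present else 'absent'})"))
    S = np.hstack([base.S, Ei]) if model.n_stimuli else base.S
    return StoichiometricNetwork(S, list(rows), reactions)
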