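"""Boolean expression trees for transcriptional regulatory rules.

Rules are propositional formulas over component presence literals, built from
AND, OR, NOT and parentheses.  Compilation to reactions needs each rule in
disjunctive normal form (DNF): each conjunction becomes one qualitative
reaction.  Contradictory conjunctions (containing both ``x`` and ``NOT x``)
are deliberately retained and flagged — in curated genome-scale regulatory
models they betray rule errors, and keeping them lets the unused-reaction
report surface exactly those defects.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import reduce

# -- expression tree --------------------------------------------------------


class BoolExpr:
    """Base class; concrete nodes are Lit, Not, And, Or."""

    __slots__ = ()


@dataclass(frozen=True)
class Lit(BoolExpr):
    name: str
    negated: bool = False


@dataclass(frozen=True)
class Not(BoolExpr):
    arg: BoolExpr


@dataclass(frozen=True)
class And(BoolExpr):
    args: tuple[BoolExpr, ...]


@dataclass(frozen=True)
class Or(BoolExpr):
    args: tuple[BoolExpr, ...]


Literal = tuple[str, bool]  # (component id, negated)


@dataclass(frozen=True)
class Conjunction:
    """One AND-term of a DNF: a set of literals, flagged if self-contradictory."""

    literals: frozenset[Literal]

    @property
    def contradictory(self) -> bool:
        names = [n for n, _ in self.literals]
        return len(set(names)) < len(names)

    def sort_key(self) -> tuple:
        return tuple(sorted(self.literals))


def free_variables(expr: BoolExpr) -> set[str]:
    if isinstance(expr, Lit):
        return {expr.name}
    if isinstance(expr, Not):
        return free_variables(expr.arg)
    return set().union(*(free_variables(a) for a in expr.args))


def evaluate(expr: BoolExpr, assignment: dict[str, bool]) -> bool:
    if isinstance(expr, Lit):
        v = assignment[expr.name]
        return (not v) if expr.negated else v
    if isinstance(expr, Not):
        return not evaluate(expr.arg, assignment)
    if isinstance(expr, And):
        return all(evaluate(a, assignment) for a in expr.args)
    if isinstance(expr, Or):
        return any(evaluate(a, assignment) for a in expr.args)
    raise TypeError(f"not a BoolExpr: {expr!r}")


# -- DNF conversion ---------------------------------------------------------


def _nnf(expr: BoolExpr, negate: bool = False) -> BoolExpr:
    """Push negations down to literals (negation normal form)."""
    if isinstance(expr, Lit):
        return Lit(expr.name, expr.negated ^ negate)
    if isinstance(expr, Not):
        return _nnf(expr.arg, not negate)
    if isinstance(expr, And):
        args = tuple(_nnf(a, negate) for a in expr.args)
        return Or(args) if negate else And(args)
    if isinstance(expr, Or):
        args = tuple(_nnf(a, negate) for a in expr.args)
        return And(args) if negate else Or(args)
    raise TypeError(f"not a BoolExpr: {expr!r}")


def _distribute(expr: BoolExpr) -> list[frozenset[Literal]]:
    if isinstance(expr, Lit):
        return [frozenset({(expr.name, expr.negated)})]
    if isinstance(expr, Or):
        out: list[frozenset[Literal]] = []
        for a in expr.args:
            out.extend(_distribute(a))
        return out
    if isinstance(expr, And):
        parts = [_distribute(a) for a in expr.args]
        return [reduce(frozenset.union, combo) for combo in _cartesian(parts)]
    raise TypeError(f"unexpected node in NNF: {expr!r}")


def _cartesian(parts):
    if not parts:
        yield ()
        return
    for head in parts[0]:
        for tail in _cartesian(parts[1:]):
            yield (head, *tail)


def to_dnf(expr: BoolExpr) -> list[Conjunction]:
    """Disjunctive normal form as a deterministic (sorted) conjunction list.

    Contradictory conjunctions are retained, not pruned; exact duplicate
    conjunctions are merged. The result is logically equivalent to the input.
    """
    terms = {Conjunction(lits) for lits in _distribute(_nnf(expr))}
    return sorted(terms, key=Conjunction.sort_key)


def dnf_to_expr(terms: list[Conjunction]) -> BoolExpr:
    """Rebuild an expression tree from a DNF term list (testing/round-trips)."""
    if not terms:
        raise ValueError("empty DNF")
    ors = []
    for t in terms:
        lits = [Lit(n, neg) for n, neg in sorted(t.literals)]
        ors.append(lits[0] if len(lits) == 1 else And(tuple(lits)))
    return ors[0] if len(ors) == 1 else Or(tuple(ors))


# -- parsing ----------------------------------------------------------------


class RuleSyntaxError(ValueError):
    """Syntax error in a rule expression, with line/column context."""

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        loc = ""
        if line is not None:
            loc = f" (line {line}" + (f", column {column}" if column is not None else "") + ")"
        super().__init__(message + loc)
        self.line = line
        self.column = column


_TOKEN = re.compile(r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<word>[A-Za-z0-9_.\-]+))")
_KEYWORDS = {"AND", "OR", "NOT"}


def _tokenize(text: str, line: int | None):
    pos, tokens = 0, []
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or m.lastgroup is None:
            rest = text[pos:].strip()
            if not rest:
                break
            raise RuleSyntaxError(f"unexpected character {rest[0]!r}", line, pos + 1)
        kind, val = m.lastgroup, m.group(m.lastgroup)
        if kind == "word":
            kind = "op" if val.upper() in _KEYWORDS else "ident"
            val = val.upper() if kind == "op" else val
        tokens.append((kind, val, m.start(m.lastgroup) + 1))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive descent over: or_expr := and_expr (OR and_expr)* ; and_expr :=
    unary (AND unary)* ; unary := NOT unary | '(' or_expr ')' | ident."""

    def __init__(self, tokens, line):
        self.tokens = tokens
        self.line = line
        self.i = 0

    def _peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def _next(self):
        tok = self._peek()
        if tok is None:
            raise RuleSyntaxError("unexpected end of expression", self.line)
        self.i += 1
        return tok

    def parse(self) -> BoolExpr:
        expr = self.or_expr()
        tok = self._peek()
        if tok is not None:
            raise RuleSyntaxError(f"unexpected token {tok[1]!r}", self.line, tok[2])
        return expr

    def or_expr(self) -> BoolExpr:
        args = [self.and_expr()]
        while (tok := self._peek()) and tok[:2] == ("op", "OR"):
            self._next()
            args.append(self.and_expr())
        return args[0] if len(args) == 1 else Or(tuple(args))

    def and_expr(self) -> BoolExpr:
        args = [self.unary()]
        while (tok := self._peek()) and tok[:2] == ("op", "AND"):
            self._next()
            args.append(self.unary())
        return args[0] if len(args) == 1 else And(tuple(args))

    def unary(self) -> BoolExpr:
        tok = self._next()
        kind, val, col = tok
        if kind == "op" and val == "NOT":
            return Not(self.unary())
        if kind == "lpar":
            expr = self.or_expr()
            tok = self._next()
            if tok[0] != "rpar":
                raise RuleSyntaxError("expected ')'", self.line, tok[2])
            return expr
        if kind == "ident":
            return Lit(val)
        raise RuleSyntaxError(f"unexpected token {val!r}", self.line, col)


def parse_expression(text: str, line: int | None = None) -> BoolExpr:
    """Parse a Boolean rule expression (AND/OR/NOT/parentheses over identifiers)."""
    tokens = _tokenize(text, line)
    if not tokens:
        raise RuleSyntaxError("empty expression", line)
    return _Parser(tokens, line).parse()


def format_expression(expr: BoolExpr) -> str:
    """Render an expression back to rule-file syntax (compound children get parens)."""
    if isinstance(expr, Lit):
        return f"NOT {expr.name}" if expr.negated else expr.name
    if isinstance(expr, Not):
        return f"NOT ({format_expression(expr.arg)})"
    if isinstance(expr, (And, Or)):
        sep = " AND " if isinstance(expr, And) else " OR "
        return sep.join(
            f"({format_expression(a)})" if isinstance(a, (And, Or)) else format_expression(a)
            for a in expr.args
        )
    raise TypeError(f"not a BoolExpr: {expr!r}")
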