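"""Extreme-pathway enumeration over the flux cone {v >= 0 : S v = 0}.

For a network whose reactions are all irreversible, the extreme rays of the
cone coincide with the elementary flux modes: the support-minimal nonzero
steady-state flux patterns.  ``enumerate_extreme_pathways`` implements the
classical tableau (double description) algorithm in exact integer arithmetic;
``brute_force_elementary_modes`` is a deliberately independent oracle that
scans all reaction subsets and tests the rank condition directly, used to
cross-check the enumerator on small networks.

All returned flux vectors are integer, gcd-normalized, and sorted by support,
so two enumeration routes can be compared as plain sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import gcd
from pathlib import Path

import numpy as np

from .network import Reaction, StoichiometricNetwork

CLASS_EXCHANGE = "I"   # carries exchange flux
CLASS_INTERNAL_CYCLE = "III"  # internal cycle, no exchange flux: thermodynamically infeasible


@dataclass(frozen=True)
class ExtremePathway:
    """One extreme ray: a nonnegative integer flux vector with gcd 1."""

    flux: tuple[int, ...]
    expa_class: str = CLASS_EXCHANGE

    @property
    def support(self) -> frozenset[int]:
        return frozenset(i for i, v in enumerate(self.flux) if v)

    def support_ids(self, net: StoichiometricNetwork) -> frozenset[str]:
        return frozenset(net.reactions[i].id for i in self.support)

    @property
    def length(self) -> int:
        return sum(1 for v in self.flux if v)


@dataclass
class ExPaSet:
    """A set of extreme pathways over a fixed network/column order."""

    network: StoichiometricNetwork
    pathways: list[ExtremePathway]
    n_class3_removed: int = 0
    log: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def vectors(self) -> set[tuple[int, ...]]:
        return {p.flux for p in self.pathways}

    @classmethod
    def from_vectors(cls, net: StoichiometricNetwork, vectors) -> "ExPaSet":
        paths = [
            ExtremePathway(flux, _classify_one(flux, net))
            for flux in (tuple(int(x) for x in v) for v in vectors)
        ]
        return cls(net, _sorted_paths(paths))

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        df = pd.DataFrame(
            [list(p.flux) for p in self.pathways],
            index=[f"ExPa_{i+1}" for i in range(len(self.pathways))],
            columns=self.network.reaction_ids,
        )
        df.to_csv(path, sep="\t", lineterminator="\n")

    def to_json(self, path: str | Path) -> None:
        import json

        payload = [
            {"flux": list(p.flux), "class": p.expa_class,
             "support": sorted(p.support_ids(self.network))}
            for p in self.pathways
        ]
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")


# -- helpers ----------------------------------------------------------------


def _normalize(vec: list[int]) -> tuple[int, ...]:
    g = 0
    for v in vec:
        g = gcd(g, v)
    if g > 1:
        return tuple(v // g for v in vec)
    return tuple(vec)


def _sorted_paths(paths: list[ExtremePathway]) -> list[ExtremePathway]:
    return sorted(paths, key=lambda p: (tuple(sorted(p.support)), p.flux))


def _classify_one(flux, net: StoichiometricNetwork) -> str:
    for j in net.exchange_columns:
        if flux[j]:
            return CLASS_EXCHANGE
    return CLASS_INTERNAL_CYCLE


def _drop_spurious_two_cycles(vectors, reactions: list[Reaction]):
    """Remove fwd+bwd two-cycles that are artifacts of reversible splitting."""
    pair_of = {}
    for j, r in enumerate(reactions):
        if r.split_of is not None:
            pair_of.setdefault(r.split_of, set()).add(j)
    spurious = {frozenset(js) for js in pair_of.values() if len(js) == 2}
    if not spurious:
        return list(vectors)
    return [v for v in vectors
            if frozenset(i for i, x in enumerate(v) if x) not in spurious]


def _strip_pinned(net: StoichiometricNetwork):
    """Return (kept column indices, submatrix) with pinned-zero columns removed."""
    keep = [j for j, r in enumerate(net.reactions) if r.id not in net.pinned_zero]
    return keep, net.S[:, keep]


# -- main enumerator --------------------------------------------------------


def enumerate_extreme_pathways(
    net: StoichiometricNetwork, row_order: list[int] | None = None
) -> ExPaSet:
    """Enumerate all extreme rays of {v >= 0 : S v = 0} by tableau elimination.

    Requires an all-irreversible network (run :func:`split_reversible` first).
    Rows are processed metabolite by metabolite; at each step, candidates with
    zero residual are kept and every positive/negative residual pair is
    combined, with support-minimality pruning against the new tableau.  Exact
    Python integers are used throughout, so no overflow or tolerance issues
    arise.  ``row_order`` overrides the default fill-reduction heuristic
    (ascending #positive x #negative); any order yields the same set.

    Spurious forward/backward two-cycles introduced by reversible splitting
    are removed from the result.
    """
    if net.has_reversible():
        raise ValueError("network has reversible reactions; run split_reversible first")
    keep, sub = _strip_pinned(net)
    rays_sub = _extreme_rays(sub.tolist(), row_order)
    n = net.n_reactions
    vectors = []
    for ray in rays_sub:
        full = [0] * n
        for j, v in zip(keep, ray):
            full[j] = v
        vectors.append(tuple(full))
    vectors = _drop_spurious_two_cycles(vectors, net.reactions)
    paths = [ExtremePathway(v, _classify_one(v, net)) for v in vectors]
    return ExPaSet(net, _sorted_paths(paths), log={"raw": len(paths)})


def _extreme_rays(S: list[list[int]], row_order: list[int] | None = None) -> list[tuple[int, ...]]:
    m = len(S)
    n = len(S[0]) if m else 0
    if n == 0:
        return []
    # candidate = (vec list[int], support bitmask, residual list[int])
    cands = [([1 if i == j else 0 for j in range(n)], 1 << i, [S[r][i] for r in range(m)])
             for i in range(n)]
    remaining = list(range(m)) if row_order is None else list(row_order)
    if row_order is not None and sorted(remaining) != list(range(m)):
        raise ValueError("row_order must be a permutation of the row indices")

    while remaining:
        if row_order is None:
            def cost(r):
                pos = sum(1 for c in cands if c[2][r] > 0)
                neg = sum(1 for c in cands if c[2][r] < 0)
                return (pos * neg, r)
            r = min(remaining, key=cost)
        else:
            r = remaining[0]
        remaining.remove(r)

        zero = [c for c in cands if c[2][r] == 0]
        pos = [c for c in cands if c[2][r] > 0]
        neg = [c for c in cands if c[2][r] < 0]
        seen = {tuple(c[0]) for c in zero}
        combos = []
        for pv, pmask, pres in pos:
            a = pres[r]
            for nv, nmask, nres in neg:
                b = -nres[r]
                vec = [b * x + a * y for x, y in zip(pv, nv)]
                res = [b * x + a * y for x, y in zip(pres, nres)]
                g = 0
                for x in vec:
                    g = gcd(g, x)
                if g > 1:  # g divides res too, since res = S . vec
                    vec = [x // g for x in vec]
                    res = [x // g for x in res]
                t = tuple(vec)
                if t in seen:
                    continue
                seen.add(t)
                combos.append((vec, pmask | nmask, res))
        # support-minimality pruning: a combined candidate survives only if no
        # other row of the new tableau has support strictly contained in it
        zero_masks = [c[1] for c in zero]
        kept = []
        for c in combos:
            mask = c[1]
            if any(zm != mask and zm & mask == zm for zm in zero_masks):
                continue
            if any(oc is not c and oc[1] != mask and oc[1] & mask == oc[1] for oc in combos):
                continue
            kept.append(c)
        cands = zero + kept

    return [_normalize(c[0]) for c in cands]


# -- classification ---------------------------------------------------------


def classify_pathways(expas: ExPaSet) -> ExPaSet:
    """Drop class III pathways (internal cycles with no exchange flux).

    Such cycles carry flux without exchanging anything with the surroundings
    and are thermodynamically infeasible. The returned set records how many
    were removed.
    """
    kept = [p for p in expas.pathways if p.expa_class != CLASS_INTERNAL_CYCLE]
    removed = len(expas.pathways) - len(kept)
    log = dict(expas.log)
    log["class3_removed"] = removed
    return ExPaSet(expas.network, kept, n_class3_removed=removed, log=log)


# -- brute-force oracle -----------------------------------------------------

_BRUTE_FORCE_MAX = 14


def brute_force_elementary_modes(net: StoichiometricNetwork) -> ExPaSet:
    """Independent oracle: enumerate elementary modes by exhaustive subset scan.

    A reaction subset is an elementary mode support iff the kernel of S
    restricted to it is one-dimensional with a strictly positive generator.
    Exponential in the reaction count; guarded at 14 reactions.
    """
    if net.has_reversible():
        raise ValueError("network has reversible reactions; run split_reversible first")
    keep, sub = _strip_pinned(net)
    k = len(keep)
    if k > _BRUTE_FORCE_MAX:
        raise ValueError(f"brute-force oracle limited to {_BRUTE_FORCE_MAX} reactions (got {k})")
    S = sub.tolist()
    m = len(S)
    col_masks_pos = [0] * m
    col_masks_neg = [0] * m
    for r in range(m):
        for j in range(k):
            if S[r][j] > 0:
                col_masks_pos[r] |= 1 << j
            elif S[r][j] < 0:
                col_masks_neg[r] |= 1 << j

    found: list[tuple[int, tuple[int, ...]]] = []  # (mask, vector over kept columns)
    for mask in range(1, 1 << k):
        # each metabolite row restricted to the subset must be balanced-able:
        # all-zero or containing both signs
        ok = True
        for r in range(m):
            p = col_masks_pos[r] & mask
            q = col_masks_neg[r] & mask
            if (p == 0) != (q == 0):
                ok = False
                break
        if not ok:
            continue
        cols = [j for j in range(k) if mask >> j & 1]
        vec = _positive_kernel_1d([[S[r][j] for j in cols] for r in range(m)])
        if vec is None:
            continue
        full = [0] * k
        for j, v in zip(cols, vec):
            full[j] = v
        found.append((mask, _normalize(full)))

    # defensive support-minimality filter (redundant given the rank test)
    minimal = [
        (mask, v) for mask, v in found
        if not any(om != mask and om & mask == om for om, _ in found)
    ]
    n = net.n_reactions
    vectors = []
    for _, ray in minimal:
        full = [0] * n
        for j, v in zip(keep, ray):
            full[j] = v
        vectors.append(tuple(full))
    vectors = _drop_spurious_two_cycles(vectors, net.reactions)
    paths = [ExtremePathway(v, _classify_one(v, net)) for v in vectors]
    return ExPaSet(net, _sorted_paths(paths))


def _positive_kernel_1d(A: list[list[int]]) -> list[int] | None:
    """If ker(A) is 1-D with a strictly positive generator, return it as integers."""
    m = len(A)
    k = len(A[0]) if m else 0
    rows = [[Fraction(x) for x in row] for row in A]
    pivots: list[int] = []
    r = 0
    for c in range(k):
        pr = next((i for i in range(r, m) if rows[i][c] != 0), None)
        if pr is None:
            continue
        rows[r], rows[pr] = rows[pr], rows[r]
        pv = rows[r][c]
        rows[r] = [x / pv for x in rows[r]]
        for i in range(m):
            if i != r and rows[i][c] != 0:
                f = rows[i][c]
                rows[i] = [x - f * y for x, y in zip(rows[i], rows[r])]
        pivots.append(c)
        r += 1
        if r == m:
            break
    free = [c for c in range(k) if c not in pivots]
    if len(free) != 1:
        return None
    fc = free[0]
    vec = [Fraction(0)] * k
    vec[fc] = Fraction(1)
    for i, pc in enumerate(pivots):
        vec[pc] = -rows[i][fc]
    if any(v <= 0 for v in vec):
        return None
    from math import lcm

    denom = lcm(*(v.denominator for v in vec))
    return [int(v * denom) for v in vec]


# -- decomposition ----------------------------------------------------------


def decompose_flux(net: StoichiometricNetwork, v, expas: ExPaSet):
    """Express a steady-state flux v >= 0 as a nonnegative combination of ExPas.

    Returns ``(True, alpha)`` with one valid witness when v lies in the cone
    spanned by the pathways, else ``(False, None)``.  Raises on vectors that
    violate the steady-state contract (S v != 0 or v < 0), checked exactly.
    """
    from scipy.optimize import linprog

    vf = [Fraction(x) for x in v]
    if len(vf) != net.n_reactions:
        raise ValueError("flux vector length does not match the network")
    if any(x < 0 for x in vf):
        raise ValueError("flux vector must be nonnegative")
    for r in range(net.n_species):
        if sum(Fraction(int(net.S[r, j])) * vf[j] for j in range(net.n_reactions)) != 0:
            raise ValueError("S v != 0: not a steady-state flux vector")

    vfloat = np.array([float(x) for x in vf])
    if not expas.pathways:
        return (not any(vf), np.zeros(0) if not any(vf) else None)
    P = np.array([p.flux for p in expas.pathways], dtype=float).T  # reactions x expas
    res = linprog(c=np.zeros(P.shape[1]), A_eq=P, b_eq=vfloat,
                  bounds=[(0, None)] * P.shape[1], method="highs")
    if not res.success:
        return False, None
    scale = max(1.0, float(np.abs(vfloat).max()))
    if np.abs(P @ res.x - vfloat).max() > 1e-7 * scale:
        return False, None
    return True, res.x
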