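"""Comparison metrics over an extreme-pathway set.

All metrics derive from the binary participation matrix (pathways x
reactions, entry 1 iff the pathway carries flux through the reaction):

* pathway count and the pathway/reaction ratio P/R — network redundancy;
* pathway length (support size, exchanges included) and L/R — route
  complexity relative to network size;
* reaction participation rate (RPR) — the percentage of pathways a reaction
  takes part in, a proxy for its functional importance;
* correlated reaction sets (CoSets) — reactions with identical participation
  signatures, "trivial" when topologically connected;
* crosstalk — pairwise classification of pathway input/output sets into
  identical / overlapped / disjoint, a 3x3 category matrix;
* the unused-reaction report — RPR = 0 reactions, split into dead-end wiring
  (type I) and contradictory-rule artifacts (type II).
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .cone import ExPaSet
from .network import ROLE_INPUT, ROLE_OUTPUT

CATEGORIES = ("identical", "overlapped", "disjoint")


# -- participation ----------------------------------------------------------


def participation_matrix(expas: ExPaSet) -> np.ndarray:
    """Binary pathways x reactions incidence matrix."""
    if not expas.pathways:
        return np.zeros((0, expas.network.n_reactions), dtype=np.int8)
    return (np.array([p.flux for p in expas.pathways]) != 0).astype(np.int8)


def reaction_participation(expas: ExPaSet) -> pd.DataFrame:
    """RPR per reaction, sorted descending (ties broken by reaction id).

    Columns: reaction, role, rpr (percent of pathways using the reaction).
    """
    if not expas.pathways:
        raise ValueError("reaction participation needs at least one pathway")
    part = participation_matrix(expas)
    rpr = part.sum(axis=0) / len(expas.pathways) * 100.0
    df = pd.DataFrame(
        {
            "reaction": expas.network.reaction_ids,
            "role": [r.role for r in expas.network.reactions],
            "rpr": rpr,
        }
    )
    return df.sort_values(["rpr", "reaction"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)


# -- lengths ----------------------------------------------------------------


@dataclass
class LengthStats:
    """Support-size statistics; ``avg_rounded`` is the half-up integer used in
    summary tables, ``lr_percent`` is 100 * mean length / #reactions."""

    n: int
    avg: float
    avg_rounded: int
    max: int
    min: int
    mode: int
    histogram: dict[int, int]
    lr_percent: float
    empty: bool = False

    def to_dict(self) -> dict:
        return {
            "n": self.n, "avg": self.avg, "avg_rounded": self.avg_rounded,
            "max": self.max, "min": self.min, "mode": self.mode,
            "histogram": {str(k): v for k, v in sorted(self.histogram.items())},
            "lr_percent": self.lr_percent, "empty": self.empty,
        }


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def pathway_lengths(expas: ExPaSet) -> LengthStats:
    """Length = number of active reactions, exchanges included.

    Mode ties break toward the smallest length. An empty pathway set returns a
    flagged, zeroed record rather than raising.
    """
    if not expas.pathways:
        return LengthStats(0, float("nan"), 0, 0, 0, 0, {}, float("nan"), empty=True)
    lengths = [p.length for p in expas.pathways]
    hist = Counter(lengths)
    mode = min((ln for ln, c in hist.items() if c == max(hist.values())))
    avg = sum(lengths) / len(lengths)
    return LengthStats(
        n=len(lengths),
        avg=avg,
        avg_rounded=_round_half_up(avg),
        max=max(lengths),
        min=min(lengths),
        mode=mode,
        histogram=dict(hist),
        lr_percent=100.0 * avg / expas.network.n_reactions,
    )


def pr_ratio(expas: ExPaSet) -> float:
    """Pathway count / reaction count (all columns: internal + exchanges)."""
    n = expas.network.n_reactions
    if n == 0:
        raise ValueError("P/R undefined for a network with no reactions")
    return len(expas.pathways) / n


# -- unused reactions -------------------------------------------------------


@dataclass(frozen=True)
class UnusedReaction:
    reaction: str
    role: str
    type: str  # "I" (wiring dead end) or "II" (contradictory rule)
    detail: str


def unused_reactions(expas: ExPaSet) -> list[UnusedReaction]:
    """Reactions participating in no pathway, with a diagnosis.

    Type II: the reaction was compiled from a self-contradictory rule
    conjunction, or it is an exchange whose state is produced only by
    contradictory reactions. Type I: everything else — typically a state with
    no producer or no consumer anywhere in the network.
    """
    net = expas.network
    part = participation_matrix(expas)
    used = part.any(axis=0) if len(part) else np.zeros(net.n_reactions, dtype=bool)
    report: list[UnusedReaction] = []
    S = net.S
    contradictory_cols = {j for j, r in enumerate(net.reactions) if r.contradictory}
    for j, r in enumerate(net.reactions):
        if used[j]:
            continue
        if r.contradictory:
            report.append(UnusedReaction(r.id, r.role, "II", "contradictory rule conjunction"))
            continue
        if r.role in (ROLE_INPUT, ROLE_OUTPUT):
            # which rows does this exchange touch, and who produces them?
            rows = np.nonzero(S[:, j])[0]
            producers = {
                k for i in rows for k in np.nonzero(S[i, :] > 0)[0] if k != j
            }
            if producers and producers <= contradictory_cols:
                report.append(UnusedReaction(
                    r.id, r.role, "II", "state produced only by contradictory reactions"))
                continue
        report.append(UnusedReaction(r.id, r.role, "I",
                                     "dead end: producing/consuming reactions unavailable"))
    return report


# -- correlated reaction sets ----------------------------------------------


@dataclass
class CoSet:
    members: tuple[str, ...]
    signature: tuple[int, ...]  # shared participation column
    trivial: bool  # True when the member graph is connected


@dataclass
class CoSetReport:
    cosets: list[CoSet]
    adjacent_ratio: float | None  # percent of trivial CoSets; None if no CoSets
    size_max: int
    size_min: int
    size_avg: float
    size_mode: int

    def to_dict(self) -> dict:
        return {
            "n_cosets": len(self.cosets),
            "adjacent_ratio": self.adjacent_ratio,
            "size_max": self.size_max, "size_min": self.size_min,
            "size_avg": self.size_avg, "size_mode": self.size_mode,
            "cosets": [
                {"members": list(c.members), "trivial": c.trivial} for c in self.cosets
            ],
        }


def find_cosets(expas: ExPaSet) -> CoSetReport:
    """Group reactions by identical nonzero participation signature.

    Each group of >= 2 reactions is a CoSet.  A CoSet is *trivial* when the
    graph over its members — an edge whenever two reactions share a species
    with nonzero stoichiometry — is connected; the adjacent ratio is the
    percentage of trivial CoSets.
    """
    if not expas.pathways:
        raise ValueError("CoSet analysis needs at least one pathway")
    net = expas.network
    part = participation_matrix(expas)
    groups: dict[tuple[int, ...], list[int]] = {}
    for j in range(net.n_reactions):
        sig = tuple(int(x) for x in part[:, j])
        if not any(sig):
            continue
        groups.setdefault(sig, []).append(j)

    cosets = []
    touched = [frozenset(np.nonzero(net.S[:, j])[0]) for j in range(net.n_reactions)]
    for sig in sorted(groups, reverse=True):
        members = groups[sig]
        if len(members) < 2:
            continue
        g = nx.Graph()
        g.add_nodes_from(members)
        for a_i, a in enumerate(members):
            for b in members[a_i + 1:]:
                if touched[a] & touched[b]:
                    g.add_edge(a, b)
        cosets.append(CoSet(
            members=tuple(net.reactions[j].id for j in members),
            signature=sig,
            trivial=nx.is_connected(g),
        ))

    if not cosets:
        return CoSetReport([], None, 0, 0, 0.0, 0)
    sizes = [len(c.members) for c in cosets]
    hist = Counter(sizes)
    mode = min(s for s, c in hist.items() if c == max(hist.values()))
    ratio = 100.0 * sum(c.trivial for c in cosets) / len(cosets)
    return CoSetReport(cosets, ratio, max(sizes), min(sizes), sum(sizes) / len(sizes), mode)


# -- crosstalk --------------------------------------------------------------


@dataclass
class CrosstalkMatrix:
    """3x3 pair counts/percentages, rows = input relation, cols = output relation."""

    counts: np.ndarray  # 3x3 int, axes ordered as CATEGORIES
    excluded_reactions: tuple[str, ...]

    @property
    def n_pairs(self) -> int:
        return int(self.counts.sum())

    @property
    def percentages(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / total * 100.0

    def to_frame(self, percent: bool = True) -> pd.DataFrame:
        data = self.percentages if percent else self.counts
        return pd.DataFrame(data,
                            index=[f"inputs_{c}" for c in CATEGORIES],
                            columns=[f"outputs_{c}" for c in CATEGORIES])


def _relation(a: frozenset, b: frozenset) -> int:
    # empty vs empty -> identical; empty vs nonempty -> disjoint
    if a == b:
        return 0
    if not (a & b):
        return 2
    return 1


def crosstalk_matrix(
    expas: ExPaSet, exclude_top_exchange_fraction: float = 0.20
) -> CrosstalkMatrix:
    """Classify every pathway pair by input-set and output-set relation.

    Before classification, the top ``ceil(fraction x #exchange reactions)``
    exchange reactions ranked by RPR are removed from all input/output sets —
    ubiquitous exchanges (currency-like species) would otherwise make nearly
    every pair "overlapped".  Set ``exclude_top_exchange_fraction=0`` to
    disable the exclusion.
    """
    if len(expas.pathways) < 2:
        raise ValueError("crosstalk needs at least two pathways")
    if not 0 <= exclude_top_exchange_fraction <= 1:
        raise ValueError("exclusion fraction must lie in [0, 1]")
    net = expas.network
    rpr = reaction_participation(expas)
    exch = rpr[rpr["role"].isin([ROLE_INPUT, ROLE_OUTPUT])]
    n_excl = math.ceil(exclude_top_exchange_fraction * len(exch))
    excluded = set(exch["reaction"].head(n_excl)) if n_excl else set()

    in_cols = [j for j, r in enumerate(net.reactions)
               if r.role == ROLE_INPUT and r.id not in excluded]
    out_cols = [j for j, r in enumerate(net.reactions)
                if r.role == ROLE_OUTPUT and r.id not in excluded]
    inputs = [frozenset(j for j in in_cols if p.flux[j]) for p in expas.pathways]
    outputs = [frozenset(j for j in out_cols if p.flux[j]) for p in expas.pathways]

    counts = np.zeros((3, 3), dtype=np.int64)
    n = len(expas.pathways)
    for i in range(n):
        for j in range(i + 1, n):
            counts[_relation(inputs[i], inputs[j]), _relation(outputs[i], outputs[j])] += 1
    return CrosstalkMatrix(counts, tuple(sorted(excluded)))


# -- aggregate report -------------------------------------------------------


@dataclass
class MetricsReport:
    n_expas: int
    n_reactions: int
    pr_ratio: float | None
    lengths: LengthStats
    rpr: pd.DataFrame | None
    cosets: CoSetReport | None
    crosstalk: CrosstalkMatrix | None
    unused: list[UnusedReaction] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_expas": self.n_expas,
            "n_reactions": self.n_reactions,
            "pr_ratio": self.pr_ratio,
            "lengths": self.lengths.to_dict(),
            "cosets": self.cosets.to_dict() if self.cosets else None,
            "crosstalk": {
                "counts": self.crosstalk.counts.tolist(),
                "percent": [[round(x, 2) for x in row] for row in self.crosstalk.percentages],
                "excluded_reactions": list(self.crosstalk.excluded_reactions),
            } if self.crosstalk else None,
            "unused": [u.__dict__ for u in self.unused],
            "flags": self.flags,
        }

    def write(self, outdir: str | Path) -> None:
        """Serialize report.json plus rpr.tsv / cosets.tsv / crosstalk.tsv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(self.to_dict(), indent=1) + "\n")
        if self.rpr is not None:
            out = self.rpr.copy()
            out["rpr"] = out["rpr"].map(lambda x: f"{x:.2f}")
            out.to_csv(outdir / "rpr.tsv", sep="\t", index=False, lineterminator="\n")
        if self.cosets is not None:
            rows = [
                {"coset": i + 1, "size": len(c.members), "trivial": int(c.trivial),
                 "members": ",".join(c.members)}
                for i, c in enumerate(self.cosets.cosets)
            ]
            pd.DataFrame(rows, columns=["coset", "size", "trivial", "members"]).to_csv(
                outdir / "cosets.tsv", sep="\t", index=False, lineterminator="\n")
        if self.crosstalk is not None:
            self.crosstalk.to_frame().round(2).to_csv(
                outdir / "crosstalk.tsv", sep="\t", lineterminator="\n")


def metrics_report(
    expas: ExPaSet,
    exclude_top_exchange_fraction: float = 0.20,
    crosstalk: bool = True,
) -> MetricsReport:
    """Run every metric and collect the results; degenerate inputs set flags
    instead of raising."""
    flags: list[str] = []
    n = len(expas.pathways)
    net = expas.network
    pr = pr_ratio(expas) if net.n_reactions else None
    if net.n_reactions == 0:
        flags.append("network has no reactions")
    lengths = pathway_lengths(expas)
    if lengths.empty:
        flags.append("empty pathway set: length stats undefined")
    rpr = reaction_participation(expas) if n else None
    cosets = find_cosets(expas) if n else None
    xtalk = (crosstalk_matrix(expas, exclude_top_exchange_fraction)
             if crosstalk and n >= 2 else None)
    if crosstalk and n < 2:
        flags.append("fewer than two pathways: crosstalk skipped")
    return MetricsReport(
        n_expas=n,
        n_reactions=net.n_reactions,
        pr_ratio=pr,
        lengths=lengths,
        rpr=rpr,
        cosets=cosets,
        crosstalk=xtalk,
        unused=unused_reactions(expas),
        flags=flags,
    )
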