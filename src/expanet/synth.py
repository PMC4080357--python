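"""Deterministic generators for test models and networks.

``toy_trn`` is the four-stimulus, two-product regulatory model used
throughout the documentation (rules: Protein1 needs A and B together;
Protein2 needs C or D).  ``random_trn`` draws seeded layered
stimulus -> transcription-factor -> gene models that mirror the flat
hierarchy of real transcriptional networks.  ``fixture_networks`` returns a
handful of tiny metabolic networks (chain, diamond, cycle, ...) whose extreme
pathways are known or cheap to recompute with the brute-force oracle.

Everything here is a pure function of its seed/config: the same inputs give
byte-identical models.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import numpy as np

from .network import (
    ROLE_INPUT,
    ROLE_INTERNAL,
    ROLE_OUTPUT,
    Reaction,
    StoichiometricNetwork,
)
from .regulatory import RegulatoryModel, parse_rule_text

TOY_RULES = """\
# toy regulatory model: two gene products driven by four stimuli
stimuli: A, B, C, D
Protein1 <- A AND B
Protein2 <- C
Protein2 <- D
"""


def toy_trn() -> RegulatoryModel:
    """The worked-example model: P1 <- A AND B; P2 <- C; P2 <- D.

    Compiles to 6 internal reactions: the forward conjunctions (A,B -> P1;
    C -> P2; D -> P2) and the converses (NOT A -> NOT P1; NOT B -> NOT P1;
    NOT C, NOT D -> NOT P2).
    """
    return parse_rule_text(TOY_RULES)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs for :func:`random_trn`; probabilities in [0, 1], counts >= 0."""

    seed: int = 0
    n_stimuli: int = 4
    n_tfs: int = 2
    n_genes: int = 2
    max_conjunction_arity: int = 2
    negation_probability: float = 0.3
    or_branch_probability: float = 0.3

    def __post_init__(self) -> None:
        if min(self.n_stimuli, self.n_tfs, self.n_genes) < 0:
            raise ValueError("counts must be nonnegative")
        for p in (self.negation_probability, self.or_branch_probability):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.max_conjunction_arity < 1:
            raise ValueError("max_conjunction_arity must be >= 1")


def random_trn(config: GeneratorConfig) -> RegulatoryModel:
    """Seeded layered regulatory model: stimuli regulate TFs, TFs (and
    stimuli) regulate genes; one rule per non-stimulus component, with
    optional OR branches and negated literals."""
    rng = random.Random(config.seed)
    stimuli = [f"S{i+1}" for i in range(config.n_stimuli)]
    tfs = [f"TF{i+1}" for i in range(config.n_tfs)]
    genes = [f"G{i+1}" for i in range(config.n_genes)]
    if not stimuli:
        raise ValueError("random_trn needs at least one stimulus")

    def conjunction(pool: list[str]) -> str:
        arity = rng.randint(1, min(config.max_conjunction_arity, len(pool)))
        chosen = rng.sample(pool, arity)
        lits = [
            f"NOT {name}" if rng.random() < config.negation_probability else name
            for name in chosen
        ]
        return " AND ".join(lits)

    def expression(pool: list[str]) -> str:
        branches = [conjunction(pool)]
        while rng.random() < config.or_branch_probability:
            branches.append(conjunction(pool))
        if len(branches) == 1:
            return branches[0]
        return " OR ".join(f"({b})" for b in branches)

    lines = [f"stimuli: {', '.join(stimuli)}"]
    for tf in tfs:
        lines.append(f"{tf} <- {expression(stimuli)}")
    for gene in genes:
        pool = stimuli + tfs
        lines.append(f"{gene} <- {expression(pool)}")
    return parse_rule_text("\n".join(lines) + "\n")


# -- small metabolic fixtures ----------------------------------------------


def _net(species, columns) -> StoichiometricNetwork:
    """columns: list of (id, role, reversible, {species: coeff})."""
    sidx = {s: i for i, s in enumerate(species)}
    S = np.zeros((len(species), len(columns)), dtype=np.int64)
    reactions = []
    for j, (rid, role, rev, coeffs) in enumerate(columns):
        for s, c in coeffs.items():
            S[sidx[s], j] = c
        reactions.append(Reaction(id=rid, role=role, reversible=rev))
    return StoichiometricNetwork(S, list(species), reactions)


def fixture_networks() -> dict[str, StoichiometricNetwork]:
    """Named small networks with well-understood extreme pathway sets.

    chain          — Ein -> A -> B -> Eout: a single route.
    diamond        — two parallel A -> B conversions: two routes.
    cycle          — A <-> B internal two-cycle plus no exchange: class III only.
    chain_cycle    — the chain with an internal A -> B -> A cycle bolted on.
    reversible_pair— chain whose middle reaction is reversible (split demo).
    parallel_chains— coupled branches whose shared-signature reactions are not
                     all topologically connected (a nontrivial CoSet example).
    """
    nets: dict[str, StoichiometricNetwork] = {}
    nets["chain"] = _net(
        ["A", "B"],
        [
            ("Ein", ROLE_INPUT, False, {"A": 1}),
            ("r1", ROLE_INTERNAL, False, {"A": -1, "B": 1}),
            ("Eout", ROLE_OUTPUT, False, {"B": -1}),
        ],
    )
    nets["diamond"] = _net(
        ["A", "B"],
        [
            ("Ein", ROLE_INPUT, False, {"A": 1}),
            ("r1", ROLE_INTERNAL, False, {"A": -1, "B": 1}),
            ("r2", ROLE_INTERNAL, False, {"A": -1, "B": 1}),
            ("Eout", ROLE_OUTPUT, False, {"B": -1}),
        ],
    )
    nets["cycle"] = _net(
        ["A", "B"],
        [
            ("c1", ROLE_INTERNAL, False, {"A": -1, "B": 1}),
            ("c2", ROLE_INTERNAL, False, {"B": -1, "A": 1}),
        ],
    )
    nets["chain_cycle"] = _net(
        ["A", "B", "C"],
        [
            ("Ein", ROLE_INPUT, False, {"A": 1}),
            ("r1", ROLE_INTERNAL, False, {"A": -1, "B": 1}),
            ("Eout", ROLE_OUTPUT, False, {"B": -1}),
            ("c1", ROLE_INTERNAL, False, {"B": -1, "C": 1}),
            ("c2", ROLE_INTERNAL, False, {"C": -1, "B": 1}),
        ],
    )
    nets["reversible_pair"] = _net(
        ["A", "B"],
        [
            ("Ein", ROLE_INPUT, False, {"A": 1}),
            ("r1", ROLE_INTERNAL, True, {"A": -1, "B": 1}),
            ("Eout", ROLE_OUTPUT, False, {"B": -1}),
        ],
    )
    # a split feeds two coupled branches; the A->B step has two alternative
    # routes, so {Ein, split, r2, Eout_B, Eout_D} share one participation
    # signature while Eout_B shares no species with the rest of that CoSet —
    # a correlated set that is NOT topologically connected:
    nets["parallel_chains"] = _net(
        ["X", "A", "B", "C", "D"],
        [
            ("Ein", ROLE_INPUT, False, {"X": 1}),
            ("split", ROLE_INTERNAL, False, {"X": -1, "A": 1, "C": 1}),
            ("r1a", ROLE_INTERNAL, False, {"A": -1, "B": 1}),
            ("r1b", ROLE_INTERNAL, False, {"A": -1, "B": 1}),
            ("r2", ROLE_INTERNAL, False, {"C": -1, "D": 1}),
            ("Eout_B", ROLE_OUTPUT, False, {"B": -1}),
            ("Eout_D", ROLE_OUTPUT, False, {"D": -1}),
        ],
    )
    return nets


def random_network(
    seed: int,
    n_species: int = 4,
    n_internal: int = 6,
    n_exchange: int = 3,
    max_coeff: int = 2,
) -> StoichiometricNetwork:
    """Seeded random integer stoichiometric network for oracle cross-checks.

    Internal columns get 2-3 nonzero entries with mixed signs; exchange
    columns are single-entry sources/sinks. Sizes default to well inside the
    brute-force oracle's reach.
    """
    rng = np.random.default_rng(seed)
    species = [f"M{i+1}" for i in range(n_species)]
    columns = []
    for j in range(n_internal):
        k = int(rng.integers(2, min(3, n_species) + 1))
        rows = rng.choice(n_species, size=k, replace=False)
        coeffs = {}
        signs = [-1, 1] + [int(rng.choice([-1, 1])) for _ in range(k - 2)]
        for r, sg in zip(rows, signs):
            coeffs[species[r]] = sg * int(rng.integers(1, max_coeff + 1))
        columns.append((f"r{j+1}", ROLE_INTERNAL, False, coeffs))
    for j in range(n_exchange):
        r = int(rng.integers(0, n_species))
        if j % 2 == 0:
            columns.append((f"Ein{j+1}", ROLE_INPUT, False, {species[r]: 1}))
        else:
            columns.append((f"Eout{j+1}", ROLE_OUTPUT, False, {species[r]: -1}))
    return _net(species, columns)
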