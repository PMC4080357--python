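"""Extreme-pathway analysis of transcriptional regulatory networks.

Two equivalent routes to the complete ExPa set of a Boolean regulatory model:

1. **Direct** (:func:`compute_trn_expa_set`): enumerate once over the
   augmented matrix R*_new = [R | E_new], whose two input columns per stimulus
   (presence, absence) cover every environment simultaneously.  The null space
   then contains spurious rays that draw on both inputs of the same stimulus —
   a stimulus cannot be both present and absent — and these are removed by
   :func:`filter_conflicting_inputs`.

2. **Per-environment sweep** (:func:`enumerate_by_environments`): enumerate
   separately for each of the 2^n environments over R*_i = [R | E_i], then
   expand each pathway's input block from n to 2n slots
   (:func:`normalize_expa`) so pathways from different environments become
   comparable, and take the union.

:func:`verify_equivalence` checks computationally that both routes produce
the same normalized set — the correctness argument for the direct method.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .cone import ExPaSet, classify_pathways, enumerate_extreme_pathways
from .network import StoichiometricNetwork
from .regulatory import (
    EnvironmentAssignment,
    RegulatoryModel,
    assemble_ri,
    assemble_rnew,
)

ENV_SWEEP_MAX = 12  # 2^12 = 4096 enumerations: the sweep stays desk-scale

PROVENANCE_DIRECT = "direct"
PROVENANCE_UNION = "per-environment union"


@dataclass
class ExPaUniverse:
    """The feasible ExPa set of a TRN plus bookkeeping about what was removed."""

    network: StoichiometricNetwork  # R*_new layout (defines vector indexing)
    feasible: list[tuple[int, ...]]
    removed_conflicting: list[tuple[int, ...]] = field(default_factory=list)
    n_raw: int = 0
    n_class3: int = 0
    provenance: str = PROVENANCE_DIRECT

    @property
    def n_feasible(self) -> int:
        return len(self.feasible)

    def feasible_set(self) -> set[tuple[int, ...]]:
        return set(self.feasible)

    def as_expa_set(self) -> ExPaSet:
        return ExPaSet.from_vectors(self.network, self.feasible)

    def summary(self) -> dict:
        return {
            "provenance": self.provenance,
            "raw": self.n_raw,
            "class3_removed": self.n_class3,
            "conflicting_removed": len(self.removed_conflicting),
            "feasible": self.n_feasible,
        }


def _input_pairs(net: StoichiometricNetwork) -> list[tuple[str, int, int]]:
    """(stimulus, presence column, absence column) for each stimulus of R*_new."""
    pres: dict[str, int] = {}
    absn: dict[str, int] = {}
    for j, r in enumerate(net.reactions):
        if r.stimulus is None:
            continue
        (pres if r.state == "present" else absn)[r.stimulus] = j
    return [(s, pres[s], absn[s]) for s in pres if s in absn]


def filter_conflicting_inputs(
    vectors, net: StoichiometricNetwork
) -> tuple[list[tuple[int, ...]], list[tuple[int, ...]]]:
    """Partition pathway vectors into (feasible, removed).

    A vector is removed iff it carries flux on both the presence and the
    absence input of the same stimulus — a state in which the stimulus is
    simultaneously present and absent, which no real environment realizes.
    """
    pairs = _input_pairs(net)
    feasible, removed = [], []
    for v in vectors:
        v = tuple(int(x) for x in v)
        if any(v[p] and v[a] for _, p, a in pairs):
            removed.append(v)
        else:
            feasible.append(v)
    return feasible, removed


def compute_trn_expa_set(model: RegulatoryModel) -> ExPaUniverse:
    """Direct route: enumerate over R*_new, drop internal cycles, filter conflicts."""
    net = assemble_rnew(model)
    raw = enumerate_extreme_pathways(net)
    kept = classify_pathways(raw)
    feasible, removed = filter_conflicting_inputs((p.flux for p in kept), net)
    return ExPaUniverse(
        network=net,
        feasible=sorted(feasible),
        removed_conflicting=sorted(removed),
        n_raw=len(raw),
        n_class3=kept.n_class3_removed,
        provenance=PROVENANCE_DIRECT,
    )


def normalize_expa(
    model: RegulatoryModel, flux, env: EnvironmentAssignment
) -> tuple[int, ...]:
    """Expand a per-environment pathway's input block from n to 2n slots.

    The single input column of stimulus e routes its flux to the presence slot
    when e is present in ``env`` and to the absence slot when absent; zero
    flux stays zero in both slots.  Internal and output entries are copied
    unchanged, so the result is indexed like an R*_new pathway.  Input fluxes
    are not rescaled: they carry the integer demand of the downstream
    conjunctions.
    """
    model.validate_environment(env)
    n = model.n_stimuli
    flux = [int(x) for x in flux]
    base = flux[: len(flux) - n]  # internal + output block
    inputs = flux[len(flux) - n:]
    pres = [0] * n
    absn = [0] * n
    for e, sid in enumerate(model.stimuli):
        if inputs[e] == 0:
            continue
        if env[sid]:
            pres[e] = inputs[e]
        else:
            absn[e] = inputs[e]
    return tuple(base + pres + absn)


def project_expa(model: RegulatoryModel, flux, env: EnvironmentAssignment) -> tuple[int, ...]:
    """Inverse of :func:`normalize_expa` for a pathway realizable in ``env``.

    Collapses the 2n input slots back to n; raises if the pathway uses an
    input inconsistent with the environment (flux on the presence slot of an
    absent stimulus or vice versa).
    """
    model.validate_environment(env)
    n = model.n_stimuli
    flux = [int(x) for x in flux]
    base = flux[: len(flux) - 2 * n]
    pres = flux[len(flux) - 2 * n: len(flux) - n]
    absn = flux[len(flux) - n:]
    inputs = [0] * n
    for e, sid in enumerate(model.stimuli):
        if pres[e] and not env[sid]:
            raise ValueError(f"pathway draws presence input of absent stimulus {sid!r}")
        if absn[e] and env[sid]:
            raise ValueError(f"pathway draws absence input of present stimulus {sid!r}")
        inputs[e] = pres[e] or absn[e]
    return tuple(base + inputs)


def transform_ri_hat(
    model: RegulatoryModel, env: EnvironmentAssignment
) -> StoichiometricNetwork:
    """Build R-hat*_i: R*_new with the environment-incompatible input columns zeroed.

    For a present stimulus the absence input column becomes all-zero (and its
    flux is pinned to zero); for an absent stimulus the presence column is
    zeroed.  The result is a sub-network of R*_new, so its pathways are a
    subset of R*_new's — the structural half of the equivalence argument.
    """
    model.validate_environment(env)
    net = assemble_rnew(model)
    S = net.S.copy()
    pinned = set(net.pinned_zero)
    for j, r in enumerate(net.reactions):
        if r.stimulus is None:
            continue
        if (r.state == "present") != env[r.stimulus]:
            S[:, j] = 0
            pinned.add(r.id)
    return StoichiometricNetwork(S, list(net.species), list(net.reactions),
                                 pinned_zero=frozenset(pinned))


def iter_environments(model: RegulatoryModel):
    """All 2^n total environment assignments, in a fixed deterministic order."""
    stimuli = model.stimuli
    for bits in itertools.product((True, False), repeat=len(stimuli)):
        yield dict(zip(stimuli, bits))


def enumerate_by_environments(model: RegulatoryModel) -> ExPaUniverse:
    """Oracle route: sweep all 2^n environments, normalize, and take the union."""
    n = model.n_stimuli
    if n > ENV_SWEEP_MAX:
        raise ValueError(
            f"environment sweep limited to {ENV_SWEEP_MAX} stimuli (got {n}); "
            "use compute_trn_expa_set for the direct method"
        )
    net_new = assemble_rnew(model)
    union: set[tuple[int, ...]] = set()
    n_raw = 0
    n_class3 = 0
    for env in iter_environments(model):
        ri = assemble_ri(model, env)
        raw = enumerate_extreme_pathways(ri)
        kept = classify_pathways(raw)
        n_raw += len(raw)
        n_class3 += kept.n_class3_removed
        for p in kept:
            union.add(normalize_expa(model, p.flux, env))
    return ExPaUniverse(
        network=net_new,
        feasible=sorted(union),
        n_raw=n_raw,
        n_class3=n_class3,
        provenance=PROVENANCE_UNION,
    )


@dataclass
class EquivalenceReport:
    """Outcome of comparing the direct set against the per-environment union."""

    equal: bool
    direct: ExPaUniverse
    union: ExPaUniverse
    only_direct: list[tuple[int, ...]]
    only_union: list[tuple[int, ...]]

    def summary(self) -> dict:
        return {
            "equal": self.equal,
            "direct_feasible": self.direct.n_feasible,
            "union_feasible": self.union.n_feasible,
            "only_direct": len(self.only_direct),
            "only_union": len(self.only_union),
        }


def verify_equivalence(model: RegulatoryModel) -> EquivalenceReport:
    """Check that the direct (filtered) set equals the per-environment union."""
    direct = compute_trn_expa_set(model)
    union = enumerate_by_environments(model)
    d, u = direct.feasible_set(), union.feasible_set()
    return EquivalenceReport(
        equal=d == u,
        direct=direct,
        union=union,
        only_direct=sorted(d - u),
        only_union=sorted(u - d),
    )
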