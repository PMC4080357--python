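"""Stoichiometric network container and text-format I/O.

A network is an integer matrix ``S`` (rows = chemical species or, for
regulatory models, component states; columns = reactions) plus per-reaction
metadata: its role (internal, exchange input, exchange output), reversibility,
and provenance.  Exchange reactions connect the system to its surroundings and
are what distinguishes a thermodynamically meaningful pathway from an internal
cycle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

ROLE_INTERNAL = "internal"
ROLE_INPUT = "exchange-input"
ROLE_OUTPUT = "exchange-output"
ROLES = (ROLE_INTERNAL, ROLE_INPUT, ROLE_OUTPUT)


@dataclass(frozen=True)
class Reaction:
    """Metadata for one column of the stoichiometric matrix.

    ``stimulus``/``state`` identify environment-input columns of compiled
    regulatory models; ``split_of``/``direction`` link the forward/backward
    halves of a split reversible reaction; ``contradictory`` marks reactions
    compiled from logically contradictory rule conjunctions.
    """

    id: str
    role: str = ROLE_INTERNAL
    reversible: bool = False
    provenance: str = ""
    contradictory: bool = False
    stimulus: str | None = None
    state: str | None = None  # "present" | "absent" for env inputs
    split_of: str | None = None
    direction: str | None = None  # "fwd" | "bwd"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown reaction role {self.role!r}")
        if self.reversible and self.role != ROLE_INTERNAL:
            raise ValueError(f"reaction {self.id!r}: only internal reactions may be reversible")


@dataclass
class StoichiometricNetwork:
    """Integer stoichiometric matrix with species and reaction metadata.

    ``pinned_zero`` lists reaction ids constrained to zero flux (used when a
    column of a regulatory state matrix is zeroed rather than removed, so
    pathway vectors keep a fixed layout).
    """

    S: np.ndarray
    species: list[str]
    reactions: list[Reaction]
    pinned_zero: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=np.int64)
        if self.S.ndim != 2:
            raise ValueError("S must be a 2-D matrix")
        m, n = self.S.shape
        if m != len(self.species):
            raise ValueError(f"S has {m} rows but {len(self.species)} species given")
        if n != len(self.reactions):
            raise ValueError(f"S has {n} columns but {len(self.reactions)} reactions given")
        ids = [r.id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate reaction ids")
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species ids")
        unknown = self.pinned_zero - set(ids)
        if unknown:
            raise ValueError(f"pinned_zero references unknown reactions {sorted(unknown)}")

    # -- basic queries ------------------------------------------------------

    @property
    def n_species(self) -> int:
        return self.S.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.S.shape[1]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction_index(self, rid: str) -> int:
        try:
            return self.reaction_ids.index(rid)
        except ValueError:
            raise KeyError(f"no reaction {rid!r}") from None

    def columns_with_role(self, *roles: str) -> list[int]:
        return [j for j, r in enumerate(self.reactions) if r.role in roles]

    @property
    def exchange_columns(self) -> list[int]:
        return self.columns_with_role(ROLE_INPUT, ROLE_OUTPUT)

    def has_reversible(self) -> bool:
        return any(r.reversible for r in self.reactions)

    # -- I/O ----------------------------------------------------------------

    def to_tsv(self, matrix_path: str | Path, metadata_path: str | Path) -> None:
        """Write the matrix and reaction metadata as two TSV files."""
        df = pd.DataFrame(self.S, index=self.species, columns=self.reaction_ids)
        df.to_csv(matrix_path, sep="\t", lineterminator="\n")
        meta = pd.DataFrame(
            {
                "id": self.reaction_ids,
                "role": [r.role for r in self.reactions],
                "reversible": [int(r.reversible) for r in self.reactions],
                "provenance": [r.provenance for r in self.reactions],
                "contradictory": [int(r.contradictory) for r in self.reactions],
                "stimulus": [r.stimulus or "" for r in self.reactions],
                "state": [r.state or "" for r in self.reactions],
            }
        )
        meta.to_csv(metadata_path, sep="\t", index=False, lineterminator="\n")

    @classmethod
    def from_tsv(cls, matrix_path: str | Path, metadata_path: str | Path) -> "StoichiometricNetwork":
        df = pd.read_csv(matrix_path, sep="\t", index_col=0)
        meta = pd.read_csv(metadata_path, sep="\t", keep_default_na=False)
        order = list(df.columns)
        meta = meta.set_index("id").loc[order].reset_index()
        reactions = [
            Reaction(
                id=str(row["id"]),
                role=str(row["role"]),
                reversible=bool(int(row.get("reversible", 0))),
                provenance=str(row.get("provenance", "")),
                contradictory=bool(int(row.get("contradictory", 0))),
                stimulus=str(row["stimulus"]) or None if "stimulus" in meta else None,
                state=str(row["state"]) or None if "state" in meta else None,
            )
            for _, row in meta.iterrows()
        ]
        return cls(df.to_numpy(dtype=np.int64), [str(s) for s in df.index], reactions)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "species": self.species,
            "reactions": [
                {
                    "id": r.id,
                    "role": r.role,
                    "reversible": r.reversible,
                    "provenance": r.provenance,
                    "contradictory": r.contradictory,
                    "stimulus": r.stimulus,
                    "state": r.state,
                }
                for r in self.reactions
            ],
            "S": self.S.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "StoichiometricNetwork":
        payload = json.loads(Path(path).read_text())
        reactions = [
            Reaction(
                id=r["id"],
                role=r.get("role", ROLE_INTERNAL),
                reversible=r.get("reversible", False),
                provenance=r.get("provenance", ""),
                contradictory=r.get("contradictory", False),
                stimulus=r.get("stimulus"),
                state=r.get("state"),
            )
            for r in payload["reactions"]
        ]
        return cls(np.array(payload["S"], dtype=np.int64), payload["species"], reactions)


def split_reversible(net: StoichiometricNetwork) -> StoichiometricNetwork:
    """Replace each reversible reaction by an irreversible forward/backward pair.

    Both halves get nonnegative flux; the backward column is the exact negation
    of the forward one. Irreversible networks are returned unchanged.
    """
    if not net.has_reversible():
        return net
    cols: list[np.ndarray] = []
    reactions: list[Reaction] = []
    for j, r in enumerate(net.reactions):
        if not r.reversible:
            cols.append(net.S[:, j])
            reactions.append(r)
            continue
        fwd = replace(r, id=f"{r.id}_fwd", reversible=False, split_of=r.id, direction="fwd")
        bwd = replace(r, id=f"{r.id}_bwd", reversible=False, split_of=r.id, direction="bwd")
        cols.append(net.S[:, j])
        reactions.append(fwd)
        cols.append(-net.S[:, j])
        reactions.append(bwd)
    return StoichiometricNetwork(np.column_stack(cols), list(net.species), reactions,
                                 pinned_zero=net.pinned_zero)


def read_sbml(path: str | Path) -> StoichiometricNetwork:
    """Import a metabolic model from SBML (requires the optional `cobra` extra).

    Species map to rows, reactions to columns; boundary/exchange reactions are
    assigned exchange roles by the sign of their net stoichiometry. Fractional
    stoichiometries are scaled to integers per column.
    """
    try:
        import cobra  # noqa: PLC0415
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("SBML import requires the 'cobra' package (pip install expanet[sbml])") from exc
    from fractions import Fraction
    from math import lcm

    model = cobra.io.read_sbml_model(str(path))
    species = [m.id for m in model.metabolites]
    sidx = {s: i for i, s in enumerate(species)}
    cols, reactions = [], []
    for rxn in model.reactions:
        col = np.zeros(len(species), dtype=np.int64)
        fracs = {m.id: Fraction(c).limit_denominator(10**6) for m, c in rxn.metabolites.items()}
        denom = lcm(*(f.denominator for f in fracs.values())) if fracs else 1
        for mid, f in fracs.items():
            col[sidx[mid]] = int(f * denom)
        if rxn.boundary:
            role = ROLE_INPUT if all(c > 0 for c in fracs.values()) else ROLE_OUTPUT
        else:
            role = ROLE_INTERNAL
        reactions.append(Reaction(id=rxn.id, role=role,
                                  reversible=role == ROLE_INTERNAL and rxn.reversibility))
        cols.append(col)
    return StoichiometricNetwork(np.column_stack(cols) if cols else np.zeros((len(species), 0), dtype=np.int64),
                                 species, reactions)
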