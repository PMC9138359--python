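"""In-memory representation of a constraint-based metabolic model.

A :class:`MetabolicModel` holds the stoichiometric matrix ``S`` (metabolites x
reactions), per-reaction bounds, and the structural classification used to
decide which reactions are legal deletion candidates.  Flux units follow the
field convention: mmol/gDCW/h for metabolic reactions, 1/h for biomass.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from scipy import sparse

from .errors import ModelFormatError


class ReactionCategory(str, Enum):
    """Structural role of a reaction, assigned at load time.

    ``internal`` reactions are deletion candidates; ``exchange`` and plain
    ``transport`` reactions are not.  ``abc_transport`` (when gene-associated)
    and ``pts`` reactions are transport processes that are nevertheless
    deletable, since they correspond to knockout-accessible enzyme systems.
    ``biomass`` and ``atp_maintenance`` are never deletable.
    """

    INTERNAL = "internal"
    EXCHANGE = "exchange"
    TRANSPORT = "transport"
    ABC_TRANSPORT = "abc_transport"
    PTS = "pts"
    BIOMASS = "biomass"
    ATP_MAINTENANCE = "atp_maintenance"


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str
    name: str = ""


@dataclass
class Reaction:
    """One column of S: stoichiometry maps metabolite id -> coefficient."""

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float
    upper_bound: float
    has_gpr: bool = False
    category: ReactionCategory = ReactionCategory.INTERNAL
    name: str = ""
    subsystem: str = ""

    @property
    def reversible(self) -> bool:
        # Reversibility is derived from the bounds, not from file metadata,
        # so the irreversible/reversible partition always matches the LP.
        return self.lower_bound < 0

    def validate(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelFormatError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        if not self.stoichiometry:
            raise ModelFormatError(f"reaction {self.id!r} has empty stoichiometry")


@dataclass
class MetabolicModel:
    """Stoichiometric model with named physiological anchor reactions.

    ``glucose_exchange_id``, ``oxygen_exchange_id`` and ``atp_maintenance_id``
    may be ``None`` when the model (e.g. a synthetic test network) has no such
    reaction; the corresponding physiological constraint is then skipped.
    """

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_reaction_id: str
    glucose_exchange_id: str | None = None
    oxygen_exchange_id: str | None = None
    atp_maintenance_id: str | None = None
    id: str = "model"
    _S: sparse.csc_matrix | None = field(default=None, repr=False, compare=False)

    # -- indexing -----------------------------------------------------------

    @property
    def metabolite_index(self) -> dict[str, int]:
        return {m.id: i for i, m in enumerate(self.metabolites)}

    @property
    def reaction_index(self) -> dict[str, int]:
        return {r.id: j for j, r in enumerate(self.reactions)}

    def reaction(self, rid: str) -> Reaction:
        try:
            return self.reactions[self.reaction_index[rid]]
        except KeyError:
            raise KeyError(f"no reaction {rid!r} in model {self.id!r}") from None

    # -- stoichiometric matrix ---------------------------------------------

    def stoichiometric_matrix(self) -> sparse.csc_matrix:
        """|N| x |M| sparse matrix; cached, shared across bound-only copies."""
        if self._S is None:
            midx = self.metabolite_index
            rows, cols, data = [], [], []
            for j, rxn in enumerate(self.reactions):
                for mid, coeff in rxn.stoichiometry.items():
                    try:
                        rows.append(midx[mid])
                    except KeyError:
                        raise ModelFormatError(
                            f"reaction {rxn.id!r} references unknown metabolite {mid!r}"
                        ) from None
                    cols.append(j)
                    data.append(float(coeff))
            self._S = sparse.csc_matrix(
                (data, (rows, cols)),
                shape=(len(self.metabolites), len(self.reactions)),
            )
        return self._S

    # -- lifecycle ----------------------------------------------------------

    def copy(self) -> "MetabolicModel":
        """Copy with independent Reaction objects (bounds may be retuned).

        Stoichiometry dicts and the cached S are shared: policy application
        and deletions only ever touch bounds.
        """
        new_reactions = [replace(r, stoichiometry=r.stoichiometry) for r in self.reactions]
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=new_reactions,
            biomass_reaction_id=self.biomass_reaction_id,
            glucose_exchange_id=self.glucose_exchange_id,
            oxygen_exchange_id=self.oxygen_exchange_id,
            atp_maintenance_id=self.atp_maintenance_id,
            id=self.id,
            _S=self._S,
        )

    def validate(self) -> None:
        if not self.reactions:
            raise ModelFormatError("model has no reactions")
        seen_m: set[str] = set()
        for m in self.metabolites:
            if m.id in seen_m:
                raise ModelFormatError(f"duplicate metabolite id {m.id!r}")
            if not m.compartment:
                raise ModelFormatError(f"metabolite {m.id!r} has empty compartment")
            seen_m.add(m.id)
        seen_r: set[str] = set()
        for r in self.reactions:
            if r.id in seen_r:
                raise ModelFormatError(f"duplicate reaction id {r.id!r}")
            seen_r.add(r.id)
            r.validate()
        for label, rid in [
            ("biomass_reaction_id", self.biomass_reaction_id),
            ("glucose_exchange_id", self.glucose_exchange_id),
            ("oxygen_exchange_id", self.oxygen_exchange_id),
            ("atp_maintenance_id", self.atp_maintenance_id),
        ]:
            if rid is not None and rid not in seen_r:
                raise ModelFormatError(f"{label}={rid!r} not found among reactions")
        # every metabolite row must touch at least one reaction
        S = self.stoichiometric_matrix()
        row_counts = np.diff(sparse.csr_matrix(S).indptr)
        if np.any(row_counts == 0):
            orphans = [self.metabolites[i].id for i in np.flatnonzero(row_counts == 0)]
            raise ModelFormatError(f"metabolites participate in no reaction: {orphans}")

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub
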