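"""Domain types for stoichiometric models and structural operations.

A genome-scale metabolic model is represented as a list of metabolites
(species, compartmented), a list of reactions (signed stoichiometries with
flux bounds and gene associations), and a designated biomass reaction whose
flux is the specific growth rate (1/h).  The stoichiometric matrix S has one
row per compartmented metabolite and one column per reaction; steady-state
flux vectors satisfy S v = 0 within bounds.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Magnitude used for "free" (unconstrained) fluxes, mmol/gDW/h.  The
#: analyses must be insensitive to this value as long as it exceeds every
#: physiologically attainable rate; the test suite asserts invariance
#: between 1000 and 10000 on toy models.
FREE_FLUX_BOUND = 1000.0

COMPARTMENTS = {"c": "cytosol", "p": "periplasm", "e": "extracellular"}

REACTION_CATEGORIES = ("intracellular", "transport", "exchange")


class ModelStructureError(ValueError):
    """Raised when a model violates a structural invariant."""


class UnknownIdError(KeyError):
    """Raised on lookup of a reaction/gene/metabolite id absent from the model."""


@dataclass(frozen=True)
class FluxBounds:
    """Closed flux interval in mmol/gDW/h (lower <= upper)."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ModelStructureError(
                f"lower bound {self.lower} exceeds upper bound {self.upper}"
            )

    @classmethod
    def free(cls, magnitude: float = FREE_FLUX_BOUND) -> "FluxBounds":
        return cls(-magnitude, magnitude)

    @classmethod
    def forward(cls, magnitude: float = FREE_FLUX_BOUND) -> "FluxBounds":
        return cls(0.0, magnitude)

    @classmethod
    def fixed(cls, value: float) -> "FluxBounds":
        return cls(value, value)


@dataclass(frozen=True)
class Metabolite:
    """A compartmented chemical species.

    ``n_carbon`` is the number of carbon atoms per molecule and is required
    for carbon-molar yield arithmetic on carbon-bearing species (glycogen is
    treated as its monomer C6H10O5, n_carbon = 6).
    """

    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None
    n_carbon: int = 0

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ModelStructureError(
                f"unknown compartment {self.compartment!r} for metabolite "
                f"{self.id!r}; expected one of {sorted(COMPARTMENTS)}"
            )
        if self.n_carbon < 0:
            raise ModelStructureError(f"negative carbon count for {self.id!r}")

    @property
    def species_id(self) -> str:
        """Compartment-suffixed id, unique within a model."""
        return f"{self.id}[{self.compartment}]"


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric conversion between compartmented species.

    ``stoichiometry`` maps species ids (``met[c]`` form) to signed
    coefficients, negative for consumed species.  Reversibility is encoded
    solely through the bounds: a single matrix column with a negative lower
    bound, never duplicated forward/backward columns.
    """

    id: str
    stoichiometry: dict[str, float]
    name: str = ""
    reversible: bool = False
    bounds: FluxBounds | None = None
    gene_association: frozenset[str] = frozenset()
    subsystem: str = ""

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ModelStructureError(f"reaction {self.id!r} has empty stoichiometry")
        if self.bounds is None:
            default = FluxBounds.free() if self.reversible else FluxBounds.forward()
            object.__setattr__(self, "bounds", default)
        if not self.reversible and self.bounds.lower < 0:
            raise ModelStructureError(
                f"irreversible reaction {self.id!r} has negative lower bound "
                f"{self.bounds.lower}"
            )
        object.__setattr__(self, "gene_association", frozenset(self.gene_association))

    def compartments(self, model: "StoichiometricModel") -> set[str]:
        return {model.metabolite(s).compartment for s in self.stoichiometry}

    def category(self, model: "StoichiometricModel") -> str:
        """One of intracellular / transport / exchange.

        An exchange reaction is a boundary pseudo-reaction with a single
        species (the implicit external pool is not represented as a row); a
        transport reaction spans more than one compartment; everything else
        is intracellular.
        """
        if len(self.stoichiometry) == 1:
            return "exchange"
        if len(self.compartments(model)) > 1:
            return "transport"
        return "intracellular"


@dataclass(frozen=True)
class FluxSolution:
    """Result of one FBA solve.

    ``fluxes`` is indexed by reaction id; biomass flux is in 1/h, all other
    fluxes in mmol/gDW/h.  ``status`` is one of optimal / infeasible /
    unbounded / failed.
    """

    fluxes: pd.Series
    objective_value: float
    status: str
    diagnostics: str = ""

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class StoichiometricModel:
    """Metabolites + reactions + biomass objective."""

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_reaction_id: str
    id: str = "model"

    def __post_init__(self) -> None:
        self._met_index = {m.species_id: m for m in self.metabolites}
        if len(self._met_index) != len(self.metabolites):
            seen: set[str] = set()
            dup = next(
                m.species_id
                for m in self.metabolites
                if m.species_id in seen or seen.add(m.species_id)
            )
            raise ModelStructureError(f"duplicate metabolite species id {dup!r}")
        self._rxn_index = {r.id: r for r in self.reactions}
        if len(self._rxn_index) != len(self.reactions):
            raise ModelStructureError("duplicate reaction ids in model")
        for rxn in self.reactions:
            for sid in rxn.stoichiometry:
                if sid not in self._met_index:
                    raise ModelStructureError(
                        f"reaction {rxn.id!r} references undeclared metabolite {sid!r}"
                    )
        if self.biomass_reaction_id not in self._rxn_index:
            raise ModelStructureError(
                f"biomass reaction {self.biomass_reaction_id!r} not in model"
            )

    # -- lookups -----------------------------------------------------------

    def metabolite(self, species_id: str) -> Metabolite:
        try:
            return self._met_index[species_id]
        except KeyError:
            raise UnknownIdError(f"unknown metabolite {species_id!r}") from None

    def reaction(self, reaction_id: str) -> Reaction:
        try:
            return self._rxn_index[reaction_id]
        except KeyError:
            raise UnknownIdError(f"unknown reaction {reaction_id!r}") from None

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def species_ids(self) -> list[str]:
        return [m.species_id for m in self.metabolites]

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for r in self.reactions for g in r.gene_association)

    @property
    def objective(self) -> pd.Series:
        """Objective vector c over reactions (1 on the biomass reaction)."""
        c = pd.Series(0.0, index=self.reaction_ids)
        c[self.biomass_reaction_id] = 1.0
        return c

    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.category(self) == "exchange"]

    # -- bound manipulation -------------------------------------------------

    def with_bounds(self, bound_map: dict[str, FluxBounds]) -> "StoichiometricModel":
        """Copy of the model with the listed reactions' bounds replaced."""
        for rid in bound_map:
            if rid not in self._rxn_index:
                raise UnknownIdError(f"unknown reaction {rid!r}")
        new_reactions = [
            replace(r, bounds=bound_map[r.id], reversible=bound_map[r.id].lower < 0)
            if r.id in bound_map
            else r
            for r in self.reactions
        ]
        return StoichiometricModel(
            metabolites=self.metabolites,
            reactions=new_reactions,
            biomass_reaction_id=self.biomass_reaction_id,
            id=self.id,
        )

    def copy(self) -> "StoichiometricModel":
        return copy.deepcopy(self)


# -- operations -------------------------------------------------------------


def build_stoichiometric_matrix(model: StoichiometricModel) -> pd.DataFrame:
    """Assemble S as a DataFrame: rows = species ids, columns = reaction ids.

    Entry (m, r) is the signed coefficient of m in r; columns follow
    model.reactions order.  Exchange reactions appear as single-entry
    columns (the implicit boundary pool has no row).
    """
    S = np.zeros((len(model.metabolites), len(model.reactions)))
    row = {sid: i for i, sid in enumerate(model.species_ids)}
    for j, rxn in enumerate(model.reactions):
        for sid, coef in rxn.stoichiometry.items():
            if sid not in row:
                raise ModelStructureError(
                    f"reaction {rxn.id!r} references undeclared metabolite {sid!r}"
                )
            S[row[sid], j] = coef
    return pd.DataFrame(S, index=model.species_ids, columns=model.reaction_ids)


def knock_out_reactions(
    model: StoichiometricModel, reaction_ids: set[str] | frozenset[str]
) -> StoichiometricModel:
    """Return a copy with the listed reactions constrained to zero flux.

    The input model is not modified; knocking out an already-blocked
    reaction is a no-op.  Adding the (0, 0) bounds only shrinks the feasible
    polytope, so no subsequent FBA optimum can increase.
    """
    return model.with_bounds({rid: FluxBounds.fixed(0.0) for rid in reaction_ids})


def genes_to_reactions(
    model: StoichiometricModel, gene_ids: set[str] | frozenset[str]
) -> frozenset[str]:
    """Reactions disabled by deleting any of ``gene_ids``.

    Any-gene-disables semantics: a reaction is disabled as soon as one of
    its associated genes is knocked out (no AND/OR boolean rules), and one
    gene may disable several reactions.
    """
    known = model.genes
    unknown = set(gene_ids) - known
    if unknown:
        raise UnknownIdError(
            f"unknown gene(s) {sorted(unknown)}; model defines {len(known)} genes"
        )
    gene_ids = set(gene_ids)
    return frozenset(
        r.id for r in model.reactions if r.gene_association & gene_ids
    )


def steady_state_residual(model: StoichiometricModel, fluxes: pd.Series) -> float:
    """max |S v| over metabolite rows for a candidate flux vector."""
    S = build_stoichiometric_matrix(model)
    v = fluxes.reindex(S.columns).to_numpy()
    return float(np.max(np.abs(S.to_numpy() @ v)))
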