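"""Strain design: flux response analysis, C-mol yields, knockout screening.

Flux response analysis (FRA) pins one reaction's flux to each value of a
grid, re-maximizes biomass, and reports the FVA range of a target export
at each constrained optimum — revealing reactions whose artificial
activation or repression would enhance production.

Knockout screening enumerates gene deletions (any associated gene disables
a reaction), evaluates growth and guaranteed product yield for each
induced reaction deletion set, and ranks designs by carbon-molar yield:
the carbon exported in the product per carbon of CO2 fixed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import StoichiometricModel, genes_to_reactions, knock_out_reactions
from .fba import FluxRange, flux_variability, pin_reaction, solve_fba
from .scenarios import GROWTH_THRESHOLD, find_exchange

logger = logging.getLogger(__name__)

#: changes in guaranteed production smaller than this are ties
RESPONSE_TIE_THRESHOLD = 1e-6
#: the combinatorial screen refuses deeper searches by default: the LP
#: count grows as (genes choose k) and k = 3 is already the practical limit
MAX_KNOCKOUT_DEPTH = 3


@dataclass(frozen=True)
class FluxResponsePoint:
    pinned_flux: float
    growth_rate: float
    target_range: FluxRange | None  # None = pinned value infeasible

    @property
    def feasible(self) -> bool:
        return self.target_range is not None


@dataclass(frozen=True)
class FluxResponseCurve:
    reaction_id: str
    target_export_id: str
    base_flux: float
    base_growth: float
    points: tuple[FluxResponsePoint, ...]

    @property
    def grid(self) -> list[float]:
        return [pt.pinned_flux for pt in self.points]


def flux_response_analysis(
    model: StoichiometricModel,
    reaction_id: str,
    target_export_id: str,
    n_grid: int = 21,
) -> FluxResponseCurve:
    """Sweep one reaction's pinned flux; report growth and target FVA range.

    The model must already carry its condition (bounds applied).  The grid
    spans the reaction's feasible flux interval with the biomass objective
    relaxed to [0, optimum], extended to include 0 and the base flux, so
    both repression (below base) and activation (above base) are probed.
    Pinned values that make the LP infeasible are flagged and skipped.
    """
    model.reaction(reaction_id)
    base = solve_fba(model)
    if not base.optimal:
        raise RuntimeError(f"baseline FBA not optimal: {base.status}")
    base_flux = float(base.fluxes[reaction_id])

    (span,) = flux_variability(
        model, reaction_ids=[reaction_id], fraction_of_optimum=0.0
    )
    lo = min(span.min_flux, 0.0) if model.reaction(reaction_id).bounds.lower < 0 else max(span.min_flux, 0.0)
    hi = span.max_flux
    grid = sorted(set(np.linspace(lo, hi, n_grid)) | {base_flux})

    points = []
    for value in grid:
        pinned = pin_reaction(model, reaction_id, value)
        sol = solve_fba(pinned)
        if not sol.optimal:
            points.append(FluxResponsePoint(value, float("nan"), None))
            continue
        (rng,) = flux_variability(pinned, reaction_ids=[target_export_id])
        points.append(FluxResponsePoint(value, sol.objective_value, rng))
    return FluxResponseCurve(
        reaction_id=reaction_id,
        target_export_id=target_export_id,
        base_flux=base_flux,
        base_growth=base.objective_value,
        points=tuple(points),
    )


def classify_flux_response(
    curve: FluxResponseCurve, tie: float = RESPONSE_TIE_THRESHOLD
) -> str:
    """activation_enhancing / repression_enhancing / neutral.

    Classification looks at guaranteed (FVA-minimum) target production: a
    reaction is activation-enhancing if the guaranteed production strictly
    increases as its flux is pinned above the base optimum, repression-
    enhancing if it increases below it.  Ambiguous cases pick the side with
    the larger gain.
    """
    feasible = [pt for pt in curve.points if pt.feasible]
    if len(feasible) < 3:
        raise ValueError("need at least 3 feasible grid points to classify")

    def min_prod(pt: FluxResponsePoint) -> float:
        return pt.target_range.min_flux

    base_pts = [pt for pt in feasible if abs(pt.pinned_flux - curve.base_flux) <= 1e-12]
    base_val = min_prod(base_pts[0]) if base_pts else 0.0

    above = [pt for pt in feasible if pt.pinned_flux > curve.base_flux + 1e-12]
    below = [pt for pt in feasible if pt.pinned_flux < curve.base_flux - 1e-12]

    def gain(points: list[FluxResponsePoint]) -> float:
        if not points:
            return 0.0
        return max(min_prod(pt) for pt in points) - base_val

    gain_above, gain_below = gain(above), gain(below)
    if gain_above <= tie and gain_below <= tie:
        return "neutral"
    return "activation_enhancing" if gain_above >= gain_below else "repression_enhancing"


def cmol_yield(
    target_flux: float, target_n_carbon: int, co2_uptake_flux: float
) -> float:
    """Carbon-molar yield (%): target carbon over fixed CO2 carbon.

    ``100 * target_flux * target_n_carbon / co2_uptake_flux`` with CO2
    carrying one carbon.  Undefined when nothing is fixed.
    """
    if co2_uptake_flux <= 0:
        raise ValueError(
            f"C-mol yield undefined: CO2 uptake flux is {co2_uptake_flux}"
        )
    return 100.0 * target_flux * target_n_carbon / co2_uptake_flux


@dataclass(frozen=True)
class KnockoutDesign:
    """Outcome of one knockout evaluation under a fixed condition."""

    knocked_genes: frozenset[str]
    knocked_reactions: frozenset[str]
    relative_growth: float         # % of wild-type growth
    target_yield_cmol: float       # guaranteed (FVA-min based) yield, %
    target_yield_cmol_max: float   # FVA-max based yield, %
    target_range: FluxRange | None
    growth_rate: float
    nitrogen_source: str = ""

    @property
    def yield_determined(self) -> bool:
        """False when alternate optima leave the production rate open."""
        return self.target_range is not None and self.target_range.degenerate


def _split_gene_reaction_ids(
    model: StoichiometricModel, ids: set[str] | frozenset[str]
) -> tuple[frozenset[str], frozenset[str]]:
    genes = frozenset(i for i in ids if i in model.genes)
    direct = frozenset(ids) - genes
    for rid in direct:
        model.reaction(rid)  # raises UnknownIdError for typos
    return genes, direct | genes_to_reactions(model, genes)


def evaluate_knockout_design(
    model: StoichiometricModel,
    gene_or_reaction_set: set[str] | frozenset[str],
    target_export_id: str,
    nitrogen_source: str = "",
    _wild_type_growth: float | None = None,
) -> KnockoutDesign:
    """Growth, target FVA range and C-mol yields for one deletion set.

    The model must already carry its condition.  Ids may mix genes (mapped
    to all associated reactions) and reaction ids.  Yields use the CO2
    uptake of the knockout FBA solution; the guaranteed yield uses the FVA
    minimum of the target export, the optimistic one its maximum.
    """
    genes, reactions = _split_gene_reaction_ids(model, gene_or_reaction_set)
    if _wild_type_growth is None:
        wt = solve_fba(model)
        if not wt.optimal or wt.objective_value <= GROWTH_THRESHOLD:
            raise RuntimeError("wild-type model does not grow under this condition")
        _wild_type_growth = wt.objective_value

    ko_model = knock_out_reactions(model, reactions)
    sol = solve_fba(ko_model)
    if not sol.optimal or sol.objective_value <= GROWTH_THRESHOLD:
        return KnockoutDesign(
            knocked_genes=genes,
            knocked_reactions=reactions,
            relative_growth=0.0,
            target_yield_cmol=0.0,
            target_yield_cmol_max=0.0,
            target_range=None,
            growth_rate=0.0,
            nitrogen_source=nitrogen_source,
        )
    (rng,) = flux_variability(ko_model, reaction_ids=[target_export_id])
    co2_uptake = -sol.fluxes[find_exchange(model, "co2")]
    (target_species,) = model.reaction(target_export_id).stoichiometry
    n_carbon = model.metabolite(target_species).n_carbon
    if co2_uptake > 0:
        y_min = cmol_yield(max(rng.min_flux, 0.0), n_carbon, co2_uptake)
        y_max = cmol_yield(max(rng.max_flux, 0.0), n_carbon, co2_uptake)
    else:
        y_min = y_max = 0.0  # no carbon fixed (e.g. heterotrophic control)
    return KnockoutDesign(
        knocked_genes=genes,
        knocked_reactions=reactions,
        relative_growth=100.0 * sol.objective_value / _wild_type_growth,
        target_yield_cmol=y_min,
        target_yield_cmol_max=y_max,
        target_range=rng,
        growth_rate=sol.objective_value,
        nitrogen_source=nitrogen_source,
    )


def knockout_screen(
    model: StoichiometricModel,
    target_export_id: str,
    k_max: int = 1,
    candidate_genes: list[str] | None = None,
    nitrogen_source: str = "",
    allow_deep: bool = False,
    deduplicate: bool = True,
    prune_lethal: bool = True,
) -> list[KnockoutDesign]:
    """Enumerate gene-deletion combinations up to ``k_max`` and rank designs.

    The model must already carry its condition.  Combinations inducing the
    same reaction-deletion set are evaluated once; supersets of lethal
    combinations are pruned (removing reactions only shrinks the feasible
    space, so a superset of a no-growth set cannot grow).  Designs are
    ranked by guaranteed yield desc, relative growth desc, then gene ids.
    """
    if k_max > MAX_KNOCKOUT_DEPTH and not allow_deep:
        raise ValueError(
            f"k_max={k_max} exceeds the supported depth {MAX_KNOCKOUT_DEPTH} "
            "(pass allow_deep=True to override)"
        )
    if candidate_genes is None:
        candidate_genes = sorted(model.genes)
    if not candidate_genes:
        raise ValueError("empty candidate gene set")
    unknown = set(candidate_genes) - model.genes
    if unknown:
        raise ValueError(f"candidate genes not in model: {sorted(unknown)}")

    wt = solve_fba(model)
    if not wt.optimal or wt.objective_value <= GROWTH_THRESHOLD:
        raise RuntimeError("wild-type model does not grow under this condition")

    seen_signatures: set[frozenset[str]] = set()
    lethal_combos: list[frozenset[str]] = []
    designs: list[KnockoutDesign] = []
    n_evaluated = 0
    for k in range(1, k_max + 1):
        for combo in itertools.combinations(sorted(candidate_genes), k):
            gene_set = frozenset(combo)
            if prune_lethal and any(le < gene_set for le in lethal_combos):
                continue
            signature = genes_to_reactions(model, gene_set)
            if deduplicate and signature in seen_signatures:
                continue
            seen_signatures.add(signature)
            design = evaluate_knockout_design(
                model,
                gene_set,
                target_export_id,
                nitrogen_source=nitrogen_source,
                _wild_type_growth=wt.objective_value,
            )
            n_evaluated += 1
            designs.append(design)
            if design.relative_growth == 0.0:
                lethal_combos.append(gene_set)
    logger.info(
        "knockout screen: %d combinations evaluated, %d unique signatures",
        n_evaluated,
        len(seen_signatures),
    )
    designs.sort(
        key=lambda d: (
            -d.target_yield_cmol,
            -d.relative_growth,
            tuple(sorted(d.knocked_genes)),
        )
    )
    return designs


def designs_to_frame(designs: list[KnockoutDesign]) -> pd.DataFrame:
    """Tabulate ranked knockout designs."""
    return pd.DataFrame(
        {
            "genes": [";".join(sorted(d.knocked_genes)) for d in designs],
            "reactions": [";".join(sorted(d.knocked_reactions)) for d in designs],
            "relative_growth_pct": [d.relative_growth for d in designs],
            "yield_cmol_min_pct": [d.target_yield_cmol for d in designs],
            "yield_cmol_max_pct": [d.target_yield_cmol_max for d in designs],
            "growth_rate": [d.growth_rate for d in designs],
        }
    )
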