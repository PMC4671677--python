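"""Flux balance analysis and flux variability analysis.

FBA solves the linear program

    maximize    c' v
    subject to  S v = 0,   vmin <= v <= vmax

where the objective is the biomass reaction unless stated otherwise.  FVA
re-solves, per reaction, a pair of LPs (maximize and minimize that flux)
with the biomass flux fixed at its prior optimum, exposing alternate
optima: a flux is determined at the optimum iff its FVA range is degenerate.

The LP backend is HiGHS via scipy.optimize.linprog behind a single
interface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .core import FluxBounds, FluxSolution, StoichiometricModel, build_stoichiometric_matrix

logger = logging.getLogger(__name__)

#: LP primal/dual feasibility tolerance passed to HiGHS.
LP_TOLERANCE = 1e-9
#: Acceptable max |S v| for a solution to be reported as optimal.
STEADY_STATE_TOLERANCE = 1e-6
#: Relative relaxations tried, in order, when fixing the objective at its
#: optimum makes the FVA subproblem numerically infeasible.
FVA_RELAXATIONS = (0.0, 1e-9, 1e-7)

_STATUS = {0: "optimal", 1: "failed", 2: "infeasible", 3: "unbounded", 4: "failed"}


@dataclass(frozen=True)
class FluxRange:
    """FVA min/max flux of one reaction (mmol/gDW/h) at fixed objective."""

    reaction_id: str
    min_flux: float
    max_flux: float

    @property
    def degenerate(self) -> bool:
        return abs(self.max_flux - self.min_flux) <= 1e-6


def _solve(
    S: np.ndarray,
    bounds: list[tuple[float, float]],
    c: np.ndarray,
    sense: str,
) -> tuple[str, np.ndarray | None, float, str]:
    sign = -1.0 if sense == "maximize" else 1.0
    res = linprog(
        sign * c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
        options={
            "primal_feasibility_tolerance": LP_TOLERANCE,
            "dual_feasibility_tolerance": LP_TOLERANCE,
        },
    )
    status = _STATUS.get(res.status, "failed")
    if status == "optimal":
        return status, res.x, sign * res.fun, res.message
    return status, None, float("nan"), res.message


def solve_fba(
    model: StoichiometricModel,
    objective_reaction_id: str | None = None,
    sense: str = "maximize",
) -> FluxSolution:
    """Solve the FBA linear program for the given objective reaction.

    Returns a :class:`FluxSolution` whose status faithfully reports
    infeasible/unbounded outcomes; solver failures carry diagnostics and are
    never reported as a silent zero optimum.
    """
    if sense not in ("maximize", "minimize"):
        raise ValueError(f"sense must be maximize or minimize, got {sense!r}")
    objective_reaction_id = objective_reaction_id or model.biomass_reaction_id
    model.reaction(objective_reaction_id)  # raises UnknownIdError if absent

    Sdf = build_stoichiometric_matrix(model)
    S = Sdf.to_numpy()
    bounds = [(r.bounds.lower, r.bounds.upper) for r in model.reactions]
    c = np.zeros(len(model.reactions))
    c[Sdf.columns.get_loc(objective_reaction_id)] = 1.0

    status, x, obj, message = _solve(S, bounds, c, sense)
    if status != "optimal":
        logger.warning("FBA %s on %s: %s (%s)", status, model.id, message, sense)
        return FluxSolution(
            fluxes=pd.Series(np.nan, index=Sdf.columns),
            objective_value=float("nan"),
            status=status,
            diagnostics=message,
        )
    residual = float(np.max(np.abs(S @ x)))
    if residual > STEADY_STATE_TOLERANCE:
        return FluxSolution(
            fluxes=pd.Series(x, index=Sdf.columns),
            objective_value=obj,
            status="failed",
            diagnostics=f"steady-state residual {residual:.3e} exceeds tolerance",
        )
    return FluxSolution(
        fluxes=pd.Series(x, index=Sdf.columns), objective_value=obj, status="optimal"
    )


def flux_variability(
    model: StoichiometricModel,
    objective_reaction_id: str | None = None,
    reaction_ids: list[str] | None = None,
    fraction_of_optimum: float = 1.0,
) -> list[FluxRange]:
    """FVA: per-reaction flux min/max at (a fraction of) maximal objective.

    With the default ``fraction_of_optimum = 1.0`` the objective flux is
    fixed exactly at its FBA optimum (within LP tolerance); a smaller
    fraction constrains it to ``[fraction * optimum, optimum]``.  Ranges are
    returned in the order of ``reaction_ids`` (default: all reactions).
    """
    objective_reaction_id = objective_reaction_id or model.biomass_reaction_id
    if reaction_ids is None:
        reaction_ids = model.reaction_ids
    for rid in reaction_ids:
        model.reaction(rid)

    fba = solve_fba(model, objective_reaction_id)
    if not fba.optimal:
        raise RuntimeError(
            f"FVA requires an optimal FBA solution; got {fba.status}: {fba.diagnostics}"
        )
    opt = fba.objective_value

    Sdf = build_stoichiometric_matrix(model)
    S = Sdf.to_numpy()
    base_bounds = [(r.bounds.lower, r.bounds.upper) for r in model.reactions]
    obj_col = Sdf.columns.get_loc(objective_reaction_id)

    ranges: list[FluxRange] = []
    for rid in reaction_ids:
        j = Sdf.columns.get_loc(rid)
        c = np.zeros(len(base_bounds))
        c[j] = 1.0
        extremes = {}
        for sense in ("minimize", "maximize"):
            value = None
            for relax in FVA_RELAXATIONS:
                slack = abs(opt) * relax
                bounds = list(base_bounds)
                lo = fraction_of_optimum * opt - slack
                hi = opt + slack
                bounds[obj_col] = (min(lo, hi), max(lo, hi))
                status, x, val, message = _solve(S, bounds, c, sense)
                if status == "optimal":
                    value = val
                    if relax > 0.0:
                        logger.info(
                            "FVA %s of %s needed relaxed objective fixing (%g)",
                            sense,
                            rid,
                            relax,
                        )
                    break
            if value is None:
                raise RuntimeError(
                    f"FVA subproblem for {rid!r} ({sense}) not optimal: {message}"
                )
            extremes[sense] = value
        lo, hi = extremes["minimize"], extremes["maximize"]
        if lo > hi:  # numerical jitter on a degenerate range
            lo, hi = hi, lo
        ranges.append(FluxRange(rid, lo, hi))
    return ranges


def ranges_to_frame(ranges: list[FluxRange]) -> pd.DataFrame:
    """Tabulate FVA ranges (reaction_id, min_flux, max_flux)."""
    return pd.DataFrame(
        {
            "reaction_id": [r.reaction_id for r in ranges],
            "min_flux": [r.min_flux for r in ranges],
            "max_flux": [r.max_flux for r in ranges],
        }
    )


def pin_reaction(
    model: StoichiometricModel, reaction_id: str, value: float
) -> StoichiometricModel:
    """Copy of the model with one reaction's flux fixed to ``value``."""
    model.reaction(reaction_id)
    return model.with_bounds({reaction_id: FluxBounds.fixed(value)})
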