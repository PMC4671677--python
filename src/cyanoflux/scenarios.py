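"""Trophic conditions and the two condition-driven experiments.

A :class:`TrophicCondition` encodes a culture scenario as exchange-bound
settings: photon and CO2 supply, organic substrate uptakes, and the
nitrogen source.  Conventions:

* uptake rates are positive numbers mapped to exchange bounds
  ``(-rate, 0)`` (uptake = negative exchange flux, up to the stated rate);
* the photon "uptake rate" is applied as an equality ``(-rate, -rate)``
  by default — all supplied photons are absorbed, excess energy must be
  dissipated metabolically — reflecting the modelling assumption that no
  light is dissipated photochemically;
* CO2, O2, water, sulfate and phosphate exchanges are free by default.

Autotrophic scenarios have zero organic uptake; heterotrophic scenarios
have zero photon uptake.  Mixing both is rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import pandas as pd
import yaml

from .core import FREE_FLUX_BOUND, FluxBounds, StoichiometricModel, UnknownIdError
from .fba import FluxRange, flux_variability, solve_fba

logger = logging.getLogger(__name__)

#: FBA growth above this threshold counts as "growth" in capability screens.
GROWTH_THRESHOLD = 1e-6

DEFAULT_FREE_EXCHANGES = ("co2", "o2", "h2o", "sulfate", "phosphate")

FREE = "free"


@dataclass(frozen=True)
class TrophicCondition:
    """Uptake-bound specification of one trophic scenario."""

    photon_uptake: float | str = 0.0
    co2_uptake: float | str = FREE
    substrate_uptakes: dict = field(default_factory=dict)
    nitrogen_source: str = "nitrate"
    nitrogen_uptake: float | str = FREE
    free_exchanges: tuple = DEFAULT_FREE_EXCHANGES
    photon_fixed: bool = True
    free_bound: float = FREE_FLUX_BOUND

    def __post_init__(self) -> None:
        if self.nitrogen_source not in ("nitrate", "ammonium"):
            raise ValueError(
                f"nitrogen source must be nitrate or ammonium, "
                f"got {self.nitrogen_source!r}"
            )
        organic = any(
            _rate_value(r, self.free_bound) > 0 for r in self.substrate_uptakes.values()
        )
        photons = _rate_value(self.photon_uptake, self.free_bound) > 0
        if organic and photons:
            raise ValueError(
                "mixotrophic condition: organic substrate uptake and photon "
                "uptake cannot both be positive"
            )

    @classmethod
    def autotrophic(
        cls,
        photon: float | str = 50.0,
        co2: float | str = FREE,
        nitrogen_source: str = "nitrate",
        nitrogen_uptake: float | str = FREE,
        **kw,
    ) -> "TrophicCondition":
        return cls(
            photon_uptake=photon,
            co2_uptake=co2,
            nitrogen_source=nitrogen_source,
            nitrogen_uptake=nitrogen_uptake,
            **kw,
        )

    @classmethod
    def heterotrophic(
        cls,
        substrate: str,
        rate: float,
        nitrogen_source: str = "nitrate",
        **kw,
    ) -> "TrophicCondition":
        return cls(
            photon_uptake=0.0,
            substrate_uptakes={substrate: rate},
            nitrogen_source=nitrogen_source,
            **kw,
        )

    @classmethod
    def from_yaml(cls, path) -> "TrophicCondition":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown condition keys {sorted(unknown)}")
        if "free_exchanges" in raw:
            raw["free_exchanges"] = tuple(raw["free_exchanges"])
        return cls(**raw)


def _rate_value(rate: float | str, free_bound: float) -> float:
    if rate == FREE:
        return free_bound
    return float(rate)


def find_exchange(model: StoichiometricModel, species_name: str) -> str:
    """Exchange reaction id for a named extracellular species."""
    for rxn in model.exchange_reactions():
        (sid,) = rxn.stoichiometry
        if model.metabolite(sid).id == species_name:
            return rxn.id
    available = sorted(
        model.metabolite(next(iter(r.stoichiometry))).id
        for r in model.exchange_reactions()
    )
    raise UnknownIdError(
        f"no exchange reaction for {species_name!r}; available exchanges: "
        f"{available}"
    )


def apply_condition(
    model: StoichiometricModel, condition: TrophicCondition
) -> StoichiometricModel:
    """Copy of the model with exchange bounds set per the condition.

    Only the exchanges the condition names are touched.
    """
    M = condition.free_bound
    updates: dict[str, FluxBounds] = {}

    def uptake_bounds(rate: float | str, fixed: bool = False, export_ok: bool = False) -> FluxBounds:
        r = _rate_value(rate, M)
        upper = -r if fixed else (M if export_ok else 0.0)
        return FluxBounds(-r, upper)

    updates[find_exchange(model, "photon")] = uptake_bounds(
        condition.photon_uptake,
        fixed=condition.photon_fixed and condition.photon_uptake != FREE,
    )
    updates[find_exchange(model, "co2")] = uptake_bounds(
        condition.co2_uptake, export_ok=True
    )
    for name in condition.free_exchanges:
        try:
            updates.setdefault(find_exchange(model, name), FluxBounds.free(M))
        except UnknownIdError:
            continue  # models need not define every conventional free species
    for substrate, rate in condition.substrate_uptakes.items():
        updates[find_exchange(model, substrate)] = uptake_bounds(rate)
    nitrate_ex = find_exchange(model, "no3")
    ammonium_ex = find_exchange(model, "nh4")
    if condition.nitrogen_source == "nitrate":
        updates[nitrate_ex] = uptake_bounds(condition.nitrogen_uptake)
        updates[ammonium_ex] = FluxBounds.fixed(0.0)
    else:
        updates[ammonium_ex] = uptake_bounds(condition.nitrogen_uptake)
        updates[nitrate_ex] = FluxBounds.fixed(0.0)
    return model.with_bounds(updates)


def growth_capability_screen(
    model: StoichiometricModel,
    substrates: list[str],
    uptake_rate: float = 10.0,
    nitrogen_source: str = "nitrate",
    threshold: float = GROWTH_THRESHOLD,
) -> pd.DataFrame:
    """Heterotrophic growth/non-growth per substrate at a fixed uptake rate.

    Photon uptake is zero; each substrate's uptake bound is set to the given
    rate in turn.  Substrates without an exchange reaction are flagged and
    reported as non-growth.  Rows follow the input order.
    """
    rows = []
    for substrate in substrates:
        try:
            cond = TrophicCondition.heterotrophic(
                substrate, uptake_rate, nitrogen_source=nitrogen_source
            )
            conditioned = apply_condition(model, cond)
        except UnknownIdError:
            rows.append(
                {"substrate": substrate, "growth": False, "growth_rate": 0.0,
                 "note": "no exchange reaction"}
            )
            continue
        sol = solve_fba(conditioned)
        rate = sol.objective_value if sol.optimal else 0.0
        rows.append(
            {"substrate": substrate, "growth": bool(sol.optimal and rate > threshold),
             "growth_rate": rate, "note": "" if sol.optimal else sol.status}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ScanResult:
    """One point of the nitrogen-limitation scan."""

    nitrate_uptake: float
    growth_rate: float
    glycogen_range: FluxRange
    byproduct_ranges: dict[str, FluxRange]


def optimal_nitrogen_uptake(
    model: StoichiometricModel, photon: float = 50.0, nitrogen_source: str = "nitrate"
) -> float:
    """N-source uptake flux at the unconstrained autotrophic optimum."""
    cond = TrophicCondition.autotrophic(photon=photon, nitrogen_source=nitrogen_source)
    conditioned = apply_condition(model, cond)
    sol = solve_fba(conditioned)
    if not sol.optimal:
        raise RuntimeError(f"baseline FBA not optimal: {sol.status}")
    species = "no3" if nitrogen_source == "nitrate" else "nh4"
    return -sol.fluxes[find_exchange(model, species)]


DEFAULT_BYPRODUCTS = ("etoh", "lac", "ac", "pyr", "formate")


def nitrogen_limitation_scan(
    model: StoichiometricModel,
    nitrate_rates: list[float] | None = None,
    photon: float = 50.0,
    target: str = "glycogen",
    byproducts: tuple = DEFAULT_BYPRODUCTS,
    n_points: int = 40,
) -> list[ScanResult]:
    """Growth and FVA-bounded product ranges across nitrate uptake rates.

    For each rate: fix nitrate uptake, maximize growth, then compute FVA
    ranges for the target (glycogen) export and each byproduct export at
    that optimum.  The default grid spans 0 to 1.2x the unconstrained-
    optimum nitrate uptake in ``n_points`` even steps.
    """
    target_ex = find_exchange(model, target)
    byproduct_ex = {}
    for name in byproducts:
        try:
            byproduct_ex[name] = find_exchange(model, name)
        except UnknownIdError:
            continue  # scan only the exports the model defines

    if nitrate_rates is None:
        n_opt = optimal_nitrogen_uptake(model, photon=photon)
        nitrate_rates = [1.2 * n_opt * i / (n_points - 1) for i in range(n_points)]
    if len(nitrate_rates) == 0:
        raise ValueError("empty nitrate rate list")

    results = []
    for rate in nitrate_rates:
        cond = TrophicCondition.autotrophic(photon=photon, nitrogen_uptake=rate)
        conditioned = apply_condition(model, cond)
        sol = solve_fba(conditioned)
        if not sol.optimal:
            raise RuntimeError(
                f"scan FBA at nitrate {rate} not optimal: {sol.status}"
            )
        wanted = [target_ex, *byproduct_ex.values()]
        ranges = flux_variability(conditioned, reaction_ids=wanted)
        by_id = {r.reaction_id: r for r in ranges}
        results.append(
            ScanResult(
                nitrate_uptake=rate,
                growth_rate=sol.objective_value,
                glycogen_range=by_id[target_ex],
                byproduct_ranges={
                    name: by_id[ex] for name, ex in byproduct_ex.items()
                },
            )
        )
    return results


def scan_to_frame(results: list[ScanResult]) -> pd.DataFrame:
    """Tabulate a nitrogen scan (rate, growth, per-product min/max)."""
    rows = []
    for r in results:
        row = {
            "nitrate_uptake": r.nitrate_uptake,
            "growth_rate": r.growth_rate,
            "glycogen_min": r.glycogen_range.min_flux,
            "glycogen_max": r.glycogen_range.max_flux,
        }
        for name, rng in r.byproduct_ranges.items():
            row[f"{name}_min"] = rng.min_flux
            row[f"{name}_max"] = rng.max_flux
        rows.append(row)
    return pd.DataFrame(rows)
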