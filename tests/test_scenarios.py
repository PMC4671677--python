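"""Trophic conditions, substrate screens, and the nitrogen-limitation scan."""

import numpy as np
import pytest

from cyanoflux import (
    TrophicCondition,
    UnknownIdError,
    apply_condition,
    growth_capability_screen,
    nitrogen_limitation_scan,
    optimal_nitrogen_uptake,
    solve_fba,
)
from cyanoflux.scenarios import find_exchange


class TestTrophicCondition:
    def test_autotrophic_condition_supports_growth(self, toy_nitrate):
        assert solve_fba(toy_nitrate).objective_value > 0.01

    def test_no_energy_no_carbon_no_growth(self, toy_model):
        cond = TrophicCondition(photon_uptake=0.0, co2_uptake=0.0)
        sol = solve_fba(apply_condition(toy_model, cond))
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_mixotrophic_rejected(self):
        with pytest.raises(ValueError, match="mixotrophic"):
            TrophicCondition(photon_uptake=50.0, substrate_uptakes={"glc": 1.0})

    def test_bad_nitrogen_source_rejected(self):
        with pytest.raises(ValueError, match="nitrate or ammonium"):
            TrophicCondition(nitrogen_source="urea")

    def test_unknown_substrate_lists_available_exchanges(self, toy_model):
        cond = TrophicCondition.heterotrophic("sucrose", 10.0)
        with pytest.raises(UnknownIdError, match="available exchanges"):
            apply_condition(toy_model, cond)

    def test_only_named_exchanges_touched(self, toy_model, toy_nitrate):
        for rxn in toy_model.reactions:
            if rxn.category(toy_model) == "exchange":
                continue  # non-exchange bounds must be untouched
            assert toy_nitrate.reaction(rxn.id).bounds == rxn.bounds

    def test_photon_bound_is_equality_by_default(self, toy_nitrate):
        ex = toy_nitrate.reaction("EX_photon")
        assert ex.bounds.lower == ex.bounds.upper == -50.0

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "cond.yaml"
        path.write_text(
            "photon_uptake: 50\nnitrogen_source: ammonium\n"
            "nitrogen_uptake: free\nsubstrate_uptakes: {}\n"
        )
        cond = TrophicCondition.from_yaml(path)
        assert cond.photon_uptake == 50
        assert cond.nitrogen_source == "ammonium"
        with pytest.raises(ValueError, match="unknown condition keys"):
            path.write_text("photon_uptake: 50\nbogus_key: 1\n")
            TrophicCondition.from_yaml(path)


class TestGrowthCapabilityScreen:
    def test_screen_rows_in_input_order(self, toy_model):
        table = growth_capability_screen(toy_model, ["glc", "akg", "sucrose"])
        assert table["substrate"].tolist() == ["glc", "akg", "sucrose"]

    def test_glucose_supports_heterotrophic_growth(self, toy_model):
        table = growth_capability_screen(toy_model, ["glc"])
        assert bool(table.loc[0, "growth"]) is True
        assert table.loc[0, "growth_rate"] > 1e-3

    def test_substrate_without_transporter_gives_non_growth(self, toy_model):
        """An exchange exists for alpha-ketoglutarate but no transporter,
        so uptake cannot reach the cytosol: predicted non-growth."""
        table = growth_capability_screen(toy_model, ["akg"])
        assert bool(table.loc[0, "growth"]) is False

    def test_substrate_without_exchange_flagged(self, toy_model):
        table = growth_capability_screen(toy_model, ["sucrose"])
        assert bool(table.loc[0, "growth"]) is False
        assert table.loc[0, "note"] == "no exchange reaction"


class TestNitrogenLimitationScan:
    def test_empty_rate_list_rejected(self, toy_model):
        with pytest.raises(ValueError, match="empty"):
            nitrogen_limitation_scan(toy_model, nitrate_rates=[])

    def test_replete_nitrate_leaves_glycogen_unforced(self, toy_model, toy_bundle):
        n_opt = optimal_nitrogen_uptake(toy_model, photon=50.0)
        assert n_opt == pytest.approx(
            toy_bundle.analytic_optimal_nitrate_uptake(50.0), abs=1e-8
        )
        res = nitrogen_limitation_scan(toy_model, nitrate_rates=[1.1 * n_opt])[0]
        assert res.glycogen_range.min_flux == pytest.approx(0.0, abs=1e-8)
        assert res.glycogen_range.max_flux == pytest.approx(0.0, abs=1e-6)

    def test_half_optimal_nitrate_glycogen_max_is_carbon_balanced(
        self, toy_model, toy_bundle
    ):
        """At half the optimal nitrate uptake, the maximal glycogen export
        equals the closed form and matches the excess-carbon balance:
        (CO2 fixed - biomass carbon) / 6 at the glycogen-maximal vertex."""
        n_opt = optimal_nitrogen_uptake(toy_model, photon=50.0)
        res = nitrogen_limitation_scan(toy_model, nitrate_rates=[0.5 * n_opt])[0]
        expected = toy_bundle.analytic_glycogen_max(0.5 * n_opt, photon=50.0)
        assert res.glycogen_range.max_flux == pytest.approx(expected, abs=1e-8)

    def test_scan_reproduces_limitation_shape(self, toy_model):
        """Below the optimum, lowering nitrate decreases growth and
        increases the attainable glycogen production."""
        n_opt = optimal_nitrogen_uptake(toy_model, photon=50.0)
        rates = [f * n_opt for f in (0.2, 0.4, 0.6, 0.8, 1.0)]
        results = nitrogen_limitation_scan(toy_model, nitrate_rates=rates)
        growth = [r.growth_rate for r in results]
        glyc_max = [r.glycogen_range.max_flux for r in results]
        assert all(np.diff(growth) > 1e-6)          # strictly increasing in N
        assert all(np.diff(glyc_max) < -1e-6)       # strictly decreasing in N
        for r in results:
            assert r.glycogen_range.min_flux >= -1e-9

    def test_byproducts_are_alternative_solutions_under_limitation(self, toy_model):
        """Overflow is not uniquely glycogen: at sub-optimal nitrate at
        least one organic acid export has positive attainable flux."""
        n_opt = optimal_nitrogen_uptake(toy_model, photon=50.0)
        res = nitrogen_limitation_scan(toy_model, nitrate_rates=[0.5 * n_opt])[0]
        acids = [res.byproduct_ranges[k].max_flux for k in ("ac", "lac", "pyr")]
        assert max(acids) > 1e-6

    def test_growth_monotone_in_photon_bound(self, toy_model):
        optima = []
        for photon in (10.0, 20.0, 40.0, 80.0):
            cond = TrophicCondition.autotrophic(photon=photon)
            optima.append(solve_fba(apply_condition(toy_model, cond)).objective_value)
        assert all(np.diff(optima) > 0)

    def test_default_grid_spans_beyond_optimum(self, toy_model):
        results = nitrogen_limitation_scan(toy_model, n_points=5)
        n_opt = optimal_nitrogen_uptake(toy_model, photon=50.0)
        assert results[0].nitrate_uptake == pytest.approx(0.0)
        assert results[-1].nitrate_uptake == pytest.approx(1.2 * n_opt, rel=1e-9)


class TestCarbonConservation:
    @pytest.mark.parametrize("nitrate_fraction", [0.5, 1.0])
    def test_exchange_carbon_balances_biomass_carbon(
        self, toy_model, toy_bundle, nitrate_fraction
    ):
        """At any optimum, carbon taken up equals biomass carbon plus
        carbon exported (glycogen, organic acids, ethanol)."""
        n_opt = optimal_nitrogen_uptake(toy_model, photon=50.0)
        cond = TrophicCondition.autotrophic(
            photon=50.0, nitrogen_uptake=nitrate_fraction * n_opt
        )
        model = apply_condition(toy_model, cond)
        sol = solve_fba(model)
        mu = sol.objective_value
        exchange_carbon = 0.0
        for rxn in model.exchange_reactions():
            (sid,) = rxn.stoichiometry
            exchange_carbon += sol.fluxes[rxn.id] * model.metabolite(sid).n_carbon
        # uptakes are negative: net exchange carbon + biomass carbon = 0
        total = exchange_carbon + mu * toy_bundle.params.biomass_carbon
        scale = max(1.0, abs(exchange_carbon))
        assert abs(total) / scale < 1e-6

    def test_find_exchange_resolves_species_names(self, toy_model):
        assert find_exchange(toy_model, "co2") == "EX_co2"
        with pytest.raises(UnknownIdError):
            find_exchange(toy_model, "unobtainium")
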