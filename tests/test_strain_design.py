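"""Flux response analysis, C-mol yields, and knockout screening."""

import itertools

import pytest

from cyanoflux import (
    FluxRange,
    TrophicCondition,
    apply_condition,
    classify_flux_response,
    cmol_yield,
    evaluate_knockout_design,
    flux_response_analysis,
    knock_out_reactions,
    knockout_screen,
    solve_fba,
)
from cyanoflux.strain_design import FluxResponseCurve, FluxResponsePoint


def synthetic_curve(base, values):
    """Curve with given (pinned_flux, min_production) pairs for classifier tests."""
    points = tuple(
        FluxResponsePoint(v, 0.1, FluxRange("EX_t", prod, prod))
        for v, prod in values
    )
    return FluxResponseCurve("R", "EX_t", base_flux=base, base_growth=0.1, points=points)


class TestCmolYield:
    def test_ethanol_arithmetic(self):
        # 1 ethanol (2 C) per 4 CO2 fixed = 50 C-mol%
        assert cmol_yield(1.0, 2, 4.0) == pytest.approx(50.0)

    def test_zero_production_zero_yield(self):
        assert cmol_yield(0.0, 6, 3.1) == 0.0

    def test_zero_co2_uptake_is_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            cmol_yield(1.0, 2, 0.0)


class TestClassifier:
    def test_monotone_increase_above_base_is_activation(self):
        curve = synthetic_curve(1.0, [(0.0, 0.0), (1.0, 0.0), (2.0, 0.5), (3.0, 1.0)])
        assert classify_flux_response(curve) == "activation_enhancing"

    def test_increase_below_base_is_repression(self):
        curve = synthetic_curve(2.0, [(0.0, 1.0), (1.0, 0.5), (2.0, 0.0), (3.0, 0.0)])
        assert classify_flux_response(curve) == "repression_enhancing"

    def test_flat_curve_is_neutral(self):
        curve = synthetic_curve(1.0, [(0.0, 0.0), (1.0, 0.0), (2.0, 0.0)])
        assert classify_flux_response(curve) == "neutral"

    def test_too_few_feasible_points_rejected(self):
        curve = FluxResponseCurve(
            "R", "EX_t", 1.0, 0.1,
            (FluxResponsePoint(0.0, float("nan"), None),
             FluxResponsePoint(1.0, 0.1, FluxRange("EX_t", 0, 0))),
        )
        with pytest.raises(ValueError):
            classify_flux_response(curve)


class TestFluxResponseAnalysis:
    def test_base_grid_point_recovers_unconstrained_optimum(self, toy_nitrate):
        curve = flux_response_analysis(toy_nitrate, "PGM", "EX_glycogen", n_grid=5)
        at_base = [
            pt for pt in curve.points
            if abs(pt.pinned_flux - curve.base_flux) < 1e-10
        ]
        assert at_base and at_base[0].growth_rate == pytest.approx(
            curve.base_growth, abs=1e-8
        )

    def test_phosphoglucomutase_activation_enhances_glycogen(self, toy_nitrate):
        """Forcing flux through the glucose-1-phosphate branch above its
        optimum diverts hexose phosphate into glycogen: guaranteed export
        rises while growth falls."""
        curve = flux_response_analysis(toy_nitrate, "PGM", "EX_glycogen", n_grid=9)
        assert classify_flux_response(curve) == "activation_enhancing"
        above = [pt for pt in curve.points if pt.pinned_flux > curve.base_flux + 1e-9]
        assert above
        mins = [pt.target_range.min_flux for pt in above if pt.feasible]
        assert all(b > a - 1e-9 for a, b in itertools.pairwise(mins))
        assert mins[-1] > 1e-3
        assert above[-1].growth_rate < curve.base_growth - 1e-3

    def test_pep_carboxylase_repression_enhances_glycogen_in_storage_strain(
        self, toy_nitrate, toy_bundle
    ):
        """With overflow exports and the respiratory chain deleted, the
        only fate for carbon and reductant freed by repressing the
        anaplerotic (PEP carboxylase) flux is glycogen: its guaranteed
        export rises as the pinned flux drops, and growth falls."""
        storage = knock_out_reactions(
            toy_nitrate,
            set(toy_bundle.byproduct_exchanges) | set(toy_bundle.respiratory_reactions),
        )
        curve = flux_response_analysis(storage, "PEPC", "EX_glycogen", n_grid=9)
        assert classify_flux_response(curve) == "repression_enhancing"
        below = [
            pt for pt in curve.points
            if pt.feasible and pt.pinned_flux < curve.base_flux - 1e-9
        ]
        assert below
        assert below[0].target_range.min_flux > below[-1].target_range.min_flux + 1e-6
        assert below[0].growth_rate < curve.base_growth - 1e-6


class TestEvaluateKnockout:
    def test_essential_reaction_knockout_gives_zero_relative_growth(self, toy_nitrate):
        design = evaluate_knockout_design(toy_nitrate, {"CBB"}, "EX_etoh")
        assert design.relative_growth == 0.0
        assert design.target_yield_cmol == 0.0

    def test_respiratory_knockout_forces_ethanol_overflow(
        self, toy_ammonium, toy_bundle
    ):
        """Deleting NADH/NADPH dehydrogenase + cytochrome oxidase under
        ammonium leaves ethanol as the only net NADPH sink: its export
        minimum is positive and growth persists at reduced rate."""
        design = evaluate_knockout_design(
            toy_ammonium,
            set(toy_bundle.respiratory_reactions),
            "EX_etoh",
            nitrogen_source="ammonium",
        )
        ana = toy_bundle.analytic_respiratory_knockout(50.0, "ammonium")
        assert design.target_range.min_flux > 1e-3
        assert 0.0 < design.relative_growth < 100.0
        assert design.relative_growth == pytest.approx(
            ana["relative_growth"], abs=1e-6
        )
        assert design.target_yield_cmol == pytest.approx(
            ana["ethanol_yield_cmol"], abs=1e-6
        )
        assert design.yield_determined

    def test_gene_level_knockout_maps_to_reactions(self, toy_ammonium, toy_bundle):
        by_genes = evaluate_knockout_design(
            toy_ammonium, {"tg_ndhB", "tg_coxA"}, "EX_etoh"
        )
        assert by_genes.knocked_reactions == {"NDH1", "NDH2", "COX"}
        by_reactions = evaluate_knockout_design(
            toy_ammonium, set(toy_bundle.respiratory_reactions), "EX_etoh"
        )
        assert by_genes.target_yield_cmol == pytest.approx(
            by_reactions.target_yield_cmol, abs=1e-9
        )

    def test_ammonium_never_worse_than_nitrate_for_ethanol(
        self, toy_nitrate, toy_ammonium, toy_bundle
    ):
        """Nitrate reduction consumes NADPH that would otherwise overflow
        to ethanol, so switching to ammonium cannot lower the yield."""
        resp = set(toy_bundle.respiratory_reactions)
        y_no3 = evaluate_knockout_design(toy_nitrate, resp, "EX_etoh").target_yield_cmol
        y_nh4 = evaluate_knockout_design(toy_ammonium, resp, "EX_etoh").target_yield_cmol
        assert y_nh4 >= y_no3 - 1e-9

    def test_wild_type_makes_no_ethanol(self, toy_ammonium):
        design = evaluate_knockout_design(toy_ammonium, set(), "EX_etoh")
        assert design.target_yield_cmol == pytest.approx(0.0, abs=1e-6)
        assert design.relative_growth == pytest.approx(100.0, abs=1e-6)


class TestKnockoutScreen:
    CANDIDATES = [
        "tg_ndhB", "tg_ndhF", "tg_coxA", "tg_pgm", "tg_ldh", "tg_pta", "tg_zwf",
    ]

    def test_k1_matches_exhaustive_single_gene_oracle(self, toy_ammonium):
        """The screen at k=1 must reproduce per-gene evaluation done by
        hand, without dedup or pruning."""
        designs = knockout_screen(
            toy_ammonium, "EX_etoh", k_max=1, candidate_genes=self.CANDIDATES,
            deduplicate=False, prune_lethal=False,
        )
        oracle = {
            gene: evaluate_knockout_design(toy_ammonium, {gene}, "EX_etoh")
            for gene in self.CANDIDATES
        }
        assert len(designs) == len(self.CANDIDATES)
        for design in designs:
            (gene,) = design.knocked_genes
            assert design.target_yield_cmol == pytest.approx(
                oracle[gene].target_yield_cmol, abs=1e-9
            )
            assert design.relative_growth == pytest.approx(
                oracle[gene].relative_growth, abs=1e-9
            )

    def test_dedup_does_not_change_best_yields(self, toy_ammonium):
        kw = dict(k_max=2, candidate_genes=self.CANDIDATES, prune_lethal=False)
        with_dedup = knockout_screen(toy_ammonium, "EX_etoh", deduplicate=True, **kw)
        without = knockout_screen(toy_ammonium, "EX_etoh", deduplicate=False, **kw)
        assert with_dedup[0].target_yield_cmol == pytest.approx(
            without[0].target_yield_cmol, abs=1e-9
        )
        best_sigs = lambda ds: {d.knocked_reactions for d in ds if d.target_yield_cmol > 1e-6}
        assert best_sigs(with_dedup) == best_sigs(without)

    def test_lethal_superset_pruning_is_sound(self, toy_nitrate):
        """Pruning may only drop supersets of no-growth sets; every
        surviving design's yield must match the unpruned screen."""
        candidates = ["tg_rbcL", "tg_ppc", "tg_ndhB", "tg_coxA", "tg_glnA"]
        kw = dict(k_max=2, candidate_genes=candidates, deduplicate=False)
        pruned = knockout_screen(toy_nitrate, "EX_etoh", prune_lethal=True, **kw)
        full = knockout_screen(toy_nitrate, "EX_etoh", prune_lethal=False, **kw)
        growing = lambda ds: {
            d.knocked_genes: round(d.target_yield_cmol, 9)
            for d in ds
            if d.relative_growth > 0
        }
        assert growing(pruned) == growing(full)

    def test_screen_recovers_respiratory_design(self, toy_ammonium):
        """Two genes suffice to delete the three respiratory reactions
        (one gene is shared by both dehydrogenases); the screen must rank
        that design first by guaranteed ethanol yield."""
        designs = knockout_screen(
            toy_ammonium, "EX_etoh", k_max=2, candidate_genes=self.CANDIDATES
        )
        best = designs[0]
        # the cytochrome-oxidase knockout alone already silences the chain
        # (the quinol pool loses its only sink), so the minimal design wins
        # the tie; the explicit two-gene design scores identically
        assert best.knocked_genes == {"tg_coxA"}
        assert best.target_yield_cmol > 50.0
        two_gene = [
            d for d in designs if d.knocked_genes == {"tg_coxA", "tg_ndhB"}
        ]
        assert two_gene and two_gene[0].knocked_reactions == {"NDH1", "NDH2", "COX"}
        assert two_gene[0].target_yield_cmol == pytest.approx(
            best.target_yield_cmol, abs=1e-6
        )

    def test_yield_bounded_by_carbon_conservation(self, toy_ammonium):
        designs = knockout_screen(
            toy_ammonium, "EX_etoh", k_max=2, candidate_genes=self.CANDIDATES
        )
        for d in designs:
            assert d.target_yield_cmol <= 100.0 + 1e-6
            assert 0.0 <= d.relative_growth <= 100.0 + 1e-6

    def test_depth_limit_and_empty_candidates(self, toy_ammonium):
        with pytest.raises(ValueError, match="k_max"):
            knockout_screen(toy_ammonium, "EX_etoh", k_max=4)
        with pytest.raises(ValueError, match="empty"):
            knockout_screen(toy_ammonium, "EX_etoh", k_max=1, candidate_genes=[])
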