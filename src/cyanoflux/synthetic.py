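"""Synthetic toy photoautotroph models with analytically known optima.

The core generator builds a ~45-reaction cyanobacterium-like network that
reproduces, at desk scale, every mechanism the full genome-scale analysis
relies on: photon-driven linear electron transport producing NADPH and ATP
in a fixed ratio, Calvin-cycle CO2 fixation, nitrate reduction consuming
NADPH versus direct ammonium assimilation, a respiratory chain (NADH and
NADPH dehydrogenases feeding a cytochrome oxidase), an oxidative
pentose-phosphate shunt, and overflow exports for glycogen, ethanol,
acetate, lactate and pyruvate.

Because every internal currency (ATP, NAD(P)H, fixed carbon, nitrogen)
enters the biomass equation through a unique cheapest path, the LP optimum
is given by closed-form linear resource accounting; those closed forms are
exposed on the bundle and serve as an oracle independent of the LP solver.

Key stoichiometric choices (per reaction):

* ``LET``   4 photons -> 1 NADPH + 1.5 ATP + 0.5 O2 (coupled photosystems;
  the ATP:NADPH supply ratio is fixed, which is what makes respiratory
  disposal of excess reductant, and its knockout phenotype, non-trivial)
* ``CBB``   CO2 + 3 ATP + 2 NADPH -> CH2O (Calvin cycle lump; CH2O is one
  carbon at sugar oxidation level)
* ``GLY_PEP`` 3 CH2O -> PEP + NADPH (lower glycolysis with NADP-dependent
  glyceraldehyde-phosphate dehydrogenase, as in cyanobacteria)
* ``OPP``   G6P -> 5 CH2O + CO2 + 2 NADPH (oxidative pentose phosphate
  shunt; combined with CBB+HEX it forms a futile cycle that dissipates
  excess ATP, the model's only free energy valve)
* respiratory chain ``NDH1``/``NDH2``/``COX`` with 1 ATP per NAD(P)H
* ``ADH`` is NADPH-linked, ``LDH`` NADH-linked: with the respiratory chain
  deleted, ethanol is the only net sink for excess NADPH, so its export
  becomes uniquely determined (the strain-design story).

Biomass drains oxaloacetate + nitrogen carrier (protein), glucose-1-
phosphate (carbohydrate), CH2O (remaining macromolecules), ATP and NADPH
in proportions set by the macromolecular composition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    FREE_FLUX_BOUND,
    FluxBounds,
    Metabolite,
    ModelStructureError,
    Reaction,
    StoichiometricModel,
)

DEFAULT_COMPOSITION = {
    "protein": 0.68,
    "carbohydrate": 0.16,
    "dna": 0.0088,
    "rna": 0.0312,
    "lipid": 0.11,
    "chlorophyll": 0.01,
}


@dataclass(frozen=True)
class ToyParams:
    """Tunable stoichiometry of the toy photoautotroph.

    Units: photon/ATP/NADPH stoichiometries are mol per mol; monomer masses
    g/mol; per-gram demands derive as 1000 * mass_fraction / monomer_mw
    (mmol per gDW).
    """

    photons_per_nadph: float = 4.0        # photons per NADPH in linear ET
    atp_per_nadph_photo: float = 1.5      # ATP co-produced per NADPH in LET
    atp_per_co2: float = 3.0              # Calvin cycle ATP per CO2 fixed
    nadph_per_co2: float = 2.0            # Calvin cycle NADPH per CO2 fixed
    nadph_per_nitrate: float = 4.0        # nitrate -> ammonium reduction cost
    resp_atp_per_nadh: float = 1.0        # oxidative phosphorylation yield
    gam_atp: float = 30.0                 # growth-associated ATP, mmol/gDW
    biosynthesis_nadph: float = 10.0      # anabolic reduction, mmol/gDW
    ammonium_assimilation_atp: float = 1.0  # GS reaction, ATP per N
    composition: dict = field(default_factory=lambda: dict(DEFAULT_COMPOSITION))
    protein_monomer_mw: float = 100.0     # lumped (oxaloacetate+N) residue
    glycogen_monomer_mw: float = 162.141  # glucosyl unit C6H10O5
    residual_monomer_mw: float = 30.0     # CH2O equivalent
    free_bound: float = FREE_FLUX_BOUND
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.composition.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ModelStructureError(
                f"biomass composition fractions sum to {total}, expected 1"
            )
        for name in (
            "photons_per_nadph",
            "atp_per_nadph_photo",
            "atp_per_co2",
            "nadph_per_co2",
            "nadph_per_nitrate",
            "resp_atp_per_nadh",
            "gam_atp",
            "biosynthesis_nadph",
            "ammonium_assimilation_atp",
        ):
            if getattr(self, name) <= 0:
                raise ModelStructureError(f"parameter {name} must be > 0")

    # -- per-gDW biomass precursor demands (mmol/gDW) -----------------------

    @property
    def x_oxa(self) -> float:
        return 1000.0 * self.composition["protein"] / self.protein_monomer_mw

    @property
    def x_n(self) -> float:
        return self.x_oxa

    @property
    def x_g1p(self) -> float:
        return 1000.0 * self.composition["carbohydrate"] / self.glycogen_monomer_mw

    @property
    def x_ch2o(self) -> float:
        rest = 1.0 - self.composition["protein"] - self.composition["carbohydrate"]
        return 1000.0 * rest / self.residual_monomer_mw

    @property
    def biomass_carbon(self) -> float:
        """mmol carbon per gDW (oxaloacetate C4, glucosyl C6, CH2O C1)."""
        return 4 * self.x_oxa + 6 * self.x_g1p + self.x_ch2o


class ToyConstructionError(ModelStructureError):
    """Raised when parameters make the toy biomass infeasible."""


@dataclass
class ToyModelBundle:
    """Toy model plus its closed-form optima (the LP-independent oracle).

    All closed forms assume the default autotrophic setting: photon uptake
    fixed (all photons absorbed), CO2/O2 free, one nitrogen source.  They
    follow from per-gDW resource accounting over the unique cheapest
    synthesis routes; see docs/methods.md for the derivation.
    """

    model: StoichiometricModel
    params: ToyParams
    #: reaction ids of the respiratory chain (NADH/NADPH dehydrogenase +
    #: cytochrome oxidase) and their gene sets, for knockout studies
    respiratory_reactions: frozenset[str] = frozenset({"NDH1", "NDH2", "COX"})
    respiratory_genes: frozenset[str] = frozenset({"tg_ndhB", "tg_ndhF", "tg_coxA"})
    byproduct_exchanges: tuple[str, ...] = ("EX_etoh", "EX_ac", "EX_lac", "EX_pyr")

    # -- per-gDW gross demands ----------------------------------------------

    def _demands(self, nitrogen_source: str) -> tuple[float, float]:
        """(ATP, NADPH) demand per gDW, net of glycolytic NADPH credit."""
        p = self.params
        ch2o = 3 * p.x_oxa + 6 * p.x_g1p + p.x_ch2o
        atp = (
            p.atp_per_co2 * ch2o
            + p.x_g1p  # hexose phosphate assembly
            + p.gam_atp
            + p.ammonium_assimilation_atp * p.x_n
        )
        nadph = p.nadph_per_co2 * ch2o + p.biosynthesis_nadph - p.x_oxa
        if nitrogen_source == "nitrate":
            nadph += p.nadph_per_nitrate * p.x_n
        elif nitrogen_source != "ammonium":
            raise ValueError(f"unknown nitrogen source {nitrogen_source!r}")
        return atp, nadph

    def _opp_cycle_coefficients(self) -> tuple[float, float]:
        """(ATP consumed, NADPH produced) per unit of the CBB/HEX/OPP cycle.

        Running the oxidative shunt against refixation costs 1 + atp_per_co2
        ATP and nets 2 - nadph_per_co2 NADPH per cycle: an ATP sink that,
        for nadph_per_co2 < 2, doubles as an ATP -> NADPH converter.
        """
        p = self.params
        return 1.0 + p.atp_per_co2, 2.0 - p.nadph_per_co2

    def photon_cost_per_gdw(self, nitrogen_source: str = "nitrate") -> float:
        """Photons consumed per gDW at the wild-type optimum."""
        p = self.params
        atp, nadph = self._demands(nitrogen_source)
        tau, rho = p.atp_per_nadph_photo, p.resp_atp_per_nadh
        if atp >= tau * nadph:
            # ATP-deficient: NADPH-dehydrogenase flux closes the ATP gap
            resp = (atp - tau * nadph) / (tau + rho)
            return p.photons_per_nadph * (nadph + resp)
        # ATP surplus: dissipated through the CBB/OPP cycle, whose NADPH
        # by-product offsets part of the photosynthetic NADPH demand
        c_atp, c_nadph = self._opp_cycle_coefficients()
        if c_nadph <= 0:
            return p.photons_per_nadph * nadph
        return (
            p.photons_per_nadph
            * (nadph * c_atp + c_nadph * atp)
            / (c_atp + c_nadph * tau)
        )

    def analytic_growth(
        self,
        photon: float | None = None,
        co2: float | None = None,
        n_uptake: float | None = None,
        nitrogen_source: str = "nitrate",
    ) -> float:
        """Closed-form FBA optimum (1/h) under the given uptake limits."""
        p = self.params
        limits = []
        if photon is not None:
            limits.append(photon / self.photon_cost_per_gdw(nitrogen_source))
        if co2 is not None:
            limits.append(co2 / p.biomass_carbon)
        if n_uptake is not None:
            limits.append(n_uptake / p.x_n)
        if not limits:
            raise ValueError("at least one uptake limit is required")
        return min(limits)

    def analytic_optimal_nitrate_uptake(self, photon: float = 50.0) -> float:
        """Nitrate uptake at the unconstrained (N-replete) optimum."""
        return self.params.x_n * self.analytic_growth(photon=photon)

    def analytic_glycogen_max(
        self, nitrate_rate: float, photon: float = 50.0
    ) -> float:
        """Maximum glycogen export (FVA max) at the N-limited optimum.

        Two candidate bottlenecks: remaining NADPH after biomass (glycogen
        costs 6*nadph_per_co2 NADPH per unit) and remaining ATP with the
        respiratory chain transforming spare NADPH into ATP.
        """
        p = self.params
        mu = min(
            nitrate_rate / p.x_n, self.analytic_growth(photon=photon)
        )
        atp_d, nadph_d = self._demands("nitrate")
        tau, rho = p.atp_per_nadph_photo, p.resp_atp_per_nadh
        atp_g = 6 * p.atp_per_co2 + 2  # hexose assembly + glucosyl transfer
        nadph_g = 6 * p.nadph_per_co2
        L = photon / p.photons_per_nadph
        by_atp = ((tau + rho) * L - (atp_d + rho * nadph_d) * mu) / (
            atp_g + rho * nadph_g
        )
        c_atp, c_nadph = self._opp_cycle_coefficients()
        if c_nadph > 0:
            # surplus ATP converts to NADPH through the CBB/OPP cycle
            by_nadph = (
                c_atp * (L - nadph_d * mu) + c_nadph * (tau * L - atp_d * mu)
            ) / (c_atp * nadph_g + c_nadph * atp_g)
        else:
            by_nadph = (L - nadph_d * mu) / nadph_g
        return max(0.0, min(by_nadph, by_atp))

    def analytic_respiratory_knockout(
        self, photon: float = 50.0, nitrogen_source: str = "ammonium"
    ) -> dict[str, float]:
        """Closed-form outcome of deleting NDH1 + NDH2 + COX.

        Without respiration the fixed LET ATP:NADPH supply ratio cannot be
        shifted toward ATP, so closing the ATP gap requires running LET
        harder and dumping the surplus NADPH into ethanol (the only net
        NADPH sink: ADH is NADPH-linked and the OPP cycle is NADPH-neutral).
        """
        p = self.params
        atp_d, nadph_d = self._demands(nitrogen_source)
        tau = p.atp_per_nadph_photo
        atp_e = 3 * p.atp_per_co2 - 1  # CBB cost minus pyruvate-kinase ATP
        nadph_e = 3 * p.nadph_per_co2  # CBB cost + ADH - glycolytic credit
        denom = tau * nadph_e - atp_e
        if denom <= 0:
            raise ToyConstructionError(
                "ethanol overflow cannot close the ATP balance: "
                "atp_per_nadph_photo * 3*nadph_per_co2 must exceed "
                "3*atp_per_co2 - 1"
            )
        ethanol_per_gdw = max(0.0, (atp_d - tau * nadph_d) / denom)
        if ethanol_per_gdw > 0:
            L = nadph_d + nadph_e * ethanol_per_gdw
            mu = photon / (p.photons_per_nadph * L)
        else:
            # ATP in surplus: the knockout is silent, growth is wild-type
            mu = self.analytic_growth(photon=photon, nitrogen_source=nitrogen_source)
        mu_wt = self.analytic_growth(photon=photon, nitrogen_source=nitrogen_source)
        co2_per_gdw = p.biomass_carbon + 2 * ethanol_per_gdw
        yield_cmol = 100.0 * 2 * ethanol_per_gdw / co2_per_gdw
        return {
            "growth": mu,
            "relative_growth": 100.0 * mu / mu_wt,
            "ethanol_flux": ethanol_per_gdw * mu,
            "co2_uptake": co2_per_gdw * mu,
            "ethanol_yield_cmol": yield_cmol,
        }


def _met(mid, name, comp, n_carbon=0, formula=None):
    return Metabolite(id=mid, name=name, compartment=comp, n_carbon=n_carbon, formula=formula)


def make_core_photoautotroph(params: ToyParams | None = None) -> ToyModelBundle:
    """Build the toy photoautotroph network and its analytic bundle."""
    p = params or ToyParams()
    M = p.free_bound

    mets = [
        # cytosol
        _met("photon", "photon", "c"),
        _met("co2", "carbon dioxide", "c", 1, "CO2"),
        _met("o2", "oxygen", "c", 0, "O2"),
        _met("nadph", "NADPH", "c"),
        _met("nadh", "NADH", "c"),
        _met("atp", "ATP", "c"),
        _met("qh2", "reduced quinone pool", "c"),
        _met("ch2o", "fixed carbon (triose equivalent)", "c", 1, "CH2O"),
        _met("g6p", "glucose-6-phosphate", "c", 6),
        _met("g1p", "glucose-1-phosphate", "c", 6),
        _met("glycogen", "glycogen (glucosyl monomer)", "c", 6, "C6H10O5"),
        _met("pep", "phosphoenolpyruvate", "c", 3),
        _met("pyr", "pyruvate", "c", 3),
        _met("accoa", "acetyl-CoA (acetyl moiety)", "c", 2),
        _met("acald", "acetaldehyde", "c", 2),
        _met("etoh", "ethanol", "c", 2, "C2H6O"),
        _met("lac", "lactate", "c", 3),
        _met("ac", "acetate", "c", 2),
        _met("oxa", "oxaloacetate", "c", 4),
        _met("no3", "nitrate", "c"),
        _met("nh4", "ammonium", "c"),
        _met("n", "nitrogen carrier", "c"),
        _met("glc", "glucose", "c", 6, "C6H12O6"),
        # extracellular
        _met("photon", "photon", "e"),
        _met("co2", "carbon dioxide", "e", 1, "CO2"),
        _met("o2", "oxygen", "e", 0, "O2"),
        _met("no3", "nitrate", "e"),
        _met("nh4", "ammonium", "e"),
        _met("glc", "glucose", "e", 6, "C6H12O6"),
        _met("glycogen", "glycogen (glucosyl monomer)", "e", 6, "C6H10O5"),
        _met("etoh", "ethanol", "e", 2, "C2H6O"),
        _met("ac", "acetate", "e", 2),
        _met("lac", "lactate", "e", 3),
        _met("pyr", "pyruvate", "e", 3),
        _met("akg", "alpha-ketoglutarate", "e", 5),
    ]

    def rxn(rid, name, stoich, genes=(), lb=0.0, ub=M, subsystem=""):
        return Reaction(
            id=rid,
            name=name,
            stoichiometry=stoich,
            reversible=lb < 0,
            bounds=FluxBounds(lb, ub),
            gene_association=frozenset(genes),
            subsystem=subsystem,
        )

    a = p.photons_per_nadph
    tau = p.atp_per_nadph_photo
    rho = p.resp_atp_per_nadh

    reactions = [
        # exchanges (uptake = negative flux)
        rxn("EX_photon", "photon exchange", {"photon[e]": -1}, lb=-M, ub=0),
        rxn("EX_co2", "CO2 exchange", {"co2[e]": -1}, lb=-M, ub=M),
        rxn("EX_o2", "O2 exchange", {"o2[e]": -1}, lb=-M, ub=M),
        rxn("EX_no3", "nitrate exchange", {"no3[e]": -1}, lb=-M, ub=0),
        rxn("EX_nh4", "ammonium exchange", {"nh4[e]": -1}, lb=0, ub=0),
        rxn("EX_glc", "glucose exchange", {"glc[e]": -1}, lb=0, ub=0),
        rxn("EX_glycogen", "glycogen export", {"glycogen[e]": -1}, lb=0, ub=M),
        rxn("EX_etoh", "ethanol export", {"etoh[e]": -1}, lb=0, ub=M),
        rxn("EX_ac", "acetate export", {"ac[e]": -1}, lb=0, ub=M),
        rxn("EX_lac", "lactate export", {"lac[e]": -1}, lb=0, ub=M),
        rxn("EX_pyr", "pyruvate export", {"pyr[e]": -1}, lb=0, ub=M),
        # alpha-ketoglutarate has an exchange but no transporter: the model
        # cannot take it up (putative-transporter scenario)
        rxn("EX_akg", "alpha-ketoglutarate exchange", {"akg[e]": -1}, lb=-M, ub=0),
        # transport
        rxn("T_photon", "photon capture", {"photon[e]": -1, "photon[c]": 1}),
        rxn("T_co2", "CO2 diffusion", {"co2[e]": -1, "co2[c]": 1}, lb=-M),
        rxn("T_o2", "O2 diffusion", {"o2[e]": -1, "o2[c]": 1}, lb=-M),
        rxn("T_no3", "nitrate transport", {"no3[e]": -1, "no3[c]": 1}, ("tg_nrtA",)),
        rxn("T_nh4", "ammonium transport", {"nh4[e]": -1, "nh4[c]": 1}, ("tg_amt1",)),
        rxn("T_glc", "glucose transport", {"glc[e]": -1, "glc[c]": 1}, ("tg_glcP",)),
        rxn("T_glycogen", "glycogen export transport (virtual)",
            {"glycogen[c]": -1, "glycogen[e]": 1}),
        rxn("T_etoh", "ethanol diffusion", {"etoh[c]": -1, "etoh[e]": 1}),
        rxn("T_ac", "acetate transport", {"ac[c]": -1, "ac[e]": 1}),
        rxn("T_lac", "lactate transport", {"lac[c]": -1, "lac[e]": 1}),
        rxn("T_pyr", "pyruvate transport", {"pyr[c]": -1, "pyr[e]": 1}),
        # light reactions and carbon fixation
        rxn("LET", "linear electron transport (PSII+PSI)",
            {"photon[c]": -a, "nadph[c]": 1, "atp[c]": tau, "o2[c]": 0.5},
            ("tg_psbA", "tg_psaB"), subsystem="photosynthesis"),
        rxn("CBB", "Calvin cycle (RuBisCO lump)",
            {"co2[c]": -1, "atp[c]": -p.atp_per_co2, "nadph[c]": -p.nadph_per_co2,
             "ch2o[c]": 1}, ("tg_rbcL",), subsystem="calvin_cycle"),
        # sugar phosphates and glycogen
        rxn("HEX", "hexose phosphate assembly",
            {"ch2o[c]": -6, "atp[c]": -1, "g6p[c]": 1}, ("tg_fbp",),
            subsystem="gluconeogenesis"),
        rxn("G6P_CAT", "hexose catabolism to triose pool",
            {"g6p[c]": -1, "ch2o[c]": 6}, ("tg_pgi",), subsystem="glycolysis"),
        rxn("OPP", "oxidative pentose phosphate shunt (zwf lump)",
            {"g6p[c]": -1, "ch2o[c]": 5, "co2[c]": 1, "nadph[c]": 2},
            ("tg_zwf",), subsystem="pentose_phosphate"),
        rxn("PGM", "phosphoglucomutase",
            {"g6p[c]": -1, "g1p[c]": 1}, ("tg_pgm",), subsystem="glycogen"),
        rxn("GLYS", "glycogen synthase",
            {"g1p[c]": -1, "atp[c]": -1, "glycogen[c]": 1}, ("tg_glgA",),
            subsystem="glycogen"),
        # lower glycolysis and overflow routes
        rxn("GLY_PEP", "lower glycolysis (NADP-GAPDH lump)",
            {"ch2o[c]": -3, "pep[c]": 1, "nadph[c]": 1}, ("tg_gap2",),
            subsystem="glycolysis"),
        rxn("PYK", "pyruvate kinase",
            {"pep[c]": -1, "pyr[c]": 1, "atp[c]": 1}, ("tg_pyk",),
            subsystem="glycolysis"),
        rxn("PEPC", "PEP carboxylase",
            {"pep[c]": -1, "co2[c]": -1, "oxa[c]": 1}, ("tg_ppc",),
            subsystem="anaplerosis"),
        rxn("PDH", "pyruvate dehydrogenase",
            {"pyr[c]": -1, "accoa[c]": 1, "co2[c]": 1, "nadh[c]": 1},
            ("tg_pdh",), subsystem="fermentation"),
        rxn("PDC", "pyruvate decarboxylase",
            {"pyr[c]": -1, "acald[c]": 1, "co2[c]": 1}, ("tg_pdc",),
            subsystem="fermentation"),
        rxn("ADH", "alcohol dehydrogenase (NADPH)",
            {"acald[c]": -1, "nadph[c]": -1, "etoh[c]": 1}, ("tg_adh",),
            subsystem="fermentation"),
        rxn("LDH", "lactate dehydrogenase (NADH)",
            {"pyr[c]": -1, "nadh[c]": -1, "lac[c]": 1}, ("tg_ldh",),
            subsystem="fermentation"),
        rxn("ACK", "phosphotransacetylase + acetate kinase",
            {"accoa[c]": -1, "ac[c]": 1, "atp[c]": 1}, ("tg_pta",),
            subsystem="fermentation"),
        # nitrogen assimilation
        rxn("NAR", "ferredoxin-nitrate reductase (NADPH lump)",
            {"no3[c]": -1, "nadph[c]": -p.nadph_per_nitrate, "nh4[c]": 1},
            ("tg_narB",), subsystem="nitrogen"),
        rxn("GS", "glutamine synthetase (N assimilation lump)",
            {"nh4[c]": -1, "atp[c]": -p.ammonium_assimilation_atp, "n[c]": 1},
            ("tg_glnA",), subsystem="nitrogen"),
        # respiratory chain
        rxn("NDH1", "NADH dehydrogenase",
            {"nadh[c]": -1, "qh2[c]": 1}, ("tg_ndhB",), subsystem="respiration"),
        rxn("NDH2", "NADPH dehydrogenase",
            {"nadph[c]": -1, "qh2[c]": 1}, ("tg_ndhB", "tg_ndhF"),
            subsystem="respiration"),
        rxn("COX", "cytochrome-c oxidase",
            {"qh2[c]": -1, "o2[c]": -0.5, "atp[c]": rho}, ("tg_coxA",),
            subsystem="respiration"),
        # heterotrophic entry
        rxn("GLK", "glucokinase",
            {"glc[c]": -1, "atp[c]": -1, "g6p[c]": 1}, ("tg_glk",),
            subsystem="glycolysis"),
        # biomass
        rxn("BIOMASS", "biomass equation",
            {"oxa[c]": -p.x_oxa, "n[c]": -p.x_n, "g1p[c]": -p.x_g1p,
             "ch2o[c]": -p.x_ch2o, "atp[c]": -p.gam_atp,
             "nadph[c]": -p.biosynthesis_nadph},
            subsystem="biomass"),
    ]

    model = StoichiometricModel(
        metabolites=mets,
        reactions=reactions,
        biomass_reaction_id="BIOMASS",
        id="toy_photoautotroph",
    )
    bundle = ToyModelBundle(model=model, params=p)
    # construction-time sanity: the closed forms must describe a viable cell
    for source in ("nitrate", "ammonium"):
        if bundle.photon_cost_per_gdw(source) <= 0:
            raise ToyConstructionError(
                f"photon balance non-positive under {source}: check LET and "
                "Calvin-cycle stoichiometry"
            )
    return bundle


def make_random_viable_model(
    n_metabolites: int, n_reactions: int, seed: int
) -> StoichiometricModel:
    """Random sparse stoichiometric model, resampled until FBA-viable.

    Structure: one substrate uptake exchange, a random sparse internal
    network biased toward connectivity (each metabolite is producible from
    a lower-indexed one), and a biomass reaction draining the last
    metabolite.  Identical seeds give identical models.
    """
    from .fba import solve_fba  # local import to avoid a cycle

    if not (n_reactions >= n_metabolites >= 3):
        raise ValueError("need n_reactions >= n_metabolites >= 3")
    rng = np.random.default_rng(seed)

    for attempt in range(1000):
        mets = [Metabolite(id=f"m{i}", compartment="c") for i in range(n_metabolites)]
        sids = [m.species_id for m in mets]
        reactions = [
            Reaction(
                id="EX_m0",
                stoichiometry={sids[0]: -1.0},
                reversible=True,
                bounds=FluxBounds(-10.0, 0.0),
            )
        ]
        # spanning chain guarantees reachability of the biomass precursor
        for i in range(1, n_metabolites):
            src = int(rng.integers(0, i))
            reactions.append(
                Reaction(
                    id=f"R{i}",
                    stoichiometry={
                        sids[src]: -float(rng.integers(1, 3)),
                        sids[i]: float(rng.integers(1, 3)),
                    },
                    reversible=False,
                    bounds=FluxBounds(0.0, FREE_FLUX_BOUND),
                )
            )
        extra = n_reactions - len(reactions) - 1
        for k in range(extra):
            i, j = rng.choice(n_metabolites, size=2, replace=False)
            reversible = bool(rng.random() < 0.3)
            reactions.append(
                Reaction(
                    id=f"X{k}",
                    stoichiometry={
                        sids[int(i)]: -float(rng.integers(1, 3)),
                        sids[int(j)]: float(rng.integers(1, 3)),
                    },
                    reversible=reversible,
                    bounds=FluxBounds(
                        -FREE_FLUX_BOUND if reversible else 0.0, FREE_FLUX_BOUND
                    ),
                )
            )
        reactions.append(
            Reaction(
                id="BIOMASS",
                stoichiometry={sids[-1]: -1.0},
                reversible=False,
                bounds=FluxBounds(0.0, FREE_FLUX_BOUND),
            )
        )
        model = StoichiometricModel(
            metabolites=mets,
            reactions=reactions,
            biomass_reaction_id="BIOMASS",
            id=f"random_{seed}_{attempt}",
        )
        sol = solve_fba(model)
        if sol.optimal and sol.objective_value > 1e-6:
            return model
    raise RuntimeError(
        f"no viable random model found in 1000 attempts "
        f"(n_metabolites={n_metabolites}, n_reactions={n_reactions}, seed={seed})"
    )
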