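# Methods

## Constraint-based model and the FBA linear program

A model is a set of compartmented metabolites (cytosol `c`, periplasm `p`,
extracellular `e`), reactions with signed stoichiometries, flux bounds and
flat gene associations, and a biomass pseudo-reaction that drains
precursors in macromolecular proportions; its flux is the specific growth
rate (1/h), all other fluxes are mmol/gDW/h.

FBA solves `max cᵀv s.t. S v = 0, v_min ≤ v ≤ v_max` with the biomass
reaction as objective. The LP backend is HiGHS (via
`scipy.optimize.linprog`) behind a single interface; primal/dual
feasibility tolerances are 1e-9, and every solution reported as optimal is
additionally checked against a steady-state residual bound `max|S·v| ≤
1e-6`. Solver failures, infeasibility and unboundedness are reported as
explicit statuses with diagnostics, never as a zero optimum.

Conventions:

- **Reversibility** is encoded in the bounds of a single matrix column
  (lower bound < 0), never as split forward/backward columns, so FVA
  ranges read directly as net fluxes.
- **"Free" fluxes** use a global magnitude M = 1000 mmol/gDW/h
  (configurable). No result may depend on M; the suite asserts invariance
  between M = 1000 and M = 10000 on the toy models.
- **Exchange reactions** are single-species boundary columns; uptake is
  negative flux. Scenario files state uptakes as positive rates, mapped to
  bounds `(-rate, 0)`.
- **Gene associations** are flat sets with any-gene-disables semantics:
  knocking out one associated gene disables the reaction, and one gene may
  disable several reactions. No AND/OR rule parsing. (This is the standard
  simplification for knockout enumeration; it overestimates fragility for
  true isozyme sets.)

## Flux variability analysis

After FBA, each queried flux is minimized and maximized with the objective
flux fixed exactly at its optimum (equality bounds; a configurable
`fraction_of_optimum` relaxes this to `[fraction·opt, opt]`). If exact
fixing is numerically infeasible the equality is relaxed in steps of
1e-9 and 1e-7 relative, with a log message. A production claim is made
only when the FVA *minimum* is positive; an FBA vertex flux by itself is
solver-dependent under degenerate optima.

## Trophic conditions

A condition sets photon, CO2, substrate, and nitrogen-source uptake
bounds; CO2, O2, water, sulfate and phosphate are freely exchanged by
default. Autotrophic conditions have zero organic uptake; heterotrophic
conditions have zero photon uptake; mixed settings are rejected.

The photon "uptake rate" is applied as an **equality** (all supplied
photons are absorbed). This models the assumption that absorbed light
energy is not photochemically dissipated: under nutrient limitation the
cell must route excess ATP/NADPH somewhere metabolically, which is what
makes storage-compound and overflow-product envelopes non-trivial. All
other uptakes are capacity bounds (uptake up to the stated rate).

The growth-capability screen fixes each organic substrate's uptake at 10
mmol/gDW/h with zero light and reports growth above a threshold of 1e-6
per hour. The nitrogen-limitation scan fixes nitrate uptake on a grid
(default 40 points from 0 to 1.2× the uptake at the unconstrained
optimum), maximizes growth, and reports FVA ranges for the glycogen
export and each overflow export (ethanol, lactate, acetate, pyruvate,
formate — whichever the model defines) at that optimum.

## Flux response analysis and knockout screening

FRA pins one reaction's flux at each value of a grid (default 21 points
spanning the reaction's feasible interval with the biomass objective
relaxed to `[0, optimum]`, always including the unconstrained-optimum
flux), re-maximizes biomass, and records the target export's FVA range.
Classification uses guaranteed (FVA-minimum) production: a reaction is
activation-enhancing if guaranteed production rises for pinned values
above the base flux, repression-enhancing below it; ties within 1e-6 are
neutral, and infeasible grid points are flagged and skipped.

The knockout screen enumerates gene combinations up to k = 3 (deeper
searches are refused by default — the LP count grows combinatorially),
maps genes to induced reaction-deletion sets, evaluates each distinct set
once, and skips supersets of combinations already found lethal (sound
because deletions only shrink the feasible polytope). Designs are ranked
by guaranteed C-mol yield, then relative growth, then gene ids. C-mol
yield is `100 × product flux × product carbon count / CO2 uptake flux`,
with the CO2 uptake taken from the knockout FBA solution; both the
FVA-minimum-based and FVA-maximum-based yields are reported, and ranking
uses the minimum (the conservative, guaranteed figure).

## The synthetic toy photoautotroph

The generator builds a ~45-reaction, 2-compartment cyanobacterium-like
network carrying every mechanism the genome-scale analyses rely on.
Reducing-power bookkeeping drives its design:

- **Linear electron transport (LET)**: 4 photons → 1 NADPH + 1.5 ATP +
  0.5 O2. ATP and NADPH are co-produced in a *fixed* ratio. This coupling
  is essential: with independently tunable photon→ATP and photon→NADPH
  reactions the cell could always match supply to demand and no knockout
  could ever create a reductant surplus.
- **Calvin cycle lump (CBB)**: CO2 + 3 ATP + 2 NADPH → CH2O, where CH2O
  is one fixed carbon at sugar oxidation level.
- **Respiratory chain**: NADH and NADPH dehydrogenases feed a quinol
  pool oxidized by cytochrome oxidase at 1 ATP per NAD(P)H. Because the
  biomass ATP:NADPH demand ratio (≈1.8 under ammonium) exceeds the LET
  supply ratio (1.5), the wild type *must* respire part of its NADPH to
  close the ATP balance.
- **Oxidative pentose-phosphate shunt (OPP)**: G6P → 5 CH2O + CO2 +
  2 NADPH. Run against refixation it forms a futile cycle that burns
  1 + 3 ATP per turn — the network's only free energy valve (there is no
  explicit maintenance ATPase), and, whenever the Calvin NADPH cost is
  below 2 per carbon, also an ATP→NADPH converter.
- **Lower glycolysis** uses an NADP-dependent glyceraldehyde-phosphate
  dehydrogenase (as in cyanobacteria): 3 CH2O → PEP + NADPH. Oxaloacetate
  for biomass comes solely from PEP carboxylase.
- **Overflow products**: glycogen (via phosphoglucomutase and glycogen
  synthase from G1P, exported through a virtual transporter), ethanol
  (pyruvate decarboxylase + NADPH-linked alcohol dehydrogenase), lactate
  (NADH-linked), acetate and pyruvate. With the respiratory chain deleted,
  ethanol is the only *net* NADPH sink — the strain-design phenotype.
- **Nitrogen**: nitrate reduction costs 4 NADPH per N before ammonium
  assimilation (1 ATP); ammonium enters the same assimilation step
  directly. An extracellular α-ketoglutarate with an exchange but no
  transporter provides a non-utilizable screen substrate.

The biomass equation drains oxaloacetate + nitrogen carrier (protein,
68%), glucose-1-phosphate (carbohydrate, 16%, glucosyl MW 162.141),
CH2O (DNA 0.88% + RNA 3.12% + lipid 11% + chlorophyll 1%, as CH2O
equivalents), 30 mmol ATP and 10 mmol NADPH per gDW. Biomass carbon
content works out to 38.45 mmol C/gDW, in the realistic range for
cyanobacteria.

### Closed-form optima

Because each precursor has a unique cheapest route, the optimum follows
from per-gDW resource accounting. With per-gDW gross demands A (ATP) and
R (NADPH, net of the glycolytic NADPH credit), LET coupling τ = 1.5 ATP
per NADPH, respiratory yield ρ = 1:

- photon cost per gDW = 4·(R + r) with respiration r = (A − τR)/(τ + ρ)
  when A > τR; in the ATP-surplus regime the OPP futile cycle dissipates
  the excess (and its NADPH by-product is credited when the Calvin NADPH
  cost is below 2/C).
- growth = min(photons/photon-cost, CO2/biomass-carbon, N-uptake/N-demand).
- the glycogen FVA maximum under nitrogen limitation is the smaller of an
  NADPH-budget and an ATP-budget bound (glycogen costs 20 ATP + 12 NADPH
  per glucosyl unit), giving the characteristic piecewise-linear envelope
  with a kink where the binding resource switches.
- deleting the respiratory chain forces ethanol at
  e = (A − τR)/(τ·6β − (3α − 1)) mmol per gDW (α, β the Calvin ATP and
  NADPH costs per CO2): the cell must over-run LET to close the ATP gap
  and dump the NADPH surplus into ethanol, whose net cost vector
  (8 ATP, 6 NADPH per ethanol from CO2) is the only one that closes both
  balances. Growth, CO2 uptake and the C-mol yield follow.

These closed forms are exposed on the `ToyModelBundle` and serve as the
solver-independent oracle: the suite checks LP agreement to 1e-8 at the
defaults and across a 50-point random parameter sweep (the knockout form
is swept only over parameters that do not alter which overflow route is
cheapest; the light/fixation stoichiometry stays at its defaults there).

### What the toy does and does not emulate

It reproduces the *mechanisms* — photon-limited growth, nitrogen-source
redox asymmetry, FVA-undetermined overflow under limitation, respiratory
knockout forcing reduced-product secretion — with round, documented
stoichiometries. It does not reproduce any real organism's numbers:
photosystem quantum yields, P/O ratios, biomass monomer masses and the
ATP maintenance are order-of-magnitude realistic choices, not fits.
Passing tests therefore certify the machinery and its invariants, not
genome-scale predictions; analyses of a real reconstruction require that
reconstruction's own supplementary tables (loadable via the XLSX/TSV/SBML
readers).

The random viable-model generator (rejection-sampled sparse networks with
a guaranteed substrate-to-biomass chain, deterministic per seed) is used
only for property tests: steady-state residuals, knockout monotonicity,
and LP-versus-vertex-enumeration agreement on ≤ 8-reaction instances.

## Numerical choices

- LP tolerances 1e-9; steady-state assertion 1e-6; FVA objective-fixing
  relaxation ladder (0, 1e-9, 1e-7 relative); growth threshold 1e-6 /h;
  FRA tie threshold 1e-6.
- Degenerate optima: `solve_fba` returns one optimal vertex
  (solver-dependent); every scientific claim about individual fluxes goes
  through FVA.
- Knockout of an already-blocked reaction is a no-op; evaluating a lethal
  design returns relative growth 0 rather than an error.
- Equation parsing accepts `->`/`→` (irreversible) and `<=>`/`↔`
  (reversible), optional coefficients (> 0), `met[compartment]` species;
  both-side species are net-summed. Rendering uses shortest round-trip
  float formatting so write/load cycles are exact.

## Problem sizes

The shipped analyses run on the 45-reaction toy (LPs solve in
milliseconds): full FVA ≈ 90 LPs, the 40-point nitrogen scan ≈ 500 LPs,
and the restricted 2-way knockout screen over all 25 toy genes ≈ 1000 LPs
— a few seconds in total. Genome-scale models (~750 reactions) load and
solve single FBA/FVA queries in seconds; exhaustive 3-way gene screens
over all genes grow as (genes choose 3) LPs and are the reason the screen
supports candidate restriction, signature deduplication and lethality
pruning.

## Known limitations

- No parsimonious FBA, MOMA/ROOM, loopless constraints, or dynamic FBA.
- No elemental/charge balancing checks or thermodynamic constraints;
  carbon conservation is asserted only on the toys, via the metabolite
  carbon counts.
- Boolean GPR logic is deliberately flattened (see above).
- The C-mol yield of a knockout uses the CO2 uptake of one optimal
  vertex; under degenerate optima the yield range inherits the target
  export's FVA range but not a joint CO2/target variability analysis.
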