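"""Model I/O: reaction-equation grammar, tabular (TSV/XLSX) and SBML formats.

The tabular layout mirrors the supplementary-table style of genome-scale
reconstructions: a reaction table (id, name, equation, genes, subsystem,
reversibility, bounds) and a metabolite table (id, name, compartment,
formula, carbon count).  Reaction equations use the grammar::

    side   := term ("+" term)*        (either side may be empty: exchanges)
    term   := [coef] species
    species:= met_id "[" compartment "]"
    arrow  := "->" | "→"  (irreversible)   "<=>" | "↔"  (reversible)

Left-side species get negative coefficients; species appearing on both
sides are net-summed and dropped when the net is zero.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from .core import (
    FREE_FLUX_BOUND,
    FluxBounds,
    Metabolite,
    ModelStructureError,
    Reaction,
    StoichiometricModel,
)

logger = logging.getLogger(__name__)

IRREVERSIBLE_ARROWS = ("-->", "->", "→", "=>")
REVERSIBLE_ARROWS = ("<==>", "<=>", "<->", "↔")  # longest first

_SPECIES_RE = re.compile(r"^(?P<met>[^\s\[\]]+)\[(?P<comp>[a-z])\]$")
_NUM_RE = re.compile(r"^\d+(\.\d+)?([eE][+-]?\d+)?$|^\.\d+$")

REACTION_COLUMNS = [
    "reaction_id",
    "name",
    "equation",
    "genes",
    "subsystem",
    "lower_bound",
    "upper_bound",
]
METABOLITE_COLUMNS = ["metabolite_id", "name", "compartment", "formula", "n_carbon"]


class EquationParseError(ValueError):
    """Malformed reaction-equation string; carries the offending column."""

    def __init__(self, message: str, column: int):
        super().__init__(f"{message} (column {column})")
        self.column = column


def _find_arrow(text: str) -> tuple[int, int, bool]:
    """Locate the (single) arrow; returns (start, end, reversible)."""
    hits: list[tuple[int, int, bool]] = []
    for arrows, rev in ((REVERSIBLE_ARROWS, True), (IRREVERSIBLE_ARROWS, False)):
        for arrow in arrows:
            start = 0
            while True:
                i = text.find(arrow, start)
                if i < 0:
                    break
                # skip matches inside an already-found longer arrow
                if not any(a <= i < b for a, b, _ in hits):
                    hits.append((i, i + len(arrow), rev))
                start = i + len(arrow)
    if not hits:
        raise EquationParseError("no reaction arrow found", 0)
    if len(hits) > 1:
        hits.sort()
        raise EquationParseError("duplicate reaction arrow", hits[1][0])
    return hits[0]


def _parse_side(text: str, offset: int, sign: float, stoich: dict[str, float]) -> None:
    if not text.strip():
        return
    pos = offset
    for chunk in text.split("+"):
        token = chunk.strip()
        col = pos + chunk.index(token[0]) if token else pos
        if not token:
            raise EquationParseError("empty term", pos)
        parts = token.split()
        if len(parts) == 1:
            coef, species = 1.0, parts[0]
        elif len(parts) == 2:
            if not _NUM_RE.match(parts[0]):
                raise EquationParseError(f"bad coefficient {parts[0]!r}", col)
            coef, species = float(parts[0]), parts[1]
        else:
            raise EquationParseError(f"malformed term {token!r}", col)
        if coef <= 0:
            raise EquationParseError(f"coefficient must be > 0, got {coef}", col)
        m = _SPECIES_RE.match(species)
        if not m:
            raise EquationParseError(
                f"species {species!r} not of form met[compartment]", col
            )
        stoich[species] = stoich.get(species, 0.0) + sign * coef
        pos += len(chunk) + 1


def parse_reaction_equation(equation: str) -> tuple[dict[str, float], bool]:
    """Parse an equation string into (stoichiometry map, reversible flag)."""
    a, b, reversible = _find_arrow(equation)
    stoich: dict[str, float] = {}
    _parse_side(equation[:a], 0, -1.0, stoich)
    _parse_side(equation[b:], b, +1.0, stoich)
    stoich = {s: c for s, c in stoich.items() if c != 0.0}
    if not stoich:
        raise EquationParseError("equation nets to nothing", 0)
    return stoich, reversible


def _fmt_coef(c: float) -> str:
    c = float(c)
    if c == 1.0:
        return ""
    if c.is_integer():
        return f"{int(c)} "
    # repr gives the shortest digit string that round-trips the float
    return f"{c!r} "


def render_reaction_equation(stoich: dict[str, float], reversible: bool) -> str:
    """Inverse of :func:`parse_reaction_equation` (up to term order)."""
    left = [f"{_fmt_coef(-c)}{s}" for s, c in stoich.items() if c < 0]
    right = [f"{_fmt_coef(c)}{s}" for s, c in stoich.items() if c > 0]
    arrow = "<=>" if reversible else "->"
    return f"{' + '.join(left)} {arrow} {' + '.join(right)}".strip()


# -- summaries ---------------------------------------------------------------


@dataclass(frozen=True)
class ModelSummary:
    """Structural counts of a loaded model (Table-1 style)."""

    n_reactions: int
    n_species: int
    n_unique_metabolites: int
    n_intracellular: int
    n_transport: int
    n_exchange: int
    n_genes: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def classify_and_summarize(model: StoichiometricModel) -> ModelSummary:
    """Count reactions per category and metabolites per identity.

    The unique-metabolite count merges compartments (a species present in
    cytosol and periplasm counts once); the species count does not.
    """
    cats = {"intracellular": 0, "transport": 0, "exchange": 0}
    for rxn in model.reactions:
        cats[rxn.category(model)] += 1
    summary = ModelSummary(
        n_reactions=len(model.reactions),
        n_species=len(model.metabolites),
        n_unique_metabolites=len({m.id for m in model.metabolites}),
        n_intracellular=cats["intracellular"],
        n_transport=cats["transport"],
        n_exchange=cats["exchange"],
        n_genes=len(model.genes),
    )
    assert (
        summary.n_intracellular + summary.n_transport + summary.n_exchange
        == summary.n_reactions
    )
    return summary


# -- tabular I/O -------------------------------------------------------------

#: fuzzy header detection for supplementary-style spreadsheets whose exact
#: column names vary; an explicit ``column_map`` overrides this.
_HEADER_ALIASES = {
    "reaction_id": ("reaction_id", "reaction id", "rxn", "abbreviation", "id"),
    "name": ("name", "reaction name", "description"),
    "equation": ("equation", "reaction", "formula", "reaction equation"),
    "genes": ("genes", "gene", "gene_association", "gene association", "gpr", "orf"),
    "subsystem": ("subsystem", "pathway", "category"),
    "lower_bound": ("lower_bound", "lb", "lower bound", "vmin"),
    "upper_bound": ("upper_bound", "ub", "upper bound", "vmax"),
    "metabolite_id": ("metabolite_id", "metabolite id", "metabolite", "abbreviation", "id"),
    "compartment": ("compartment", "comp", "location"),
    "formula": ("formula", "elemental formula", "composition"),
    "n_carbon": ("n_carbon", "carbon", "carbons", "c atoms", "ncarbon"),
}


def _map_columns(df: pd.DataFrame, wanted: list[str], column_map: dict | None) -> pd.DataFrame:
    column_map = column_map or {}
    rename: dict[str, str] = {}
    lowered = {str(c).strip().lower(): c for c in df.columns}
    for target in wanted:
        if target in column_map:
            rename[column_map[target]] = target
            continue
        for alias in _HEADER_ALIASES.get(target, (target,)):
            if alias in lowered and lowered[alias] not in rename:
                rename[lowered[alias]] = target
                break
    return df.rename(columns=rename)


def _clean_str(cell) -> str:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return ""
    return str(cell)


def _split_genes(cell) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or str(cell).strip() == "":
        return frozenset()
    return frozenset(g.strip() for g in re.split(r"[;,\s]+", str(cell)) if g.strip())


def _build_model(
    rxn_df: pd.DataFrame,
    met_df: pd.DataFrame | None,
    biomass_reaction_id: str,
    model_id: str,
    free_bound: float,
) -> StoichiometricModel:
    metabolites: dict[str, Metabolite] = {}
    if met_df is not None:
        for _, row in met_df.iterrows():
            met = Metabolite(
                id=str(row["metabolite_id"]),
                name=_clean_str(row.get("name")),
                compartment=_clean_str(row.get("compartment")) or "c",
                formula=_clean_str(row.get("formula")) or None,
                n_carbon=int(row.get("n_carbon", 0) or 0),
            )
            metabolites[met.species_id] = met

    reactions: list[Reaction] = []
    for i, row in rxn_df.iterrows():
        rid = str(row["reaction_id"]).strip()
        try:
            stoich, reversible = parse_reaction_equation(str(row["equation"]))
        except EquationParseError as exc:
            raise ModelStructureError(
                f"row {i} (reaction {rid!r}): unparseable equation: {exc}"
            ) from exc
        for sid in stoich:
            if sid not in metabolites:
                m = _SPECIES_RE.match(sid)
                logger.warning(
                    "metabolite %s referenced by %s absent from metabolite table; "
                    "auto-stubbed",
                    sid,
                    rid,
                )
                metabolites[sid] = Metabolite(
                    id=m.group("met"), compartment=m.group("comp")
                )
        lb = row.get("lower_bound")
        ub = row.get("upper_bound")
        if pd.notna(lb) and pd.notna(ub):
            bounds = FluxBounds(float(lb), float(ub))
            reversible = bounds.lower < 0
        else:
            bounds = FluxBounds.free(free_bound) if reversible else FluxBounds.forward(free_bound)
        reactions.append(
            Reaction(
                id=rid,
                name=_clean_str(row.get("name")),
                stoichiometry=stoich,
                reversible=reversible,
                bounds=bounds,
                gene_association=_split_genes(row.get("genes")),
                subsystem=_clean_str(row.get("subsystem")),
            )
        )

    if biomass_reaction_id not in {r.id for r in reactions}:
        raise ModelStructureError(
            f"biomass reaction {biomass_reaction_id!r} missing from model"
        )
    model = StoichiometricModel(
        metabolites=list(metabolites.values()),
        reactions=reactions,
        biomass_reaction_id=biomass_reaction_id,
        id=model_id,
    )
    logger.info("loaded model %s: %s", model_id, classify_and_summarize(model))
    return model


def load_model(
    path: str | Path,
    dialect: str | None = None,
    biomass_reaction_id: str = "BIOMASS",
    column_map: dict | None = None,
    free_bound: float = FREE_FLUX_BOUND,
) -> StoichiometricModel:
    """Load a model from TSV, XLSX or SBML.

    For the tabular dialects the reaction table lives in ``<stem>.tsv`` /
    the first sheet, and the metabolite table in ``<stem>.metabolites.tsv``
    / the second sheet; metabolites referenced but not listed are stubbed
    with a warning.
    """
    path = Path(path)
    if dialect is None:
        dialect = {".tsv": "tsv", ".xlsx": "xlsx", ".xml": "sbml", ".sbml": "sbml"}.get(
            path.suffix.lower(), "tsv"
        )
    if dialect == "sbml":
        return read_sbml(path)
    if dialect == "tsv":
        rxn_df = pd.read_csv(path, sep="\t")
        met_path = path.with_suffix("").with_suffix(".metabolites.tsv")
        if not met_path.exists():
            met_path = path.parent / (path.stem + ".metabolites.tsv")
        met_df = pd.read_csv(met_path, sep="\t") if met_path.exists() else None
    elif dialect == "xlsx":
        sheets = pd.read_excel(path, sheet_name=None, engine="openpyxl")
        names = list(sheets)
        rxn_df = sheets[names[0]]
        met_df = sheets[names[1]] if len(names) > 1 else None
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    rxn_df = _map_columns(rxn_df, REACTION_COLUMNS, column_map)
    if met_df is not None:
        met_df = _map_columns(met_df, METABOLITE_COLUMNS, column_map)
    return _build_model(rxn_df, met_df, biomass_reaction_id, path.stem, free_bound)


def model_to_tables(model: StoichiometricModel) -> tuple[pd.DataFrame, pd.DataFrame]:
    rxn_df = pd.DataFrame(
        {
            "reaction_id": [r.id for r in model.reactions],
            "name": [r.name for r in model.reactions],
            "equation": [
                render_reaction_equation(r.stoichiometry, r.reversible)
                for r in model.reactions
            ],
            "genes": [";".join(sorted(r.gene_association)) for r in model.reactions],
            "subsystem": [r.subsystem for r in model.reactions],
            "lower_bound": [r.bounds.lower for r in model.reactions],
            "upper_bound": [r.bounds.upper for r in model.reactions],
        }
    )
    met_df = pd.DataFrame(
        {
            "metabolite_id": [m.id for m in model.metabolites],
            "name": [m.name for m in model.metabolites],
            "compartment": [m.compartment for m in model.metabolites],
            "formula": [m.formula or "" for m in model.metabolites],
            "n_carbon": [m.n_carbon for m in model.metabolites],
        }
    )
    return rxn_df, met_df


def write_model(model: StoichiometricModel, path: str | Path, dialect: str = "tsv") -> None:
    """Write the model as TSV pair, XLSX workbook, or SBML."""
    path = Path(path)
    if dialect == "sbml":
        write_sbml(model, path)
        return
    rxn_df, met_df = model_to_tables(model)
    if dialect == "tsv":
        rxn_df.to_csv(path, sep="\t", index=False)
        met_df.to_csv(path.parent / (path.stem + ".metabolites.tsv"), sep="\t", index=False)
    elif dialect == "xlsx":
        with pd.ExcelWriter(path, engine="openpyxl") as xw:
            rxn_df.to_excel(xw, sheet_name="reactions", index=False)
            met_df.to_excel(xw, sheet_name="metabolites", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# -- SBML --------------------------------------------------------------------


def _sbml_sid(raw: str) -> str:
    return re.sub(r"[^A-Za-z0-9_]", "_", raw)


def write_sbml(model: StoichiometricModel, path: str | Path) -> None:
    """Export as SBML Level 3 with fbc flux bounds and GPRs."""
    import libsbml

    doc = libsbml.SBMLDocument(libsbml.SBMLNamespaces(3, 1, "fbc", 2))
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sbml_sid(model.id))
    fbc = sbml_model.getPlugin("fbc")
    fbc.setStrict(True)

    for code, name in (("c", "cytosol"), ("p", "periplasm"), ("e", "extracellular")):
        comp = sbml_model.createCompartment()
        comp.setId(code)
        comp.setName(name)
        comp.setConstant(True)

    sid_of = {}
    for met in model.metabolites:
        sp = sbml_model.createSpecies()
        sid = f"M_{_sbml_sid(met.id)}_{met.compartment}"
        sid_of[met.species_id] = sid
        sp.setId(sid)
        sp.setName(met.name or met.id)
        sp.setCompartment(met.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        sfbc = sp.getPlugin("fbc")
        if met.formula:
            sfbc.setChemicalFormula(met.formula)

    bound_ids: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_ids:
            p = sbml_model.createParameter()
            pid = f"B_{len(bound_ids)}"
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_ids[value] = pid
        return bound_ids[value]

    for gene in sorted(model.genes):
        gp = fbc.createGeneProduct()
        gp.setId(f"G_{_sbml_sid(gene)}")
        gp.setLabel(gene)

    objective = fbc.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    fbc.setActiveObjectiveId("obj")
    flux_obj = objective.createFluxObjective()
    flux_obj.setReaction(f"R_{_sbml_sid(model.biomass_reaction_id)}")
    flux_obj.setCoefficient(1.0)

    for rxn in model.reactions:
        r = sbml_model.createReaction()
        r.setId(f"R_{_sbml_sid(rxn.id)}")
        r.setName(rxn.name or rxn.id)
        r.setReversible(rxn.bounds.lower < 0)
        r.setFast(False)
        for sid, coef in rxn.stoichiometry.items():
            ref = r.createReactant() if coef < 0 else r.createProduct()
            ref.setSpecies(sid_of[sid])
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rfbc = r.getPlugin("fbc")
        rfbc.setLowerFluxBound(bound_param(rxn.bounds.lower))
        rfbc.setUpperFluxBound(bound_param(rxn.bounds.upper))
        if rxn.gene_association:
            gpa = rfbc.createGeneProductAssociation()
            # any-gene-disables semantics: all listed genes are required
            terms = " and ".join(f"G_{_sbml_sid(g)}" for g in sorted(rxn.gene_association))
            gpa.setAssociation(terms, True, False)  # match by id, no auto-create
    libsbml.writeSBMLToFile(doc, str(path))


def read_sbml(path: str | Path, biomass_reaction_id: str | None = None) -> StoichiometricModel:
    """Import SBML Level 3 (fbc bounds); gene products map to flat gene sets."""
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        raise ModelStructureError(
            f"SBML read error: {doc.getErrorLog().toString()}"
        )
    sbml_model = doc.getModel()

    metabolites = []
    species_of = {}
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        raw = re.sub(r"^M_", "", sp.getId())
        comp = sp.getCompartment()
        raw = re.sub(rf"_{comp}$", "", raw)
        met = Metabolite(id=raw, name=sp.getName(), compartment=comp)
        metabolites.append(met)
        species_of[sp.getId()] = met.species_id

    mfbc = sbml_model.getPlugin("fbc")
    gene_labels = {}
    if mfbc is not None:
        for i in range(mfbc.getNumGeneProducts()):
            gp = mfbc.getGeneProduct(i)
            gene_labels[gp.getId()] = gp.getLabel() or gp.getId()

    def genes_of(rfbc) -> frozenset[str]:
        gpa = rfbc.getGeneProductAssociation() if rfbc else None
        if gpa is None:
            return frozenset()
        labels = set()

        def walk(assoc):
            if assoc is None:
                return
            if assoc.isGeneProductRef():
                gid = assoc.getGeneProduct()
                labels.add(gene_labels.get(gid, gid))
            else:
                for k in range(assoc.getNumAssociations()):
                    walk(assoc.getAssociation(k))

        walk(gpa.getAssociation())
        return frozenset(labels)

    reactions = []
    for i in range(sbml_model.getNumReactions()):
        r = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for k in range(r.getNumReactants()):
            ref = r.getReactant(k)
            stoich[species_of[ref.getSpecies()]] = (
                stoich.get(species_of[ref.getSpecies()], 0.0) - ref.getStoichiometry()
            )
        for k in range(r.getNumProducts()):
            ref = r.getProduct(k)
            stoich[species_of[ref.getSpecies()]] = (
                stoich.get(species_of[ref.getSpecies()], 0.0) + ref.getStoichiometry()
            )
        rfbc = r.getPlugin("fbc")
        lb, ub = -FREE_FLUX_BOUND, FREE_FLUX_BOUND
        if rfbc is not None:
            lp = sbml_model.getParameter(rfbc.getLowerFluxBound())
            up = sbml_model.getParameter(rfbc.getUpperFluxBound())
            if lp is not None:
                lb = lp.getValue()
            if up is not None:
                ub = up.getValue()
        rid = re.sub(r"^R_", "", r.getId())
        reactions.append(
            Reaction(
                id=rid,
                name=r.getName(),
                stoichiometry=stoich,
                reversible=lb < 0,
                bounds=FluxBounds(lb, ub),
                gene_association=genes_of(rfbc),
            )
        )

    if biomass_reaction_id is None:
        candidates = [r.id for r in reactions if "BIOMASS" in r.id.upper()]
        if not candidates:
            raise ModelStructureError("no biomass reaction found in SBML model")
        biomass_reaction_id = candidates[0]
    return StoichiometricModel(
        metabolites=metabolites,
        reactions=reactions,
        biomass_reaction_id=biomass_reaction_id,
        id=sbml_model.getId() or Path(path).stem,
    )
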