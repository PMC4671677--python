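"""Shared fixtures and the brute-force LP oracle for small models."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from cyanoflux import (
    FluxBounds,
    Metabolite,
    Reaction,
    StoichiometricModel,
    TrophicCondition,
    apply_condition,
    build_stoichiometric_matrix,
    make_core_photoautotroph,
)


def vertex_enumeration_optimum(
    model: StoichiometricModel, objective_reaction_id: str, sense: str = "maximize"
) -> float:
    """Brute-force LP optimum by enumerating polytope vertices.

    The feasible set {S v = 0, l <= v <= u} is a polytope; every vertex has
    at least n - rank(S) variables at a bound.  Enumerate all choices of
    fixed variables and bound sides, solve the remaining square-ish linear
    system, keep feasible solutions, and return the best objective.  Only
    practical for models with <= ~8 reactions; independent of any LP solver.
    """
    S = build_stoichiometric_matrix(model).to_numpy()
    n = S.shape[1]
    lo = np.array([r.bounds.lower for r in model.reactions])
    hi = np.array([r.bounds.upper for r in model.reactions])
    rank = np.linalg.matrix_rank(S)
    n_fixed = n - rank
    jobj = model.reaction_ids.index(objective_reaction_id)

    best = None
    for size in range(n_fixed, n + 1):
        for fixed in itertools.combinations(range(n), size):
            free = [j for j in range(n) if j not in fixed]
            for sides in itertools.product((0, 1), repeat=size):
                v = np.zeros(n)
                for j, side in zip(fixed, sides):
                    v[j] = hi[j] if side else lo[j]
                A = S[:, free]
                b = -S[:, list(fixed)] @ v[list(fixed)]
                if free:
                    sol, _, _, _ = np.linalg.lstsq(A, b, rcond=None)
                    if not np.allclose(A @ sol, b, atol=1e-9):
                        continue
                    v[free] = sol
                elif not np.allclose(b, 0.0, atol=1e-9):
                    continue
                if np.all(v >= lo - 1e-9) and np.all(v <= hi + 1e-9):
                    val = v[jobj]
                    if best is None:
                        best = val
                    elif sense == "maximize":
                        best = max(best, val)
                    else:
                        best = min(best, val)
    if best is None:
        raise RuntimeError("vertex enumeration found no feasible vertex")
    return float(best)


def make_chain_model(uptake: float = 10.0) -> StoichiometricModel:
    """EX_A (uptake-limited) -> A -> B -> biomass: optimum equals the uptake."""
    mets = [Metabolite(id=m, compartment="c") for m in ("A", "B")]
    rxns = [
        Reaction(id="EX_A", stoichiometry={"A[c]": -1}, reversible=True,
                 bounds=FluxBounds(-uptake, 0)),
        Reaction(id="R1", stoichiometry={"A[c]": -1, "B[c]": 1},
                 bounds=FluxBounds(0, 1000)),
        Reaction(id="BIO", stoichiometry={"B[c]": -1}, bounds=FluxBounds(0, 1000)),
    ]
    return StoichiometricModel(mets, rxns, biomass_reaction_id="BIO", id="chain")


def make_parallel_model(uptake: float = 10.0) -> StoichiometricModel:
    """Two equivalent A->B paths (isozymes): alternate optima, FVA [0, total]."""
    mets = [Metabolite(id=m, compartment="c") for m in ("A", "B")]
    rxns = [
        Reaction(id="EX_A", stoichiometry={"A[c]": -1}, reversible=True,
                 bounds=FluxBounds(-uptake, 0)),
        Reaction(id="R1", stoichiometry={"A[c]": -1, "B[c]": 1},
                 bounds=FluxBounds(0, 1000), gene_association={"g_iso1"}),
        Reaction(id="R2", stoichiometry={"A[c]": -1, "B[c]": 1},
                 bounds=FluxBounds(0, 1000), gene_association={"g_iso2"}),
        Reaction(id="BIO", stoichiometry={"B[c]": -1}, bounds=FluxBounds(0, 1000)),
    ]
    return StoichiometricModel(mets, rxns, biomass_reaction_id="BIO", id="parallel")


@pytest.fixture(scope="session")
def toy_bundle():
    return make_core_photoautotroph()


@pytest.fixture(scope="session")
def toy_model(toy_bundle):
    return toy_bundle.model


@pytest.fixture(scope="session")
def toy_nitrate(toy_model):
    """Toy model under the standard autotrophic nitrate condition."""
    cond = TrophicCondition.autotrophic(photon=50.0, nitrogen_source="nitrate")
    return apply_condition(toy_model, cond)


@pytest.fixture(scope="session")
def toy_ammonium(toy_model):
    cond = TrophicCondition.autotrophic(photon=50.0, nitrogen_source="ammonium")
    return apply_condition(toy_model, cond)


@pytest.fixture()
def chain_model():
    return make_chain_model()


@pytest.fixture()
def parallel_model():
    return make_parallel_model()
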