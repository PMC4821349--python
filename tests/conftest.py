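import itertools

import numpy as np
import pytest

from metnet.model import MetabolicModel, Metabolite, Reaction
from metnet.gpr import parse_gpr
from metnet.synth import ToySpec, make_toy_model


@pytest.fixture
def toy_branched():
    """Two branches with yields 0.5 / 0.3, one gene per reaction."""
    return make_toy_model(ToySpec(n_branches=2, branch_yields=(0.5, 0.3)))


@pytest.fixture
def toy_nested():
    """Two branches with nested '(gA and (gB or gC))' GPRs."""
    return make_toy_model(
        ToySpec(n_branches=2, branch_yields=(0.5, 0.3), gpr_scheme="nested")
    )


@pytest.fixture
def toy_single():
    """One linear pathway: every pathway gene essential."""
    return make_toy_model(ToySpec(n_branches=1, branch_yields=(0.5,)))


def tiny_model():
    """2 metabolites / 3 reactions / empty GPRs."""
    return MetabolicModel(
        id="tiny",
        metabolites=[Metabolite("a_c"), Metabolite("b_c")],
        reactions=[
            Reaction("IN_a", stoichiometry={"a_c": 1.0}, lower_bound=0, upper_bound=10),
            Reaction("A2B", stoichiometry={"a_c": -1.0, "b_c": 1.0}, lower_bound=0),
            Reaction(
                "OUT_biomass",
                stoichiometry={"b_c": -1.0},
                lower_bound=0,
                objective_coefficient=1.0,
            ),
        ],
    )


@pytest.fixture
def tiny():
    return tiny_model()


# ---------------------------------------------------------------------------
# independent oracles


def enumerate_vertices(model, extra_fixed=None):
    """Brute-force vertex enumeration of {v : S·v=0, lb≤v≤ub}.

    Solves every square system formed by the mass-balance rows plus a
    choice of active bounds; returns the feasible vertices. Only usable
    for toy networks (≤ ~8 reactions).
    """
    S, _, rxn_ids = model.stoichiometric_matrix()
    S = S.toarray()
    n = len(rxn_ids)
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    if extra_fixed:
        for rid, val in extra_fixed.items():
            j = rxn_ids.index(rid)
            lb[j] = ub[j] = val
    rank = np.linalg.matrix_rank(S) if S.size else 0
    need = n - rank
    vertices = []
    choices = [(j, b) for j in range(n) for b in ("lb", "ub")]
    for combo in itertools.combinations(choices, need):
        if len({j for j, _ in combo}) != need:
            continue
        A = [S[i] for i in range(S.shape[0])]
        b = [0.0] * S.shape[0]
        for j, which in combo:
            row = np.zeros(n)
            row[j] = 1.0
            A.append(row)
            b.append(lb[j] if which == "lb" else ub[j])
        A = np.array(A)
        b = np.array(b)
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        if np.max(np.abs(A @ sol - b)) > 1e-8:
            continue
        if np.all(sol >= lb - 1e-8) and np.all(sol <= ub + 1e-8):
            vertices.append(dict(zip(rxn_ids, sol)))
    return vertices


def brute_force_optimum(model, objective=None, extra_fixed=None):
    """Max objective flux over enumerated vertices (LP optimum oracle)."""
    objective = objective or model.objective_reaction()
    vertices = enumerate_vertices(model, extra_fixed)
    assert vertices, "oracle found no feasible vertex"
    return max(v[objective] for v in vertices)
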