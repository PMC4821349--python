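"""Linear-programming core: FBA, lexicographic product maximisation,
linearised MOMA, and robustness scans.

Flux balance analysis (FBA) finds a steady-state flux vector v maximising
an objective (typically biomass) subject to mass balance S·v = 0 and flux
bounds lb ≤ v ≤ ub. All problems here are linear and solved with HiGHS
through :func:`scipy.optimize.linprog`; |·| terms are linearised with
split/auxiliary variables.

The optimal *objective value* is unique and deterministic; the flux vector
itself may be any optimal vertex, so downstream methods that need a
reproducible reference (lMOMA) use a parsimonious tie-break
(:func:`wildtype_reference`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import MetabolicModel

__all__ = [
    "FluxDistribution",
    "MediumSpec",
    "solve_fba",
    "lex_maximize_product",
    "solve_lmoma",
    "wildtype_reference",
    "robustness_scan",
    "flux_range",
    "mass_imbalance",
]

#: default tolerance on ‖S·v‖∞ for a distribution to count as balanced
TOL_BALANCE = 1e-6
#: slack used when fixing a previously optimised flux in a later stage
TOL_FIX = 1e-9


@dataclass
class FluxDistribution:
    """One steady-state flux vector (mmol·gDW⁻¹·h⁻¹) with solve metadata."""

    fluxes: dict[str, float] = field(default_factory=dict)
    objective_value: float | None = None
    status: str = "optimal"  # optimal | infeasible | unbounded
    #: biomass / product fluxes recorded by two-stage optimisations
    biomass: float | None = None
    product: float | None = None

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


@dataclass
class MediumSpec:
    """Exchange-bound overrides defining the growth medium.

    ``overrides`` maps reaction ids to (lower, upper) bounds; uptake is a
    negative lower bound on an exchange reaction. ``aerobic`` opens oxygen
    uptake (EX_o2 lower bound −1000) as a convenience.
    """

    overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    aerobic: bool = False

    def resolve(self, model: MetabolicModel) -> dict[str, tuple[float, float]]:
        out = dict(self.overrides)
        for rid in out:
            if not model.has_reaction(rid):
                raise KeyError(f"medium names unknown reaction {rid!r}")
        if self.aerobic:
            o2 = [
                r.id
                for r in model.reactions
                if r.id.lower().startswith("ex_o2") and r.id not in out
            ]
            for rid in o2:
                out[rid] = (-1000.0, model.get_reaction(rid).upper_bound)
        return out


# ---------------------------------------------------------------------------
# problem assembly


class _Problem:
    """Bounds and stoichiometry of a model with medium/knockouts applied."""

    def __init__(
        self,
        model: MetabolicModel,
        medium: MediumSpec | None = None,
        knockouts: set[str] | frozenset[str] | None = None,
    ):
        self.model = model
        self.S, self.met_ids, self.rxn_ids = model.stoichiometric_matrix()
        self.index = {rid: j for j, rid in enumerate(self.rxn_ids)}
        self.lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
        self.ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
        if medium is not None:
            for rid, (lo, hi) in medium.resolve(model).items():
                j = self.index[rid]
                self.lb[j], self.ub[j] = lo, hi
        for rid in knockouts or ():
            j = self.index.get(rid)
            if j is None:
                raise KeyError(f"knockout names unknown reaction {rid!r}")
            self.lb[j] = self.ub[j] = 0.0

    @property
    def n(self) -> int:
        return len(self.rxn_ids)

    def fix(self, rid: str, value: float, slack: float = 0.0) -> None:
        j = self.index[rid]
        self.lb[j] = value - slack
        self.ub[j] = value + slack

    def maximize(self, rid: str) -> FluxDistribution:
        """max v[rid] s.t. S·v=0, bounds."""
        c = np.zeros(self.n)
        c[self.index[rid]] = -1.0
        return self._solve(c, sense=-1.0)

    def minimize_flux(self, rid: str) -> FluxDistribution:
        c = np.zeros(self.n)
        c[self.index[rid]] = 1.0
        return self._solve(c, sense=1.0)

    def _solve(self, c: np.ndarray, sense: float) -> FluxDistribution:
        res = linprog(
            c,
            A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            bounds=np.column_stack([self.lb, self.ub]),
            method="highs",
        )
        if res.status == 2:
            return FluxDistribution(status="infeasible")
        if res.status == 3:
            return FluxDistribution(status="unbounded")
        if not res.success:
            raise RuntimeError(f"LP solver failure: {res.message}")
        fluxes = dict(zip(self.rxn_ids, (float(x) for x in res.x)))
        return FluxDistribution(fluxes=fluxes, objective_value=float(sense * res.fun))

    def minimize_l1(self, target: np.ndarray) -> FluxDistribution:
        """min Σ|v − target| s.t. S·v=0, bounds (split auxiliary variables)."""
        n = self.n
        eye = sparse.identity(n, format="csr")
        A_eq = sparse.hstack([self.S, sparse.csr_matrix((self.S.shape[0], n))])
        A_ub = sparse.vstack(
            [sparse.hstack([eye, -eye]), sparse.hstack([-eye, -eye])]
        )
        b_ub = np.concatenate([target, -target])
        c = np.concatenate([np.zeros(n), np.ones(n)])
        bounds = np.column_stack(
            [
                np.concatenate([self.lb, np.zeros(n)]),
                np.concatenate([self.ub, np.full(n, np.inf)]),
            ]
        )
        res = linprog(
            c,
            A_eq=A_eq,
            b_eq=np.zeros(self.S.shape[0]),
            A_ub=A_ub,
            b_ub=b_ub,
            bounds=bounds,
            method="highs",
        )
        if res.status == 2:
            return FluxDistribution(status="infeasible")
        if not res.success:
            raise RuntimeError(f"LP solver failure: {res.message}")
        fluxes = dict(zip(self.rxn_ids, (float(x) for x in res.x[:n])))
        return FluxDistribution(fluxes=fluxes, objective_value=float(res.fun))


# ---------------------------------------------------------------------------
# public operations


def solve_fba(
    model: MetabolicModel,
    medium: MediumSpec | None = None,
    objective_reaction: str | None = None,
    knockout_reactions: set[str] | None = None,
) -> FluxDistribution:
    """Maximise the objective flux at steady state.

    Returns a distribution whose ``objective_value`` is the LP optimum;
    infeasible problems return ``status="infeasible"`` with no fluxes.
    """
    obj = objective_reaction or model.objective_reaction()
    prob = _Problem(model, medium, knockout_reactions)
    sol = prob.maximize(obj)
    if sol.ok:
        sol.biomass = sol.fluxes.get(obj)
    return sol


def lex_maximize_product(
    model: MetabolicModel,
    medium: MediumSpec | None,
    product_reaction: str,
    growth_floor: float | None = None,
    knockout_reactions: set[str] | None = None,
    objective_reaction: str | None = None,
) -> FluxDistribution:
    """Two-stage (lexicographic) optimisation: biomass first, then product.

    Stage 1 maximises biomass; stage 2 fixes biomass at its optimum (or at
    ``growth_floor`` × optimum when given, 0 < growth_floor ≤ 1 acting as a
    lower bound) and maximises the product flux. The returned distribution
    records both values (``biomass``, ``product``).
    """
    obj = objective_reaction or model.objective_reaction()
    prob = _Problem(model, medium, knockout_reactions)
    if product_reaction not in prob.index:
        raise KeyError(f"no product reaction {product_reaction!r}")
    stage1 = prob.maximize(obj)
    if not stage1.ok:
        stage1.status = "infeasible"
        return stage1
    b_opt = stage1.objective_value
    slack = TOL_FIX * max(1.0, abs(b_opt))
    if growth_floor is not None:
        j = prob.index[obj]
        prob.lb[j] = growth_floor * b_opt - slack
    else:
        prob.fix(obj, b_opt, slack=slack)
    stage2 = prob.maximize(product_reaction)
    if not stage2.ok:
        return stage2
    stage2.biomass = stage2.fluxes[obj]
    stage2.product = stage2.objective_value
    return stage2


def wildtype_reference(
    model: MetabolicModel,
    medium: MediumSpec | None = None,
    objective_reaction: str | None = None,
) -> FluxDistribution:
    """Reproducible wild-type flux state: FBA optimum with minimal Σ|v|.

    FBA optima are generally degenerate; the parsimonious secondary
    objective picks a canonical vertex so that lMOMA distances are
    well-defined and repeatable.
    """
    obj = objective_reaction or model.objective_reaction()
    prob = _Problem(model, medium)
    stage1 = prob.maximize(obj)
    if not stage1.ok:
        return stage1
    prob.fix(obj, stage1.objective_value, slack=TOL_FIX * max(1.0, abs(stage1.objective_value)))
    sol = prob.minimize_l1(np.zeros(prob.n))
    sol.objective_value = stage1.objective_value
    sol.biomass = sol.fluxes.get(obj)
    return sol


def solve_lmoma(
    model: MetabolicModel,
    wildtype_flux: FluxDistribution,
    knockout_reactions: set[str],
    medium: MediumSpec | None = None,
    objective_reaction: str | None = None,
) -> FluxDistribution:
    """Linear minimisation of metabolic adjustment.

    Finds the mutant steady state minimising the L1 distance
    Σ|vᵢ − v_wt,i| to the wild-type reference, with the knocked-out
    reactions forced to zero. The mutant's growth is read off the solution
    rather than optimised — the premise is that a perturbed cell first
    stays close to its old flux state instead of re-optimising growth.
    """
    obj = objective_reaction or model.objective_reaction()
    prob = _Problem(model, medium, knockout_reactions)
    missing = [rid for rid in prob.rxn_ids if rid not in wildtype_flux.fluxes]
    if missing:
        raise ValueError(
            f"wild-type flux lacks {len(missing)} reactions, e.g. {missing[:3]}"
        )
    target = np.array([wildtype_flux.fluxes[rid] for rid in prob.rxn_ids])
    sol = prob.minimize_l1(target)
    if sol.ok:
        sol.biomass = sol.fluxes.get(obj)
    else:
        sol.biomass = 0.0
    return sol


def flux_range(
    model: MetabolicModel,
    reaction: str,
    medium: MediumSpec | None = None,
) -> tuple[float, float]:
    """Feasible (min, max) flux through one reaction (flux variability)."""
    prob = _Problem(model, medium)
    lo = prob.minimize_flux(reaction)
    hi = prob.maximize(reaction)
    if not (lo.ok and hi.ok):
        raise RuntimeError(f"flux range of {reaction!r}: model infeasible")
    return lo.objective_value, hi.objective_value


def robustness_scan(
    model: MetabolicModel,
    reaction: str,
    n_points: int = 20,
    medium: MediumSpec | None = None,
    objective_reaction: str | None = None,
) -> list[tuple[float, float | None]]:
    """Growth as a function of the flux forced through one reaction.

    The reaction's feasible range is gridded evenly (``n_points`` ≥ 2);
    at each grid value the flux is pinned there and biomass re-maximised.
    Infeasible points report ``None``. A blocked reaction (range {0})
    yields a single-point result.
    """
    if n_points < 2:
        raise ValueError("n_points must be ≥ 2")
    obj = objective_reaction or model.objective_reaction()
    vmin, vmax = flux_range(model, reaction, medium)
    if abs(vmax - vmin) < 1e-12:
        grid = np.array([vmin])
    else:
        grid = np.linspace(vmin, vmax, n_points)
    out: list[tuple[float, float | None]] = []
    for t in grid:
        prob = _Problem(model, medium)
        prob.fix(reaction, float(t), slack=TOL_FIX * max(1.0, abs(t)))
        sol = prob.maximize(obj)
        out.append((float(t), sol.objective_value if sol.ok else None))
    return out


def mass_imbalance(model: MetabolicModel, flux: FluxDistribution) -> float:
    """‖S·v‖∞ over non-boundary metabolites; ≤ 1e-6 for a valid optimum."""
    S, _, rxn_ids = model.stoichiometric_matrix()
    v = np.array([flux.fluxes[rid] for rid in rxn_ids])
    if S.shape[0] == 0:
        return 0.0
    return float(np.max(np.abs(S @ v)))
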