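"""Knockout strain design by bounded local search (GDLS-style).

Given a production target (an exchange or sink reaction), the search
looks for a set of reaction knockouts that raises the product flux the
cell would excrete while still growing. Candidate designs are scored by
lexicographic FBA — maximise biomass first, then the product at that
biomass — mirroring how paired product/growth rates are reported for
engineered strains. The search walks the space of knockout sets in steps
of bounded Hamming distance (neighbourhood size k), keeps at most K
knockouts, enforces a minimum growth rate, and stops at a local optimum.
Deterministic tie-breaking (fewer knockouts, then lexicographic ids)
makes results reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .fba import MediumSpec, lex_maximize_product
from .model import MetabolicModel

__all__ = ["DesignConfig", "DesignResult", "evaluate_design", "gdls_search"]

GROWTH_TOL = 1e-9
IMPROVE_TOL = 1e-9


@dataclass
class DesignConfig:
    """Search parameters for knockout design.

    ``neighborhood_size`` (k): how many knockouts may change per move;
    ``max_knockouts`` (K): design size budget (``None`` = unlimited);
    ``min_growth``: growth floor every accepted design must satisfy
    (mmol·gDW⁻¹·h⁻¹); ``candidate_reactions``: knockout pool, defaulting
    to all non-exchange, non-objective reactions.
    """

    product_reaction: str = ""
    neighborhood_size: int = 2
    max_knockouts: int | None = 5
    min_growth: float = 0.05
    medium: MediumSpec | None = None
    candidate_reactions: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.neighborhood_size < 1:
            raise ValueError("neighborhood_size must be ≥ 1")
        if self.max_knockouts is not None and self.max_knockouts < 0:
            raise ValueError("max_knockouts must be ≥ 0")
        if self.min_growth < 0:
            raise ValueError("min_growth must be ≥ 0")

    def candidates(self, model: MetabolicModel) -> list[str]:
        if self.candidate_reactions is not None:
            return sorted(self.candidate_reactions)
        objective = model.objective_reaction()
        return sorted(
            r.id
            for r in model.reactions
            if not r.is_exchange and r.id not in (objective, self.product_reaction)
        )


@dataclass
class DesignResult:
    knockouts: frozenset[str]
    biomass: float
    product: float
    feasible: bool = True
    trajectory: list[tuple[int, frozenset[str], float]] = field(default_factory=list)


def normalize_reaction_id(rid: str) -> str:
    """Collapse stray whitespace in printed reaction ids ("GLYt2 m" → "GLYt2m")."""
    return "".join(rid.split())


def _resolve_knockouts(model: MetabolicModel, knockouts: set[str]) -> set[str]:
    known = {r.id for r in model.reactions}
    squashed = {normalize_reaction_id(r.id): r.id for r in model.reactions}
    resolved = set()
    for rid in knockouts:
        if rid in known:
            resolved.add(rid)
        elif normalize_reaction_id(rid) in squashed:
            resolved.add(squashed[normalize_reaction_id(rid)])
        else:
            raise KeyError(f"knockout names unknown reaction {rid!r}")
    return resolved


def evaluate_design(
    model: MetabolicModel,
    knockouts: set[str] | frozenset[str],
    config: DesignConfig,
) -> DesignResult:
    """Score a knockout set: biomass-first, then product at that biomass.

    Both bounds of every knocked-out reaction are zeroed, the medium is
    applied, and a two-stage LP records the growth rate and the product
    excretion rate. An infeasible design reports 0/0 and is flagged.
    """
    if not config.product_reaction:
        raise ValueError("config.product_reaction is required")
    resolved = _resolve_knockouts(model, set(knockouts))
    sol = lex_maximize_product(
        model,
        config.medium,
        config.product_reaction,
        knockout_reactions=resolved,
    )
    if not sol.ok:
        return DesignResult(
            knockouts=frozenset(resolved), biomass=0.0, product=0.0, feasible=False
        )
    return DesignResult(
        knockouts=frozenset(resolved), biomass=sol.biomass, product=sol.product
    )


def _neighbourhood(
    current: frozenset[str],
    candidates: list[str],
    k: int,
    max_ko: int | None,
) -> list[frozenset[str]]:
    """All knockout sets within Hamming distance ≤ k of ``current``."""
    pool = [c for c in candidates if c not in current]
    inside = sorted(current)
    seen: set[frozenset[str]] = set()
    out: list[frozenset[str]] = []
    for n_rm in range(0, min(k, len(inside)) + 1):
        for removed in combinations(inside, n_rm):
            base = current - set(removed)
            max_add = k - n_rm
            for n_add in range(0, max_add + 1):
                if n_rm == 0 and n_add == 0:
                    continue
                if max_ko is not None and len(base) + n_add > max_ko:
                    continue
                for added in combinations(pool, n_add):
                    cand = frozenset(base | set(added))
                    if cand != current and cand not in seen:
                        seen.add(cand)
                        out.append(cand)
    return out


def gdls_search(model: MetabolicModel, config: DesignConfig) -> DesignResult:
    """Local search for a product-maximising knockout set.

    Starts from no knockouts; each round scores every design within
    Hamming distance ≤ k of the incumbent (respecting the knockout budget
    and the growth floor) and moves to the best product improvement,
    preferring fewer knockouts and then lexicographically smaller sets on
    ties. Stops at a local optimum. Raises if even the wild type cannot
    meet the growth floor.
    """
    candidates = config.candidates(model)
    incumbent = frozenset()
    base = evaluate_design(model, incumbent, config)
    if not base.feasible or base.biomass < config.min_growth - GROWTH_TOL:
        raise RuntimeError(
            f"no feasible design: wild-type growth {base.biomass:.4g} is below "
            f"the floor {config.min_growth}"
        )
    best = base
    trajectory = [(0, incumbent, base.product)]
    iteration = 0
    while True:
        iteration += 1
        moves: list[tuple[float, int, tuple[str, ...], frozenset[str], DesignResult]] = []
        for cand in _neighbourhood(
            incumbent, candidates, config.neighborhood_size, config.max_knockouts
        ):
            res = evaluate_design(model, cand, config)
            if not res.feasible or res.biomass < config.min_growth - GROWTH_TOL:
                continue
            moves.append((-res.product, len(cand), tuple(sorted(cand)), cand, res))
        if not moves:
            break
        moves.sort()
        _, _, _, cand, res = moves[0]
        if res.product <= best.product + IMPROVE_TOL:
            break
        incumbent, best = cand, res
        trajectory.append((iteration, incumbent, res.product))
    best.trajectory = trajectory
    return best
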