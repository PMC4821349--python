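"""Genome-scale metabolic model containers.

A :class:`MetabolicModel` is the substrate of every optimisation in this
package: a stoichiometric network of metabolites and reactions with flux
bounds (mmol·gDW⁻¹·h⁻¹), GPR rules, and a biomass-style objective. The
stoichiometric matrix S has one row per non-boundary metabolite and one
column per reaction; steady state means S·v = 0.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse

from .gpr import Gpr

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ModelValidationError",
    "validate_model",
]

DEFAULT_BOUND = 1000.0


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    boundary: bool = False


@dataclass
class Reaction:
    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    subsystem: str = ""
    gpr: Gpr | None = None
    objective_coefficient: float = 0.0

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def is_exchange(self) -> bool:
        """Boundary reactions: single-metabolite or EX_-prefixed."""
        return self.id.startswith("EX_") or len(self.stoichiometry) == 1

    def genes(self) -> frozenset[str]:
        return self.gpr.genes() if self.gpr is not None else frozenset()


@dataclass
class MetabolicModel:
    id: str
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)

    # -- lookups ---------------------------------------------------------

    @property
    def genes(self) -> frozenset[str]:
        """Gene set, derived as the union of all GPR leaves."""
        out: set[str] = set()
        for r in self.reactions:
            out |= r.genes()
        return frozenset(out)

    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"no reaction {rid!r} in model {self.id!r}")

    def get_metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(f"no metabolite {mid!r} in model {self.id!r}")

    def has_reaction(self, rid: str) -> bool:
        return any(r.id == rid for r in self.reactions)

    # -- structure -------------------------------------------------------

    def stoichiometric_matrix(self) -> tuple[sparse.csr_matrix, list[str], list[str]]:
        """S over non-boundary metabolites.

        Returns (S, row metabolite ids, column reaction ids).
        """
        rows = [m.id for m in self.metabolites if not m.boundary]
        ridx = {mid: i for i, mid in enumerate(rows)}
        cols = self.reaction_ids()
        data, ii, jj = [], [], []
        for j, rxn in enumerate(self.reactions):
            for mid, coef in rxn.stoichiometry.items():
                i = ridx.get(mid)
                if i is not None:
                    ii.append(i)
                    jj.append(j)
                    data.append(coef)
        S = sparse.csr_matrix(
            (np.asarray(data, dtype=float), (ii, jj)), shape=(len(rows), len(cols))
        )
        return S, rows, cols

    def objective_reaction(self) -> str:
        """Resolve the objective reaction id.

        Prefers an explicit nonzero objective coefficient; falls back to the
        unique reaction whose id contains "biomass" (case-insensitive).
        """
        flagged = [r.id for r in self.reactions if r.objective_coefficient != 0]
        if len(flagged) == 1:
            return flagged[0]
        if len(flagged) > 1:
            raise ModelValidationError(
                f"multiple objective reactions flagged: {sorted(flagged)}"
            )
        biomass = [r.id for r in self.reactions if "biomass" in r.id.lower()]
        if len(biomass) == 1:
            return biomass[0]
        if not biomass:
            raise ModelValidationError(f"model {self.id!r} has no objective reaction")
        raise ModelValidationError(
            f"ambiguous biomass objective candidates: {sorted(biomass)}"
        )

    # -- editing ---------------------------------------------------------

    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)

    def with_reactions_removed(self, remove: set[str]) -> "MetabolicModel":
        """Sub-model without ``remove``; orphan metabolites are pruned.

        Genes are derived from GPRs, so genes appearing only in removed
        reactions disappear automatically.
        """
        kept = [_copy.deepcopy(r) for r in self.reactions if r.id not in remove]
        used = {mid for r in kept for mid in r.stoichiometry}
        mets = [replace(m) for m in self.metabolites if m.id in used]
        return MetabolicModel(id=self.id, metabolites=mets, reactions=kept)


def validate_model(model: MetabolicModel) -> list[str]:
    """Check structural invariants; returns human-readable violations.

    Reports rather than raises: an empty list means the model is valid.
    """
    issues: list[str] = []
    seen_m: set[str] = set()
    for m in model.metabolites:
        if not m.id:
            issues.append("metabolite with empty id")
            continue
        if m.id in seen_m:
            issues.append(f"duplicate metabolite id {m.id!r}")
        seen_m.add(m.id)
        if not m.compartment:
            issues.append(f"metabolite {m.id!r}: empty compartment")
    seen_r: set[str] = set()
    n_objective = 0
    for r in model.reactions:
        if not r.id:
            issues.append("reaction with empty id")
            continue
        if r.id in seen_r:
            issues.append(f"duplicate reaction id {r.id!r}")
        seen_r.add(r.id)
        if r.lower_bound > r.upper_bound:
            issues.append(
                f"reaction {r.id!r}: lower_bound {r.lower_bound} > "
                f"upper_bound {r.upper_bound}"
            )
        for mid in r.stoichiometry:
            if mid not in seen_m and mid not in {m.id for m in model.metabolites}:
                issues.append(
                    f"reaction {r.id!r}: stoichiometry references "
                    f"undeclared metabolite {mid!r}"
                )
        if r.gpr is not None:
            for g in r.gpr.genes():
                if not g:
                    issues.append(f"reaction {r.id!r}: empty gene id in GPR")
        if r.objective_coefficient != 0:
            n_objective += 1
    if n_objective > 1:
        issues.append(f"{n_objective} reactions carry a nonzero objective coefficient")
    return issues
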