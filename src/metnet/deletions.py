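"""GPR-aware single-gene deletion screening and essentiality statistics.

Deleting a gene disables every reaction whose GPR rule evaluates false
once that gene is removed: a gene in several reactions takes them all
down, while a reaction backed by isoenzymes (OR) survives single
deletions. Disabled reactions have both flux bounds set to zero and
growth is re-computed with FBA or linear MOMA.

Mutants are classified in three phenotype classes relative to the
unmutated optimum: *unchanged* (growing at > 99.9 % of wild type),
*no_growth* (growth at the solver noise floor), and *reduced* in
between. When comparing against an experimental essential-gene list,
"lethal" means the no_growth class.
"""

from __future__ import annotations

from dataclasses import dataclass

from .fba import FluxDistribution, MediumSpec, solve_fba, solve_lmoma, wildtype_reference
from .model import MetabolicModel

__all__ = [
    "DeletionResult",
    "ConfusionSummary",
    "reactions_disabled_by",
    "single_gene_deletion_screen",
    "confusion_vs_reference",
    "GROWTH_ZERO_TOL",
    "UNCHANGED_RATIO",
]

#: absolute growth below which a mutant counts as non-growing (LP noise floor)
GROWTH_ZERO_TOL = 1e-6
#: growth ratio above which a mutant counts as unchanged
UNCHANGED_RATIO = 0.999


@dataclass
class DeletionResult:
    gene: str
    disabled_reactions: frozenset[str]
    growth: float
    growth_ratio: float
    phenotype: str  # no_growth | reduced | unchanged


@dataclass
class ConfusionSummary:
    """Confusion counts of in-silico growth calls against annotated essentiality.

    Positive = the model predicts growth after the deletion; a true
    positive is therefore a *non-essential* gene whose mutant grows.
    """

    tp: int
    fn: int
    fp: int
    tn: int
    dropped: int = 0  # reference genes absent from the screen

    @property
    def sensitivity(self) -> float:
        """100·TP/(TP+FN), percent."""
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def ppv(self) -> float:
        """100·TP/(TP+FP), percent."""
        return 100.0 * self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")


def reactions_disabled_by(model: MetabolicModel, deleted_genes: set[str]) -> frozenset[str]:
    """Reactions whose GPR evaluates false with ``deleted_genes`` removed.

    Reactions without a gene association are never disabled. Unknown gene
    ids are allowed and have no effect.
    """
    deleted = frozenset(deleted_genes)
    return frozenset(
        r.id
        for r in model.reactions
        if r.gpr is not None and not r.gpr.active_after_deletion(deleted)
    )


def _classify(growth: float, wild_type: float) -> tuple[float, str]:
    ratio = growth / wild_type if wild_type > GROWTH_ZERO_TOL else 0.0
    if growth <= GROWTH_ZERO_TOL:
        return max(ratio, 0.0), "no_growth"
    if ratio > UNCHANGED_RATIO:
        return ratio, "unchanged"
    return ratio, "reduced"


def single_gene_deletion_screen(
    model: MetabolicModel,
    method: str = "fba",
    medium: MediumSpec | None = None,
    genes: list[str] | None = None,
) -> list[DeletionResult]:
    """Delete each model gene in turn and score mutant growth.

    ``method`` is ``"fba"`` (mutant re-optimises growth) or ``"lmoma"``
    (mutant stays L1-closest to a parsimonious wild-type reference).
    Infeasible mutants score growth 0. Results come back in sorted gene
    order, one per gene.
    """
    if method not in ("fba", "lmoma"):
        raise ValueError(f"unknown deletion method {method!r}")
    gene_list = sorted(genes) if genes is not None else sorted(model.genes)
    wt = solve_fba(model, medium=medium)
    if not wt.ok:
        raise RuntimeError("wild-type model is infeasible under the given medium")
    wt_growth = wt.objective_value
    reference: FluxDistribution | None = None
    if method == "lmoma":
        reference = wildtype_reference(model, medium=medium)

    # deletions sharing a disabled-reaction set share a growth value
    cache: dict[frozenset[str], float] = {frozenset(): wt_growth}
    results: list[DeletionResult] = []
    for gene in gene_list:
        disabled = reactions_disabled_by(model, {gene})
        if disabled not in cache:
            if method == "fba":
                sol = solve_fba(model, medium=medium, knockout_reactions=set(disabled))
                growth = sol.objective_value if sol.ok else 0.0
            else:
                sol = solve_lmoma(model, reference, set(disabled), medium=medium)
                growth = sol.biomass if sol.ok else 0.0
            cache[disabled] = growth
        ratio, phenotype = _classify(cache[disabled], wt_growth)
        results.append(
            DeletionResult(
                gene=gene,
                disabled_reactions=disabled,
                growth=cache[disabled],
                growth_ratio=ratio,
                phenotype=phenotype,
            )
        )
    return results


def confusion_vs_reference(
    results: list[DeletionResult],
    essential_reference: set[str],
) -> ConfusionSummary:
    """Score growth predictions against an annotated essential-gene list.

    A gene absent from the reference is treated as inessential. Reference
    genes that were not screened are dropped (counted in ``dropped``), not
    scored as false calls.
    """
    if not results:
        raise ValueError("no deletion results to score")
    screened = {r.gene for r in results}
    dropped = len(set(essential_reference) - screened)
    tp = fn = fp = tn = 0
    for r in results:
        predicts_growth = r.phenotype != "no_growth"
        essential = r.gene in essential_reference
        if predicts_growth and not essential:
            tp += 1
        elif not predicts_growth and not essential:
            fn += 1
        elif predicts_growth and essential:
            fp += 1
        else:
            tn += 1
    return ConfusionSummary(tp=tp, fn=fn, fp=fp, tn=tn, dropped=dropped)


def phenotype_counts(results: list[DeletionResult]) -> dict[str, int]:
    """Tally of the three phenotype classes (sums to the gene count)."""
    out = {"no_growth": 0, "reduced": 0, "unchanged": 0}
    for r in results:
        out[r.phenotype] += 1
    return out
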