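"""Expression-evidence consensus and model extraction (GIMME / iMAT).

The cross-species workflow: map each model gene against per-species
transcriptomes (homology hit tables), call a gene *present* in a species
when it has a hit at or below an e-value threshold (1e-4 by default,
merging the genome-guided and de-novo assembly strategies with OR), and
intersect presence across species to get a consensus gene set. Gene-level
evidence is then pushed onto reactions through the GPR rules (AND→min,
OR→max) and a context-specific sub-model is extracted with either

* **GIMME** — an LP that keeps a required fraction of the optimal biomass
  while minimising flux through below-threshold reactions, weighted by
  how far below threshold they are; zero-flux penalised reactions are
  dropped; or
* **iMAT** — a MILP that classifies reactions as high/low expressed by
  quantile and maximises (# high reactions carrying flux ≥ ε) +
  (# low reactions carrying none); inactive low reactions are dropped.

Both prune metabolites and genes that no longer appear in any reaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp, linprog

from .fba import solve_fba
from .model import MetabolicModel

__all__ = [
    "HomologyHit",
    "EvidenceTable",
    "ExtractionConfig",
    "ModelDiff",
    "presence_calls",
    "consensus_gene_set",
    "map_reaction_expression",
    "extract_gimme",
    "extract_imat",
    "compare_models",
]

EVALUE_DEFAULT = 1e-4
FLUX_ZERO_TOL = 1e-6


@dataclass
class HomologyHit:
    """One row of a BLAST tabular (outfmt 6) hit, annotated with species/strategy."""

    query: str
    subject: str
    identity: float
    align_length: int
    evalue: float
    bitscore: float
    species: str
    strategy: str = "genome_guided"  # genome_guided | de_novo


@dataclass
class EvidenceTable:
    """Per-gene, per-species presence calls, kept per assembly strategy.

    ``data[gene][species]`` is a set of strategies with supporting
    evidence; merged presence is the OR over strategies.
    """

    data: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    def add(self, gene: str, species: str, strategy: str) -> None:
        self.data.setdefault(gene, {}).setdefault(species, set()).add(strategy)

    def present(self, gene: str, species: str, strategy: str | None = None) -> bool:
        strategies = self.data.get(gene, {}).get(species, set())
        return bool(strategies) if strategy is None else strategy in strategies

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.data)

    @property
    def species(self) -> frozenset[str]:
        return frozenset(s for per in self.data.values() for s in per)


def presence_calls(hits: list[HomologyHit], evalue_max: float = EVALUE_DEFAULT) -> EvidenceTable:
    """Call a gene present in (species, strategy) iff it has a hit with
    e-value ≤ ``evalue_max``. Idempotent under duplicated hits."""
    table = EvidenceTable()
    for h in hits:
        if h.evalue <= evalue_max:
            table.add(h.query, h.species, h.strategy)
    return table


def consensus_gene_set(evidence: EvidenceTable, species: list[str]) -> frozenset[str]:
    """Genes with merged evidence in *every* listed species."""
    if not species:
        raise ValueError("need at least one species")
    return frozenset(
        g for g in evidence.genes if all(evidence.present(g, s) for s in species)
    )


def map_reaction_expression(
    model: MetabolicModel, gene_values: dict[str, float]
) -> dict[str, float | None]:
    """Push gene-level expression onto reactions through the GPR rules.

    AND nodes take the min of their children (complex limited by its
    scarcest subunit), OR nodes the max (best isoenzyme). Reactions with
    no gene association — and genes missing from ``gene_values`` — map to
    ``None`` ("unevidenced"), which extraction treats as above threshold.
    """
    out: dict[str, float | None] = {}
    for r in model.reactions:
        if r.gpr is None:
            out[r.id] = None
            continue
        if not (r.gpr.genes() & gene_values.keys()):
            out[r.id] = None
            continue
        out[r.id] = r.gpr.fold(gene_values, missing=float("inf"))
        if out[r.id] == float("inf"):
            out[r.id] = None
    return out


# ---------------------------------------------------------------------------
# extraction


@dataclass
class ExtractionConfig:
    """Tunable knobs of the two extraction algorithms.

    ``expression_threshold`` (GIMME's T): reactions below it are
    penalised; ``None`` uses the median of the evidenced reaction values.
    ``required_fraction`` (f): fraction of the optimal biomass the
    extracted model must retain. ``imat_low``/``imat_high``: expression
    quantiles splitting reactions into low/middle/high classes.
    ``activity_epsilon``: minimum |flux| for a high reaction to count as
    active in iMAT.
    """

    expression_threshold: float | None = None
    required_fraction: float = 0.9
    imat_low: float = 0.25
    imat_high: float = 0.75
    activity_epsilon: float = 1.0
    milp_time_limit: float = 300.0

    def __post_init__(self) -> None:
        if not (0 < self.required_fraction <= 1):
            raise ValueError("required_fraction must be in (0, 1]")
        if not (self.imat_low < self.imat_high):
            raise ValueError("imat_low must be < imat_high")
        if self.activity_epsilon <= 0:
            raise ValueError("activity_epsilon must be > 0")


def _evidenced(reaction_expression: dict[str, float | None]) -> dict[str, float]:
    return {r: x for r, x in reaction_expression.items() if x is not None}


def extract_gimme(
    model: MetabolicModel,
    reaction_expression: dict[str, float | None],
    config: ExtractionConfig | None = None,
) -> MetabolicModel:
    """GIMME extraction: drop below-threshold reactions the network can
    do without while keeping ``required_fraction`` of optimal biomass.

    Solves min Σ_{x_i<T} (T − x_i)·|v_i| s.t. S·v = 0, bounds, and
    biomass ≥ f·optimum, then removes penalised reactions with zero flux
    in the minimiser and prunes orphaned metabolites/genes.
    """
    config = config or ExtractionConfig()
    evid = _evidenced(reaction_expression)
    T = (
        config.expression_threshold
        if config.expression_threshold is not None
        else (float(np.median(list(evid.values()))) if evid else 0.0)
    )

    wt = solve_fba(model)
    if not wt.ok:
        raise RuntimeError("input model is infeasible; cannot extract")
    floor = config.required_fraction * wt.objective_value

    S, _, rxn_ids = model.stoichiometric_matrix()
    n = len(rxn_ids)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    weights = np.zeros(n)
    for j, rid in enumerate(rxn_ids):
        x = reaction_expression.get(rid)
        if x is not None and x < T:
            weights[j] = T - x

    # split v = vp − vn so |v| = vp + vn at the optimum of penalised terms
    lp = np.maximum(lb, 0.0)
    up = np.maximum(ub, 0.0)
    ln = np.maximum(-ub, 0.0)
    un = np.maximum(-lb, 0.0)
    A_eq = sparse.hstack([S, -S], format="csr")
    obj_j = rxn_ids.index(model.objective_reaction())
    biomass_row = sparse.csr_matrix(
        (np.array([-1.0, 1.0]), (np.zeros(2, dtype=int), [obj_j, n + obj_j])),
        shape=(1, 2 * n),
    )
    res = linprog(
        np.concatenate([weights, weights]),
        A_eq=A_eq,
        b_eq=np.zeros(S.shape[0]),
        A_ub=biomass_row,
        b_ub=np.array([-floor]),
        bounds=np.column_stack(
            [np.concatenate([lp, ln]), np.concatenate([up, un])]
        ),
        method="highs",
    )
    if res.status == 2:
        raise RuntimeError(
            f"GIMME functionality constraint infeasible at required_fraction="
            f"{config.required_fraction}"
        )
    if not res.success:
        raise RuntimeError(f"GIMME LP failed: {res.message}")
    v = res.x[:n] - res.x[n:]
    remove = {
        rid
        for j, rid in enumerate(rxn_ids)
        if weights[j] > 0 and abs(v[j]) <= FLUX_ZERO_TOL
    }
    return model.with_reactions_removed(remove)


def extract_imat(
    model: MetabolicModel,
    reaction_expression: dict[str, float | None],
    config: ExtractionConfig | None = None,
) -> MetabolicModel:
    """iMAT extraction via mixed-integer programming.

    Reactions are split by expression quantile into high (≥ ``imat_high``
    quantile), low (≤ ``imat_low`` quantile) and middle; unevidenced
    reactions are unconstrained (middle). The MILP maximises the number of
    high reactions carrying |v| ≥ ε plus the number of low reactions
    carrying no flux; low reactions inactive in the optimum are removed.
    """
    config = config or ExtractionConfig()
    evid = _evidenced(reaction_expression)
    if evid:
        values = np.array(list(evid.values()), dtype=float)
        q_low = float(np.quantile(values, config.imat_low))
        q_high = float(np.quantile(values, config.imat_high))
    else:
        q_low, q_high = -np.inf, np.inf
    eps = config.activity_epsilon

    S, _, rxn_ids = model.stoichiometric_matrix()
    n = len(rxn_ids)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    high = [j for j, rid in enumerate(rxn_ids) if rid in evid and evid[rid] >= q_high]
    low = [
        j
        for j, rid in enumerate(rxn_ids)
        if rid in evid and evid[rid] <= q_low and evid[rid] < q_high
    ]

    # columns: v (n) | yf,yb per high reaction | y0 per low reaction
    n_bin = 2 * len(high) + len(low)
    ncol = n + n_bin
    rows, cols, vals, lo_c, hi_c = [], [], [], [], []
    row = 0

    def add_entry(r: int, c: int, v: float) -> None:
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(S.shape[0]):
        start, end = S.indptr[i], S.indptr[i + 1]
        for k in range(start, end):
            add_entry(row, int(S.indices[k]), float(S.data[k]))
        lo_c.append(0.0)
        hi_c.append(0.0)
        row += 1

    col = n
    c_obj = np.zeros(ncol)
    for j in high:
        yf, yb = col, col + 1
        col += 2
        c_obj[yf] = c_obj[yb] = -1.0  # milp minimises
        # forward active: v_j + yf·(lb_j − ε) ≥ lb_j
        add_entry(row, j, 1.0)
        add_entry(row, yf, lb[j] - eps)
        lo_c.append(lb[j])
        hi_c.append(np.inf)
        row += 1
        # backward active: v_j + yb·(ub_j + ε) ≤ ub_j
        add_entry(row, j, 1.0)
        add_entry(row, yb, ub[j] + eps)
        lo_c.append(-np.inf)
        hi_c.append(ub[j])
        row += 1
        # at most one direction
        add_entry(row, yf, 1.0)
        add_entry(row, yb, 1.0)
        lo_c.append(-np.inf)
        hi_c.append(1.0)
        row += 1
    low_bin: dict[int, int] = {}
    for j in low:
        y0 = col
        col += 1
        low_bin[j] = y0
        c_obj[y0] = -1.0
        # y0 = 1 forces v_j = 0
        add_entry(row, j, 1.0)
        add_entry(row, y0, ub[j])
        lo_c.append(-np.inf)
        hi_c.append(ub[j])
        row += 1
        add_entry(row, j, 1.0)
        add_entry(row, y0, lb[j])
        lo_c.append(lb[j])
        hi_c.append(np.inf)
        row += 1

    A = sparse.csr_matrix((vals, (rows, cols)), shape=(row, ncol))
    lower = np.concatenate([lb, np.zeros(n_bin)])
    upper = np.concatenate([ub, np.ones(n_bin)])
    integrality = np.concatenate([np.zeros(n), np.ones(n_bin)])
    res = milp(
        c=c_obj,
        constraints=LinearConstraint(A, np.array(lo_c), np.array(hi_c)),
        bounds=Bounds(lower, upper),
        integrality=integrality,
        options={"time_limit": config.milp_time_limit},
    )
    if res.status == 1:
        raise RuntimeError(
            f"iMAT MILP hit the {config.milp_time_limit:.0f} s time limit; "
            "no partial result is returned"
        )
    if not res.success:
        raise RuntimeError(f"iMAT MILP failed: {res.message}")
    v = res.x[:n]
    remove = {
        rxn_ids[j]
        for j, y0 in low_bin.items()
        if res.x[y0] > 0.5 and abs(v[j]) <= FLUX_ZERO_TOL
    }
    return model.with_reactions_removed(remove)


# ---------------------------------------------------------------------------
# structural comparison


@dataclass
class ModelDiff:
    """Structured difference between two models; empty ⇔ equivalent."""

    reactions_only_in_a: list[str] = field(default_factory=list)
    reactions_only_in_b: list[str] = field(default_factory=list)
    metabolites_only_in_a: list[str] = field(default_factory=list)
    metabolites_only_in_b: list[str] = field(default_factory=list)
    genes_only_in_a: list[str] = field(default_factory=list)
    genes_only_in_b: list[str] = field(default_factory=list)
    reactions_differing: list[str] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not any(
            [
                self.reactions_only_in_a,
                self.reactions_only_in_b,
                self.metabolites_only_in_a,
                self.metabolites_only_in_b,
                self.genes_only_in_a,
                self.genes_only_in_b,
                self.reactions_differing,
            ]
        )


def _gpr_equivalent(a, b) -> bool:
    if a is None or b is None:
        return a is None and b is None
    if a.genes() != b.genes():
        return False
    if len(a.genes()) <= 16:
        return a.truth_table() == b.truth_table()
    return a.to_string() == b.to_string()


def compare_models(
    a: MetabolicModel, b: MetabolicModel, bound_tol: float = 1e-9
) -> ModelDiff:
    """Structural diff: id sets, stoichiometries, bounds (to ``bound_tol``)
    and GPRs compared as truth tables, not as strings."""
    diff = ModelDiff()
    ra = {r.id: r for r in a.reactions}
    rb = {r.id: r for r in b.reactions}
    diff.reactions_only_in_a = sorted(ra.keys() - rb.keys())
    diff.reactions_only_in_b = sorted(rb.keys() - ra.keys())
    ma = {m.id for m in a.metabolites}
    mb = {m.id for m in b.metabolites}
    diff.metabolites_only_in_a = sorted(ma - mb)
    diff.metabolites_only_in_b = sorted(mb - ma)
    diff.genes_only_in_a = sorted(a.genes - b.genes)
    diff.genes_only_in_b = sorted(b.genes - a.genes)
    for rid in sorted(ra.keys() & rb.keys()):
        x, y = ra[rid], rb[rid]
        same = (
            x.stoichiometry == y.stoichiometry
            and abs(x.lower_bound - y.lower_bound) <= bound_tol
            and abs(x.upper_bound - y.upper_bound) <= bound_tol
            and _gpr_equivalent(x.gpr, y.gpr)
        )
        if not same:
            diff.reactions_differing.append(rid)
    return diff
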