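"""Synthetic inputs with known ground truth.

Every input format the analysis consumes can be generated here: toy
metabolic models whose optima and essential genes are known by
construction, negative-binomial count matrices with the four-species /
two-replicate design of the yeast comparison (with planted fold changes
and planted coexpression modules), and homology hit tables with planted
presence/absence patterns. All generators are deterministic under a
fixed seed, and their outputs pass the corresponding readers unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .extraction import HomologyHit
from .fba import solve_fba
from .gpr import parse_gpr
from .model import MetabolicModel, Metabolite, Reaction

__all__ = [
    "ToySpec",
    "ToyModel",
    "ExprSimSpec",
    "make_toy_model",
    "simulate_expression",
    "simulate_homology",
    "DEFAULT_SPECIES",
]

DEFAULT_SPECIES = ("Sce", "Spa", "Smi", "Sba")


# ---------------------------------------------------------------------------
# toy metabolic models


@dataclass
class ToySpec:
    """A branched toy network: uptake → n parallel branches → biomass.

    Each branch converts substrate to biomass precursor at its own yield
    (in (0, 1]); the FBA optimum is uptake_bound × max(yields).
    ``gpr_scheme``: ``none`` (no gene associations), ``simple`` (one gene
    per reaction), or ``nested`` ("(gA and (gB or gC))" per branch step).
    """

    n_branches: int = 2
    branch_yields: tuple[float, ...] = (0.5, 0.3)
    gpr_scheme: str = "simple"
    uptake_bound: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_branches < 1:
            raise ValueError("toy model needs at least one branch")
        if len(self.branch_yields) != self.n_branches:
            raise ValueError("one yield per branch required")
        if any(not (0 < y <= 1) for y in self.branch_yields):
            raise ValueError("branch yields must lie in (0, 1]")
        if self.gpr_scheme not in ("none", "simple", "nested"):
            raise ValueError(f"unknown gpr_scheme {self.gpr_scheme!r}")


@dataclass
class ToyModel:
    model: MetabolicModel
    essential_genes: frozenset[str]
    fba_optimum: float


def _branch_gpr(scheme: str, branch: int, step: str) -> str:
    if scheme == "none":
        return ""
    if scheme == "simple":
        return f"gB{branch}{step}"
    return f"(gA{branch}{step} and (gB{branch}{step} or gC{branch}{step}))"


def make_toy_model(spec: ToySpec) -> ToyModel:
    """Build the toy network and compute its ground truth.

    Essential genes are found by the built-in exhaustive oracle: every
    single-gene deletion is applied by truth-table evaluation of the GPRs
    and scored with one LP each.
    """
    mets = [
        Metabolite("sub_e", "substrate (extracellular)", "e"),
        Metabolite("sub_c", "substrate", "c"),
        Metabolite("biom_c", "biomass precursor", "c"),
    ]
    rxns = [
        Reaction(
            "EX_sub(e)",
            "substrate exchange",
            {"sub_e": -1.0},
            lower_bound=-spec.uptake_bound,
            upper_bound=0.0,
        ),
        Reaction(
            "SUBt",
            "substrate transport",
            {"sub_e": -1.0, "sub_c": 1.0},
            lower_bound=0.0,
            gpr=parse_gpr("" if spec.gpr_scheme == "none" else "gT"),
        ),
    ]
    for i, y in enumerate(spec.branch_yields, start=1):
        mid = f"mid{i}_c"
        mets.append(Metabolite(mid, f"branch {i} intermediate", "c"))
        rxns.append(
            Reaction(
                f"B{i}a",
                f"branch {i} step a",
                {"sub_c": -1.0, mid: 1.0},
                lower_bound=0.0,
                gpr=parse_gpr(_branch_gpr(spec.gpr_scheme, i, "a")),
            )
        )
        rxns.append(
            Reaction(
                f"B{i}b",
                f"branch {i} step b",
                {mid: -1.0, "biom_c": float(y)},
                lower_bound=0.0,
                gpr=parse_gpr(_branch_gpr(spec.gpr_scheme, i, "b")),
            )
        )
    rxns.append(
        Reaction(
            "BIOMASS_toy",
            "biomass drain",
            {"biom_c": -1.0},
            lower_bound=0.0,
            objective_coefficient=1.0,
        )
    )
    model = MetabolicModel(id=f"toy_{spec.n_branches}branch", metabolites=mets, reactions=rxns)

    optimum = spec.uptake_bound * max(spec.branch_yields)

    essentials: set[str] = set()
    wt = solve_fba(model)
    for gene in sorted(model.genes):
        disabled = {
            r.id
            for r in model.reactions
            if r.gpr is not None and not r.gpr.active_after_deletion({gene})
        }
        sol = solve_fba(model, knockout_reactions=disabled)
        growth = sol.objective_value if sol.ok else 0.0
        if growth <= 1e-6 * max(1.0, wt.objective_value):
            essentials.add(gene)
    return ToyModel(
        model=model, essential_genes=frozenset(essentials), fba_optimum=optimum
    )


# ---------------------------------------------------------------------------
# expression simulation


@dataclass
class ExprSimSpec:
    """Negative-binomial count simulation with species/replicate structure.

    Defaults emulate the yeast study design: four species with two
    replicates each. Variance is μ + αμ² (α = ``dispersion``).
    ``planted_degs``: (gene, species, fold) triples multiplying that
    gene's mean in that species. ``planted_modules``: (genes, loading,
    noise_sd) triples sharing a per-sample latent factor on the log2
    scale. ``mean_sigma`` adds an optional log-normal spread to per-gene
    baseline means (0 = all genes share ``baseline_mean``).
    """

    n_genes: int = 1000
    species: tuple[str, ...] = DEFAULT_SPECIES
    replicates_per_species: int = 2
    baseline_mean: float = 100.0
    dispersion: float = 0.1
    mean_sigma: float = 0.0
    module_amplitude: float = 2.0
    planted_degs: list[tuple[str, str, float]] = field(default_factory=list)
    planted_modules: list[tuple[tuple[str, ...], float, float]] = field(
        default_factory=list
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if any(fold <= 0 for _, _, fold in self.planted_degs):
            raise ValueError("planted fold changes must be > 0")
        if any(not (-1 <= load <= 1) for _, load, _ in self.planted_modules):
            raise ValueError("module loadings must lie in [-1, 1]")


def gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def simulate_expression(spec: ExprSimSpec) -> ExpressionMatrix:
    """Draw the count matrix described by ``spec`` (reproducible by seed)."""
    rng = np.random.default_rng(spec.seed)
    genes = gene_names(spec.n_genes)
    samples = [
        f"{sp}_r{rep + 1}"
        for sp in spec.species
        for rep in range(spec.replicates_per_species)
    ]
    sample_species = [s.rsplit("_r", 1)[0] for s in samples]
    n_s = len(samples)

    base = np.full(spec.n_genes, spec.baseline_mean)
    if spec.mean_sigma > 0:
        base = base * rng.lognormal(0.0, spec.mean_sigma, size=spec.n_genes)
    lib = rng.uniform(0.7, 1.3, size=n_s)

    log2_shift = np.zeros((spec.n_genes, n_s))
    gidx = {g: i for i, g in enumerate(genes)}
    for gene, species, fold in spec.planted_degs:
        i = gidx[gene]
        for j, sp in enumerate(sample_species):
            if sp == species:
                log2_shift[i, j] += np.log2(fold)
    for module_genes, loading, noise_sd in spec.planted_modules:
        z = rng.normal(0.0, 1.0, size=n_s)
        for gene in module_genes:
            i = gidx[gene]
            log2_shift[i, :] += loading * spec.module_amplitude * z
            if noise_sd > 0:
                log2_shift[i, :] += rng.normal(0.0, noise_sd, size=n_s)

    mu = base[:, None] * lib[None, :] * np.power(2.0, log2_shift)
    if spec.dispersion > 0:
        r = 1.0 / spec.dispersion
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p)
    else:
        counts = rng.poisson(mu)

    lengths = pd.Series(
        rng.integers(300, 3001, size=spec.n_genes), index=genes, name="length"
    )
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    meta = pd.DataFrame(
        {
            "species": sample_species,
            "replicate": [int(s.rsplit("_r", 1)[1]) for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )
    return ExpressionMatrix(counts=counts_df, gene_lengths=lengths, samples=meta)


# ---------------------------------------------------------------------------
# homology hit simulation


def simulate_homology(
    genes: list[str],
    species: list[str],
    presence: dict[tuple[str, str], bool],
    seed: int = 0,
    strategies: tuple[str, ...] = ("genome_guided", "de_novo"),
) -> list[HomologyHit]:
    """Hit tables realising a planted presence/absence pattern.

    Present (gene, species) pairs get at least one strong hit
    (e-value ≤ 1e-6) in at least one strategy; absent pairs get either no
    hit at all or a decoy with e-value ≥ 1e-2, so presence calls at the
    1e-4 threshold recover the planted map exactly.
    """
    rng = np.random.default_rng(seed)
    hits: list[HomologyHit] = []
    for gene in genes:
        for sp in species:
            if presence.get((gene, sp), False):
                supporting = [
                    s for s in strategies if rng.random() < 0.8
                ] or [strategies[int(rng.integers(len(strategies)))]]
                for strat in supporting:
                    for _ in range(int(rng.integers(1, 4))):
                        hits.append(
                            HomologyHit(
                                query=gene,
                                subject=f"{sp}_{strat[:2]}_t{int(rng.integers(1e5)):05d}",
                                identity=float(rng.uniform(85, 100)),
                                align_length=int(rng.integers(120, 2000)),
                                evalue=float(10.0 ** -rng.uniform(6, 50)),
                                bitscore=float(rng.uniform(100, 2000)),
                                species=sp,
                                strategy=strat,
                            )
                        )
            elif rng.random() < 0.3:
                hits.append(
                    HomologyHit(
                        query=gene,
                        subject=f"{sp}_decoy_t{int(rng.integers(1e5)):05d}",
                        identity=float(rng.uniform(60, 80)),
                        align_length=int(rng.integers(40, 120)),
                        evalue=float(10.0 ** -rng.uniform(0, 2)),
                        bitscore=float(rng.uniform(20, 50)),
                        species=sp,
                        strategy=strategies[int(rng.integers(len(strategies)))],
                    )
                )
    return hits
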