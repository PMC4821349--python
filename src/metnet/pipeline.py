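"""End-to-end orchestration of the consensus-network workflow.

One declarative config drives the four-stage analysis: (1) homology
evidence → per-species presence calls, (2) intersection to a consensus
gene set, (3) GIMME and iMAT extraction of a consensus sub-model (with an
agreement check between the two), and (4) simulation and annotation —
single-gene deletion screen, robustness scan, coexpression network, and
optional knockout design. Every stage's parameters, inputs, outputs, and
summary counts go into a JSON manifest; identical configs and seeds
reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import tables
from .deletions import phenotype_counts, single_gene_deletion_screen
from .design import DesignConfig, gdls_search
from .expression import build_coexpression, nb_pairwise_test
from .extraction import (
    ExtractionConfig,
    compare_models,
    consensus_gene_set,
    extract_gimme,
    extract_imat,
    map_reaction_expression,
    presence_calls,
)
from .fba import robustness_scan, solve_fba
from .io import read_model, write_model

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    model_path: str = ""
    hits_paths: list[str] = field(default_factory=list)
    expression_path: str = ""  # directory with counts/lengths/samples TSVs
    species: list[str] = field(default_factory=lambda: ["Sce", "Spa", "Smi", "Sba"])
    outgroup: str = "Sba"
    evalue_max: float = 1e-4
    deg_p_cutoff: float = 0.05
    r_min: float = 0.90
    variance_filter_quantile: float = 0.25
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    deletion_method: str = "fba"
    robustness_reaction: str = ""
    design_product: str = ""
    design_max_knockouts: int = 5
    design_min_growth: float = 0.05
    out_dir: str = "pipeline_out"
    seed: int = 0

    def validate(self) -> None:
        if not self.model_path or not Path(self.model_path).exists():
            raise FileNotFoundError(f"model not found: {self.model_path!r}")
        for p in self.hits_paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"hit table not found: {p!r}")
        if self.expression_path and not Path(self.expression_path).exists():
            raise FileNotFoundError(
                f"expression bundle not found: {self.expression_path!r}"
            )
        if self.outgroup not in self.species:
            raise ValueError(f"outgroup {self.outgroup!r} not in species list")


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    extraction = ExtractionConfig(**raw.pop("extraction", {}))
    return PipelineConfig(extraction=extraction, **raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages; returns (and writes) the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {
            **{
                k: v
                for k, v in asdict(config).items()
                if k != "extraction"
            },
            "extraction": asdict(config.extraction),
        },
        "stages": [],
        "outputs": {},
    }

    def record(stage: str, **counts) -> None:
        manifest["stages"].append({"stage": stage, **counts})

    def emit(key: str, path: Path) -> None:
        manifest["outputs"][key] = {
            "path": str(path),
            "sha256": _sha256(path),
        }

    def fail(stage: str, exc: Exception) -> PipelineError:
        (out / "FAILED").write_text(f"{stage}: {exc}\n")
        return PipelineError(stage, str(exc))

    # stage 1-2: evidence and consensus gene set
    try:
        model = read_model(config.model_path)
        record("load_model", metabolites=len(model.metabolites),
               reactions=len(model.reactions), genes=len(model.genes))
    except Exception as exc:
        raise fail("load_model", exc) from exc

    consensus = None
    if config.hits_paths:
        try:
            hits = [h for p in config.hits_paths for h in tables.read_hits(p)]
            evidence = presence_calls(hits, config.evalue_max)
            consensus = consensus_gene_set(evidence, config.species)
            (out / "consensus_genes.txt").write_text(
                "\n".join(sorted(consensus)) + "\n"
            )
            emit("consensus_genes", out / "consensus_genes.txt")
            record("consensus", hits=len(hits),
                   evidenced_genes=len(evidence.genes),
                   consensus_genes=len(consensus))
        except Exception as exc:
            raise fail("consensus", exc) from exc

    # stage 3: extraction (both algorithms, then agreement check)
    working = model
    if consensus is not None:
        try:
            gene_values = {
                g: (1.0 if g in consensus else 0.0) for g in model.genes
            }
            rxn_expr = map_reaction_expression(model, gene_values)
            cfg = config.extraction
            if cfg.expression_threshold is None:
                cfg = ExtractionConfig(
                    expression_threshold=0.5,
                    required_fraction=cfg.required_fraction,
                    imat_low=cfg.imat_low,
                    imat_high=cfg.imat_high,
                    activity_epsilon=cfg.activity_epsilon,
                    milp_time_limit=cfg.milp_time_limit,
                )
            gimme = extract_gimme(model, rxn_expr, cfg)
            imat = extract_imat(model, rxn_expr, cfg)
            diff = compare_models(gimme, imat)
            working = gimme
            write_model(working, out / "consensus_model", format="tsv")
            emit("consensus_model_reactions", out / "consensus_model" / "reactions.tsv")
            record(
                "extraction",
                gimme_reactions=len(gimme.reactions),
                imat_reactions=len(imat.reactions),
                removed_reactions=len(model.reactions) - len(gimme.reactions),
                genes=len(gimme.genes),
                methods_agree=diff.empty,
            )
        except Exception as exc:
            raise fail("extraction", exc) from exc

    # stage 4a: growth and deletion phenotypes
    try:
        wt = solve_fba(working)
        results = single_gene_deletion_screen(working, method=config.deletion_method)
        tables.write_deletions(results, out / "deletions.tsv")
        emit("deletions", out / "deletions.tsv")
        record("deletion_screen", optimal_flux=wt.objective_value,
               **phenotype_counts(results))
    except Exception as exc:
        raise fail("deletion_screen", exc) from exc

    # stage 4b: robustness
    if config.robustness_reaction:
        try:
            scan = robustness_scan(working, config.robustness_reaction)
            lines = ["forced_flux\tbiomass"] + [
                f"{t:.6g}\t{'' if b is None else format(b, '.6g')}" for t, b in scan
            ]
            (out / "robustness.tsv").write_text("\n".join(lines) + "\n")
            emit("robustness", out / "robustness.tsv")
            record("robustness", points=len(scan))
        except Exception as exc:
            raise fail("robustness", exc) from exc

    # stage 4c: expression statistics
    if config.expression_path:
        try:
            matrix = tables.read_expression_bundle(config.expression_path)
            others = [s for s in config.species if s != config.outgroup]
            deg_tables = {
                sp: nb_pairwise_test(
                    matrix, config.outgroup, sp, p_cutoff=config.deg_p_cutoff
                )
                for sp in others
            }
            for sp, calls in deg_tables.items():
                tables.write_deg_table(
                    calls, out / f"deg_{config.outgroup}_vs_{sp}.tsv"
                )
                emit(f"deg_{sp}", out / f"deg_{config.outgroup}_vs_{sp}.tsv")
            edges = build_coexpression(
                matrix,
                variance_filter_quantile=config.variance_filter_quantile,
                r_min=config.r_min,
            )
            tables.write_edges(edges, out / "coexpression_edges.tsv")
            emit("coexpression", out / "coexpression_edges.tsv")
            record(
                "expression",
                genes=matrix.counts.shape[0],
                samples=matrix.counts.shape[1],
                degs={sp: sum(c.is_deg for c in calls)
                      for sp, calls in deg_tables.items()},
                edges=len(edges),
            )
        except Exception as exc:
            raise fail("expression", exc) from exc

    # stage 4d: strain design
    if config.design_product:
        try:
            design = gdls_search(
                working,
                DesignConfig(
                    product_reaction=config.design_product,
                    max_knockouts=config.design_max_knockouts,
                    min_growth=config.design_min_growth,
                ),
            )
            (out / "design.tsv").write_text(
                "iteration\tknockouts\tproduct\n"
                + "\n".join(
                    f"{i}\t{','.join(sorted(ko))}\t{prod:.6g}"
                    for i, ko, prod in design.trajectory
                )
                + "\n"
            )
            emit("design", out / "design.tsv")
            record("design", knockouts=sorted(design.knockouts),
                   biomass=design.biomass, product=design.product)
        except Exception as exc:
            raise fail("design", exc) from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
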