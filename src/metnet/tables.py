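"""Flat-file readers/writers for the pipeline's tabular interfaces.

All formats are plain TSV so that runs are diffable and reproducible:
BLAST tabular hits (outfmt 6 plus species/strategy columns), expression
bundles (counts/lengths/samples), essential-gene lists (one systematic
name per line), flux vectors, DEG tables and coexpression edge lists.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .deletions import DeletionResult
from .expression import CoexpressionEdge, DegCall, ExpressionMatrix
from .extraction import HomologyHit
from .fba import FluxDistribution, MediumSpec

__all__ = [
    "read_hits",
    "write_hits",
    "read_expression_bundle",
    "write_expression_bundle",
    "read_gene_list",
    "read_medium",
    "write_flux",
    "write_deg_table",
    "write_edges",
    "write_deletions",
]

#: BLAST -outfmt 6 columns followed by the two annotation columns
HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    "species", "strategy",
]


def read_hits(
    path: str | Path,
    species: str | None = None,
    strategy: str | None = None,
) -> list[HomologyHit]:
    """Read an annotated BLAST tabular file.

    Files carrying only the 12 standard columns need ``species`` (and
    optionally ``strategy``) supplied by the caller — the filename
    convention ``<species>__<strategy>.tsv`` is used when neither is
    given.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == 12:
        if species is None:
            stem = path.stem
            if "__" in stem:
                species, strategy = stem.split("__", 1)
            else:
                raise ValueError(
                    f"{path}: 12-column hit table needs species/strategy "
                    "annotation (columns 13-14, arguments, or a "
                    "'<species>__<strategy>' filename)"
                )
        df["species"] = species
        df["strategy"] = strategy or "genome_guided"
    if df.shape[1] != 14:
        raise ValueError(f"{path}: expected 12 or 14 columns, got {df.shape[1]}")
    df.columns = HIT_COLUMNS
    return [
        HomologyHit(
            query=str(r.qseqid),
            subject=str(r.sseqid),
            identity=float(r.pident),
            align_length=int(r.length),
            evalue=float(r.evalue),
            bitscore=float(r.bitscore),
            species=str(r.species),
            strategy=str(r.strategy),
        )
        for r in df.itertuples()
    ]


def write_hits(hits: list[HomologyHit], path: str | Path) -> None:
    rows = [
        (
            h.query, h.subject, h.identity, h.align_length, 0, 0,
            1, h.align_length, 1, h.align_length, h.evalue, h.bitscore,
            h.species, h.strategy,
        )
        for h in hits
    ]
    pd.DataFrame(rows, columns=HIT_COLUMNS).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_expression_bundle(directory: str | Path) -> ExpressionMatrix:
    """Read counts.tsv (gene × sample), lengths.tsv and samples.tsv."""
    directory = Path(directory)
    counts = pd.read_csv(directory / "counts.tsv", sep="\t", index_col=0)
    lengths = pd.read_csv(directory / "lengths.tsv", sep="\t", index_col=0).iloc[:, 0]
    samples = pd.read_csv(directory / "samples.tsv", sep="\t", index_col=0)
    return ExpressionMatrix(counts=counts, gene_lengths=lengths, samples=samples)


def write_expression_bundle(matrix: ExpressionMatrix, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    matrix.counts.to_csv(directory / "counts.tsv", sep="\t")
    matrix.gene_lengths.rename("length").to_frame().rename_axis("gene").to_csv(
        directory / "lengths.tsv", sep="\t"
    )
    matrix.samples.to_csv(directory / "samples.tsv", sep="\t")


def read_gene_list(path: str | Path) -> frozenset[str]:
    """One systematic gene name per line; blank lines and # comments skipped."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return frozenset(out)


def read_medium(path: str | Path) -> MediumSpec:
    """Medium TSV with columns reaction_id, lb, ub."""
    df = pd.read_csv(path, sep="\t")
    overrides = {
        str(r.reaction_id): (float(r.lb), float(r.ub)) for r in df.itertuples()
    }
    return MediumSpec(overrides=overrides)


def write_flux(flux: FluxDistribution, path: str | Path) -> None:
    pd.DataFrame(
        sorted(flux.fluxes.items()), columns=["reaction_id", "flux"]
    ).to_csv(path, sep="\t", index=False)


def write_deg_table(calls: list[DegCall], path: str | Path) -> None:
    pd.DataFrame(
        [
            (c.gene, c.fold_change, c.log2_fold_change, c.p_value, int(c.is_deg))
            for c in calls
        ],
        columns=["gene", "fold_change", "log2_fold_change", "p_value", "is_deg"],
    ).to_csv(path, sep="\t", index=False)


def write_edges(edges: list[CoexpressionEdge], path: str | Path) -> None:
    pd.DataFrame(
        [(e.gene_a, e.gene_b, e.r) for e in edges],
        columns=["gene_a", "gene_b", "r"],
    ).to_csv(path, sep="\t", index=False)


def write_deletions(results: list[DeletionResult], path: str | Path) -> None:
    pd.DataFrame(
        [(r.gene, r.growth, r.growth_ratio, r.phenotype) for r in results],
        columns=["gene", "growth", "ratio", "phenotype"],
    ).to_csv(path, sep="\t", index=False)
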