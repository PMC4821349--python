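"""Cross-species RNA-seq statistics.

Covers the quantification and comparison layer of the workflow: RPKM
expression levels, a simplified negative-binomial (NB) test for
differential expression between species, outgroup-consistent divergence
calls, correlation-threshold coexpression networks, and contig-length
summaries (N50) for assembly QC.

The differential-expression test follows the classic count-model recipe:
median-of-ratios size factors, a pooled method-of-moments NB dispersion,
and an exact-style conditional test on the group count sums. It is a
deliberately simple NB test — no dispersion shrinkage across genes — and
is documented as such; it targets correct type-I behaviour and good power
at ≥2-fold effects, not numerical agreement with any particular DE
package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "DegCall",
    "CoexpressionEdge",
    "rpkm",
    "rpkm_matrix",
    "size_factors",
    "nb_pairwise_test",
    "call_divergent",
    "build_coexpression",
    "assembly_stats",
]

P_CUTOFF = 0.05
FC_HIGH = 2.0
FC_LOW = 0.5
R_MIN_DEFAULT = 0.90


@dataclass
class ExpressionMatrix:
    """Gene × sample read counts with gene lengths and sample metadata.

    ``counts``: integer DataFrame (genes × samples). ``gene_lengths``:
    exon length in bp per gene (Series indexed like counts). ``samples``:
    DataFrame indexed by sample with columns ``species`` and
    ``replicate``. Library sizes are the per-sample count totals.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative read counts")
        missing = self.counts.index.difference(self.gene_lengths.index)
        if len(missing):
            raise ValueError(f"genes without length: {list(missing[:3])}")
        if (self.gene_lengths.loc[self.counts.index] <= 0).any():
            raise ValueError("non-positive gene length")
        if not self.counts.columns.equals(self.samples.index):
            raise ValueError("sample metadata does not match count columns")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def samples_of(self, species: str) -> list[str]:
        sel = self.samples.index[self.samples["species"] == species]
        if len(sel) == 0:
            raise KeyError(f"no samples for species {species!r}")
        return list(sel)

    def species_list(self) -> list[str]:
        return list(dict.fromkeys(self.samples["species"]))


@dataclass
class DegCall:
    gene: str
    log2_fold_change: float
    p_value: float
    is_deg: bool
    fold_change: float = float("nan")


@dataclass(frozen=True)
class CoexpressionEdge:
    """Unordered coexpressed gene pair with its Pearson correlation."""

    gene_a: str
    gene_b: str
    r: float

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError("self-edge")
        if self.gene_a > self.gene_b:
            a, b = self.gene_b, self.gene_a
            object.__setattr__(self, "gene_a", a)
            object.__setattr__(self, "gene_b", b)


# ---------------------------------------------------------------------------
# RPKM


def rpkm(counts: float, library_size: float, gene_length: float) -> float:
    """Reads per kilobase of exon per million mapped reads: 10⁹·C/(N·L)."""
    if library_size <= 0:
        raise ValueError("library size must be > 0")
    if gene_length <= 0:
        raise ValueError("gene length must be > 0")
    return 1e9 * counts / (library_size * gene_length)


def rpkm_matrix(matrix: ExpressionMatrix) -> pd.DataFrame:
    N = matrix.library_sizes
    L = matrix.gene_lengths.loc[matrix.counts.index]
    return 1e9 * matrix.counts.div(N, axis=1).div(L, axis=0)


# ---------------------------------------------------------------------------
# differential expression


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalisation factors.

    Each sample's factor is the median across genes of its count divided
    by that gene's geometric mean, using only genes with all-positive
    counts.
    """
    log_counts = np.log(counts.where(counts > 0))
    log_geomean = log_counts.mean(axis=1)
    usable = np.isfinite(log_geomean)
    if not usable.any():
        return pd.Series(1.0, index=counts.columns)
    ratios = log_counts.loc[usable].sub(log_geomean[usable], axis=0)
    return np.exp(ratios.median(axis=0))


def _nb_sum_pmf(k: np.ndarray, mean: float, var: float) -> np.ndarray:
    """pmf of a group count sum, NB-approximated by its mean and variance."""
    if var <= mean * (1 + 1e-12):
        return stats.poisson.pmf(k, mean)
    p = mean / var
    r = mean * mean / (var - mean)
    return stats.nbinom.pmf(k, r, p)


def _exact_test_gene(
    ka: int, kb: int, sa: np.ndarray, sb: np.ndarray, alpha: float
) -> float:
    """Conditional two-sided test of equal NB means given the total count.

    Under H0 both groups share mean μ̂ per normalised unit; the group sums
    are approximated as NB with means μ̂·Σs and variances Σ(μ̂s + αμ̂²s²).
    The p-value sums the joint probabilities of all splits of the total
    that are no more likely than the observed one.
    """
    total = ka + kb
    if total == 0:
        return 1.0
    mu = total / (sa.sum() + sb.sum())
    mean_a = mu * sa.sum()
    var_a = float(np.sum(mu * sa + alpha * (mu * sa) ** 2))
    mean_b = mu * sb.sum()
    var_b = float(np.sum(mu * sb + alpha * (mu * sb) ** 2))
    a = np.arange(total + 1)
    joint = _nb_sum_pmf(a, mean_a, var_a) * _nb_sum_pmf(total - a, mean_b, var_b)
    denom = joint.sum()
    if denom <= 0:
        return 1.0
    observed = joint[ka]
    return float(min(1.0, joint[joint <= observed * (1 + 1e-12)].sum() / denom))


def nb_pairwise_test(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    p_cutoff: float = P_CUTOFF,
) -> list[DegCall]:
    """Per-gene NB test of differential expression between two species.

    Size factors are fit on the two groups jointly; dispersion is a
    per-gene method-of-moments estimate pooled across both groups (floored
    at 0). Fold change is the ratio of normalised group means (B over A).
    A gene is a DEG when p < ``p_cutoff`` and fold change > 2 or < 0.5
    (strict inequalities; all-zero genes get p = 1 and no call).
    """
    cols_a = matrix.samples_of(group_a)
    cols_b = matrix.samples_of(group_b)
    sub = matrix.counts[cols_a + cols_b]
    sf = size_factors(sub)
    sa = sf[cols_a].to_numpy()
    sb = sf[cols_b].to_numpy()
    norm = sub.div(sf, axis=1)
    norm_a = norm[cols_a].to_numpy()
    norm_b = norm[cols_b].to_numpy()

    # per-gene method-of-moments overdispersion, pooled across the two
    # groups: within-group variance of normalised counts minus the Poisson
    # shot-noise part, divided by the squared mean
    xi = float(np.mean(1.0 / np.concatenate([sa, sb])))
    raw_alpha = np.full(len(sub.index), np.nan)
    mus = np.zeros(len(sub.index))
    for i in range(len(sub.index)):
        qa, qb = norm_a[i], norm_b[i]
        mu = np.concatenate([qa, qb]).mean()
        mus[i] = mu
        within = 0.0
        dof = 0
        for g in (qa, qb):
            if len(g) >= 2:
                within += g.var(ddof=1) * (len(g) - 1)
                dof += len(g) - 1
        if dof and mu > 0:
            raw_alpha[i] = (within / dof - mu * xi) / (mu * mu)
    # few replicates make per-gene estimates very noisy and biased toward
    # zero after flooring, which would inflate the type-I error; share
    # strength across genes and keep the larger of the per-gene and the
    # pooled estimate (conservative "maximum" sharing)
    finite = raw_alpha[np.isfinite(raw_alpha)]
    alpha_pool = float(np.median(finite)) if finite.size else 0.0
    alpha_pool = max(alpha_pool, 0.0)

    calls: list[DegCall] = []
    for i, gene in enumerate(sub.index):
        ka = int(round(sub.iloc[i][cols_a].sum()))
        kb = int(round(sub.iloc[i][cols_b].sum()))
        if ka + kb == 0:
            calls.append(DegCall(gene, float("nan"), 1.0, False))
            continue
        qa, qb = norm_a[i], norm_b[i]
        a_gene = raw_alpha[i] if np.isfinite(raw_alpha[i]) else 0.0
        alpha = max(a_gene, alpha_pool, 0.0)
        p = _exact_test_gene(ka, kb, sa, sb, alpha)
        mean_a, mean_b = qa.mean(), qb.mean()
        if mean_a > 0 and mean_b > 0:
            fc = mean_b / mean_a
            lfc = float(np.log2(fc))
        elif mean_b > 0:
            fc, lfc = float("inf"), float("inf")
        else:
            fc, lfc = 0.0, float("-inf")
        is_deg = p < p_cutoff and (fc > FC_HIGH or fc < FC_LOW)
        calls.append(DegCall(gene, lfc, p, bool(is_deg), fold_change=fc))
    return calls


def call_divergent(
    deg_tables: dict[str, list[DegCall]],
    outgroup: str,
    species: list[str] | None = None,
) -> dict[str, str]:
    """Genes with outgroup-consistent divergent expression.

    ``deg_tables`` maps a non-outgroup species name to the DEG table of
    the comparison outgroup-vs-that-species (fold change = species over
    outgroup). A gene is divergent iff it is a DEG in *every* comparison
    with the same tendency: all fold changes > 2 ("down": the outgroup is
    higher — equivalently the gene is down in the outgroup) or all < 0.5
    ("up" in the outgroup). Returns gene → "up"/"down" relative to the
    outgroup.
    """
    wanted = species or sorted(deg_tables)
    for sp in wanted:
        if sp not in deg_tables:
            raise KeyError(f"missing outgroup-vs-{sp} comparison")
        if sp == outgroup:
            raise ValueError("outgroup cannot be compared against itself")
    per_gene: dict[str, list[float]] = {}
    deg_in_all: dict[str, int] = {}
    for sp in wanted:
        for call in deg_tables[sp]:
            if call.is_deg:
                per_gene.setdefault(call.gene, []).append(call.fold_change)
                deg_in_all[call.gene] = deg_in_all.get(call.gene, 0) + 1
    out: dict[str, str] = {}
    for gene, fcs in per_gene.items():
        if deg_in_all[gene] != len(wanted):
            continue
        if all(fc > FC_HIGH for fc in fcs):
            out[gene] = "down"  # expressed higher in the other species
        elif all(fc < FC_LOW for fc in fcs):
            out[gene] = "up"
    return out


# ---------------------------------------------------------------------------
# coexpression


def build_coexpression(
    matrix: ExpressionMatrix,
    variance_filter_quantile: float = 0.25,
    r_min: float = R_MIN_DEFAULT,
) -> list[CoexpressionEdge]:
    """Correlation-threshold coexpression network.

    Expression is log2(RPKM+1); the lowest-variance fraction of genes
    (default 25 %) is removed, constant genes (undefined r) are excluded,
    and every unordered pair with |Pearson r| ≥ ``r_min`` across all
    samples becomes an edge.
    """
    if matrix.counts.shape[1] < 3:
        raise ValueError("need at least 3 samples for coexpression")
    log_expr = np.log2(rpkm_matrix(matrix) + 1.0)
    variances = log_expr.var(axis=1, ddof=1)
    if variance_filter_quantile > 0:
        cutoff = variances.quantile(variance_filter_quantile)
        log_expr = log_expr.loc[variances > cutoff]
    keep = log_expr.std(axis=1, ddof=1) > 0
    log_expr = log_expr.loc[keep]
    genes = list(log_expr.index)
    if len(genes) < 2:
        return []
    R = np.corrcoef(log_expr.to_numpy())
    edges: list[CoexpressionEdge] = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            r = float(R[i, j])
            if abs(r) >= r_min:
                edges.append(CoexpressionEdge(genes[i], genes[j], r))
    return edges


# ---------------------------------------------------------------------------
# assembly summaries


@dataclass
class AssemblySummary:
    n: int
    mean: float
    n50: int


def assembly_stats(lengths: list[int]) -> AssemblySummary:
    """Contig-length summary: count, mean, and N50.

    N50 is the largest length L such that contigs of length ≥ L together
    cover at least half the total assembled length.
    """
    if not lengths:
        raise ValueError("empty contig-length list")
    arr = np.asarray(lengths)
    if (arr <= 0).any():
        raise ValueError("contig lengths must be positive")
    total = arr.sum()
    acc = 0
    for L in sorted(lengths, reverse=True):
        acc += L
        if acc * 2 >= total:
            return AssemblySummary(n=len(lengths), mean=float(arr.mean()), n50=int(L))
    raise AssertionError("unreachable")
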