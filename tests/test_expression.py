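"""RPKM, NB differential expression, divergence, coexpression, N50."""

import itertools

import numpy as np
import pandas as pd
import pytest

from metnet.expression import (
    DegCall,
    ExpressionMatrix,
    assembly_stats,
    build_coexpression,
    call_divergent,
    nb_pairwise_test,
    rpkm,
    rpkm_matrix,
    size_factors,
)
from metnet.synth import ExprSimSpec, gene_names, simulate_expression


# -- RPKM --------------------------------------------------------------------


@pytest.mark.parametrize(
    "c,n,l,expected",
    [
        (0, 1e6, 1000, 0.0),
        (1000, 1e6, 1000, 1000.0),
        (50, 2e7, 500, 5.0),
    ],
)
def test_rpkm_hand_values(c, n, l, expected):
    assert rpkm(c, n, l) == pytest.approx(expected)


def test_rpkm_rejects_bad_inputs():
    with pytest.raises(ValueError):
        rpkm(1, 0, 100)
    with pytest.raises(ValueError):
        rpkm(1, 1e6, 0)


def test_rpkm_matrix_matches_scalar():
    m = simulate_expression(ExprSimSpec(n_genes=5, seed=3))
    R = rpkm_matrix(m)
    N = m.library_sizes
    g, s = m.counts.index[2], m.counts.columns[1]
    assert R.loc[g, s] == pytest.approx(
        rpkm(m.counts.loc[g, s], N[s], m.gene_lengths[g])
    )


# -- size factors & NB test --------------------------------------------------


def test_size_factors_recover_proportional_columns():
    rng = np.random.default_rng(0)
    base = rng.integers(10, 1000, size=50).astype(float)
    scale = np.array([1.0, 2.0, 0.5, 4.0])
    counts = pd.DataFrame(
        np.round(np.outer(base, scale)), columns=list("abcd")
    )
    sf = size_factors(counts)
    ratio = sf.to_numpy() / scale
    assert np.allclose(ratio, ratio[0], rtol=1e-6)


def test_identical_groups_give_no_degs():
    col = np.array([100, 200, 50, 400, 10])
    counts = pd.DataFrame({f"s{i}": col for i in range(4)}, index=gene_names(5))
    matrix = ExpressionMatrix(
        counts=counts,
        gene_lengths=pd.Series(1000, index=counts.index),
        samples=pd.DataFrame(
            {"species": ["A", "A", "B", "B"], "replicate": [1, 2, 1, 2]},
            index=counts.columns,
        ),
    )
    assert np.allclose(size_factors(counts).to_numpy(), 1.0)
    calls = nb_pairwise_test(matrix, "A", "B")
    assert not any(c.is_deg for c in calls)


def test_all_zero_gene_gets_p_one_not_deg():
    counts = pd.DataFrame(
        {"a1": [0, 5], "a2": [0, 7], "b1": [0, 6], "b2": [0, 4]},
        index=["dead", "alive"],
    )
    matrix = ExpressionMatrix(
        counts=counts,
        gene_lengths=pd.Series(500, index=counts.index),
        samples=pd.DataFrame(
            {"species": ["A", "A", "B", "B"], "replicate": [1, 2, 1, 2]},
            index=counts.columns,
        ),
    )
    call = {c.gene: c for c in nb_pairwise_test(matrix, "A", "B")}["dead"]
    assert call.p_value == 1.0 and not call.is_deg


def test_null_type_one_error_within_band():
    """Null simulation (shared mean 100, dispersion 0.1, 3+3, 2000 genes):
    the fraction of p < 0.05 stays near nominal."""
    spec = ExprSimSpec(
        n_genes=2000, species=("A", "B"), replicates_per_species=3,
        baseline_mean=100.0, dispersion=0.1, seed=42,
    )
    calls = nb_pairwise_test(simulate_expression(spec), "A", "B")
    rate = np.mean([c.p_value < 0.05 for c in calls])
    assert 0.03 <= rate <= 0.07


def test_planted_fourfold_degs_recovered():
    """Planted 4-fold genes (mean 100, dispersion 0.05, 3+3) are called
    DEG at ≥90 %."""
    genes = gene_names(1000)
    planted = genes[:100]
    spec = ExprSimSpec(
        n_genes=1000, species=("A", "B"), replicates_per_species=3,
        baseline_mean=100.0, dispersion=0.05, seed=7,
        planted_degs=[(g, "B", 4.0) for g in planted],
    )
    calls = {c.gene: c for c in nb_pairwise_test(simulate_expression(spec), "A", "B")}
    recovered = np.mean([calls[g].is_deg for g in planted])
    assert recovered >= 0.90
    for g in planted[:10]:
        assert calls[g].fold_change > 2


def test_pvalues_invariant_to_sample_order_within_groups():
    spec = ExprSimSpec(n_genes=50, species=("A", "B"), replicates_per_species=3, seed=5)
    m = simulate_expression(spec)
    base = nb_pairwise_test(m, "A", "B")
    cols = list(m.counts.columns)
    cols[0], cols[1] = cols[1], cols[0]  # swap two replicates of A
    m2 = ExpressionMatrix(
        counts=m.counts[cols],
        gene_lengths=m.gene_lengths,
        samples=m.samples.loc[cols],
    )
    swapped = nb_pairwise_test(m2, "A", "B")
    assert np.allclose(
        [c.p_value for c in base], [c.p_value for c in swapped], atol=1e-12
    )


def test_boundary_fold_change_two_is_not_deg():
    calls = [DegCall("g", 1.0, 0.001, False, fold_change=2.0)]
    # the caller applies strict thresholds; emulate its rule here
    assert not (calls[0].fold_change > 2.0 or calls[0].fold_change < 0.5)


# -- divergence --------------------------------------------------------------


def _deg(gene, fc, is_deg=True):
    lfc = np.log2(fc) if fc > 0 else float("-inf")
    return DegCall(gene, lfc, 0.001 if is_deg else 0.5, is_deg, fold_change=fc)


def test_consistent_up_in_all_three_is_divergent():
    tables = {sp: [_deg("FAS2-like", 0.25)] for sp in ("Sce", "Spa", "Smi")}
    out = call_divergent(tables, outgroup="Sba")
    assert out == {"FAS2-like": "up"}


def test_consistent_high_in_others_is_down_in_outgroup():
    tables = {sp: [_deg("g", 3.0)] for sp in ("Sce", "Spa", "Smi")}
    assert call_divergent(tables, outgroup="Sba") == {"g": "down"}


def test_deg_in_two_of_three_not_divergent():
    tables = {
        "Sce": [_deg("g", 3.0)],
        "Spa": [_deg("g", 3.0)],
        "Smi": [_deg("g", 3.0, is_deg=False)],
    }
    assert call_divergent(tables, outgroup="Sba") == {}


def test_mixed_tendency_not_divergent():
    tables = {
        "Sce": [_deg("g", 3.0)],
        "Spa": [_deg("g", 4.0)],
        "Smi": [_deg("g", 0.25)],
    }
    assert call_divergent(tables, outgroup="Sba") == {}


def test_missing_comparison_raises():
    with pytest.raises(KeyError):
        call_divergent({"Sce": []}, outgroup="Sba", species=["Sce", "Spa", "Smi"])


def test_divergent_subset_of_degs():
    rng = np.random.default_rng(2)
    tables = {}
    genes = gene_names(30)
    for sp in ("Sce", "Spa", "Smi"):
        tables[sp] = [
            _deg(g, float(rng.choice([0.2, 3.0, 1.0])), is_deg=bool(rng.random() < 0.7))
            for g in genes
        ]
    out = call_divergent(tables, outgroup="Sba")
    deg_everywhere = set.intersection(
        *[{c.gene for c in t if c.is_deg} for t in tables.values()]
    )
    assert set(out) <= deg_everywhere


# -- coexpression ------------------------------------------------------------


def _module_sim(seed=11):
    genes = gene_names(200)
    module = tuple(genes[:10])
    spec = ExprSimSpec(
        n_genes=200, replicates_per_species=5,  # 4 species × 5 = 20 samples
        baseline_mean=200.0, dispersion=0.05, seed=seed,
        planted_modules=[(module, 0.98, 0.1)],
    )
    return simulate_expression(spec), module


def test_planted_module_edges_recovered():
    """≥95 % of the 45 within-module pairs reach |r| ≥ 0.90."""
    matrix, module = _module_sim()
    edges = build_coexpression(matrix, r_min=0.90)
    got = {frozenset((e.gene_a, e.gene_b)) for e in edges}
    wanted = [frozenset(p) for p in itertools.combinations(module, 2)]
    hit = np.mean([w in got for w in wanted])
    assert hit >= 0.95


def test_duplicated_profile_gives_r_one():
    matrix, _ = _module_sim(seed=3)
    counts = matrix.counts.copy()
    counts.loc["dup1"] = counts.iloc[5] * 2  # proportional on the count scale
    counts.loc["dup2"] = counts.iloc[5] * 2
    m2 = ExpressionMatrix(
        counts=counts,
        gene_lengths=pd.concat(
            [matrix.gene_lengths, pd.Series({"dup1": 1000, "dup2": 1000})]
        ),
        samples=matrix.samples,
    )
    edges = build_coexpression(m2, r_min=0.90)
    pair = next(
        e for e in edges if {e.gene_a, e.gene_b} == {"dup1", "dup2"}
    )
    assert pair.r == pytest.approx(1.0, abs=1e-9)


def test_anticorrelated_pair_retained_by_absolute_value():
    rng = np.random.default_rng(8)
    n = 20
    z = rng.normal(0, 1, n)
    up = np.round(200 * 2 ** (2 * z)).astype(int)
    down = np.round(200 * 2 ** (-2 * z)).astype(int)
    filler = rng.poisson(200, size=(30, n))
    counts = pd.DataFrame(
        np.vstack([up, down, filler]),
        index=["up", "down"] + gene_names(30),
        columns=[f"s{i}" for i in range(n)],
    )
    matrix = ExpressionMatrix(
        counts=counts,
        gene_lengths=pd.Series(1000, index=counts.index),
        samples=pd.DataFrame(
            {"species": ["A"] * n, "replicate": range(1, n + 1)}, index=counts.columns
        ),
    )
    edges = build_coexpression(matrix, r_min=0.90)
    pair = next(e for e in edges if {e.gene_a, e.gene_b} == {"up", "down"})
    assert pair.r < -0.9


def test_raising_r_min_never_adds_edges():
    matrix, _ = _module_sim(seed=5)
    loose = {frozenset((e.gene_a, e.gene_b)) for e in build_coexpression(matrix, r_min=0.85)}
    tight = {frozenset((e.gene_a, e.gene_b)) for e in build_coexpression(matrix, r_min=0.95)}
    assert tight <= loose


def test_edges_are_deduplicated_and_unordered():
    matrix, _ = _module_sim(seed=9)
    edges = build_coexpression(matrix, r_min=0.90)
    keys = [frozenset((e.gene_a, e.gene_b)) for e in edges]
    assert len(keys) == len(set(keys))
    assert all(e.gene_a < e.gene_b for e in edges)


def test_too_few_samples_rejected():
    matrix, _ = _module_sim()
    small = ExpressionMatrix(
        counts=matrix.counts.iloc[:, :2],
        gene_lengths=matrix.gene_lengths,
        samples=matrix.samples.iloc[:2],
    )
    with pytest.raises(ValueError):
        build_coexpression(small)


# -- assembly stats ----------------------------------------------------------


@pytest.mark.parametrize(
    "lengths,n50",
    [
        ([5000], 5000),
        ([4, 3, 3, 2, 2, 2], 3),
        ([7, 7, 7, 7], 7),
        ([10, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1], 10),
    ],
)
def test_n50_values(lengths, n50):
    s = assembly_stats(lengths)
    assert s.n50 == n50
    assert s.n == len(lengths)
    assert s.mean == pytest.approx(np.mean(lengths))


def test_assembly_stats_rejects_empty_and_nonpositive():
    with pytest.raises(ValueError):
        assembly_stats([])
    with pytest.raises(ValueError):
        assembly_stats([10, 0])
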