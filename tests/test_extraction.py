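"""Evidence calling, consensus sets, and GIMME/iMAT extraction."""

import itertools

import numpy as np
import pytest

from metnet.extraction import (
    ExtractionConfig,
    HomologyHit,
    compare_models,
    consensus_gene_set,
    extract_gimme,
    extract_imat,
    map_reaction_expression,
    presence_calls,
)
from metnet.fba import solve_fba
from metnet.model import MetabolicModel
from metnet.synth import ToySpec, make_toy_model

SPECIES = ["Sce", "Spa", "Smi", "Sba"]


def _hit(gene, species, evalue, strategy="genome_guided"):
    return HomologyHit(
        query=gene, subject=f"{species}_t1", identity=95.0, align_length=500,
        evalue=evalue, bitscore=800.0, species=species, strategy=strategy,
    )


def test_evalue_threshold_is_inclusive_boundary():
    table = presence_calls([_hit("g1", "Sce", 1e-5), _hit("g2", "Sce", 1e-3)], 1e-4)
    assert table.present("g1", "Sce")
    assert not table.present("g2", "Sce")


def test_empty_hit_list_gives_empty_table():
    table = presence_calls([], 1e-4)
    assert table.genes == frozenset()


def test_planted_pattern_recovered_exactly():
    planted = {
        ("g1", "Sce"): True, ("g1", "Spa"): True,
        ("g2", "Sce"): True, ("g3", "Smi"): True,
    }
    hits = [_hit(g, s, 1e-10) for (g, s), v in planted.items() if v]
    table = presence_calls(hits, 1e-4)
    for g in ("g1", "g2", "g3"):
        for s in SPECIES:
            assert table.present(g, s) == planted.get((g, s), False)


def test_presence_calls_idempotent_under_duplication():
    hits = [_hit("g1", "Sce", 1e-9)]
    once = presence_calls(hits, 1e-4)
    thrice = presence_calls(hits * 3, 1e-4)
    assert once.data == thrice.data


def test_merged_presence_is_or_over_strategies():
    hits = [_hit("g1", "Sce", 1e-9, "de_novo")]
    table = presence_calls(hits, 1e-4)
    assert table.present("g1", "Sce")
    assert table.present("g1", "Sce", "de_novo")
    assert not table.present("g1", "Sce", "genome_guided")


def test_consensus_requires_all_species():
    hits = [_hit("g1", s, 1e-9) for s in SPECIES]
    hits += [_hit("g2", s, 1e-9) for s in SPECIES[:3]]
    table = presence_calls(hits, 1e-4)
    assert consensus_gene_set(table, SPECIES) == {"g1"}
    assert consensus_gene_set(table, SPECIES[:3]) == {"g1", "g2"}


def test_consensus_single_species_is_identity():
    hits = [_hit("g1", "Sce", 1e-9), _hit("g2", "Sce", 1e-9)]
    table = presence_calls(hits, 1e-4)
    assert consensus_gene_set(table, ["Sce"]) == {"g1", "g2"}


def test_consensus_planted_intersection_of_seven():
    core = [f"core{i}" for i in range(7)]
    extra = [f"x{i}" for i in range(5)]
    hits = [_hit(g, s, 1e-12) for g in core for s in SPECIES]
    hits += [_hit(g, s, 1e-12) for g in extra for s in SPECIES[:2]]
    table = presence_calls(hits, 1e-4)
    assert consensus_gene_set(table, SPECIES) == frozenset(core)


def test_consensus_monotone_in_species():
    hits = [_hit("g1", s, 1e-9) for s in SPECIES]
    hits += [_hit("g2", s, 1e-9) for s in SPECIES[:2]]
    table = presence_calls(hits, 1e-4)
    prev = None
    for k in range(1, len(SPECIES) + 1):
        cur = consensus_gene_set(table, SPECIES[:k])
        if prev is not None:
            assert cur <= prev
        prev = cur


# -- reaction expression mapping ---------------------------------------------


def test_reaction_expression_or_takes_max(toy_branched):
    m = toy_branched.model.copy()
    from metnet.gpr import parse_gpr

    m.get_reaction("B1a").gpr = parse_gpr("g1 or g2")
    expr = map_reaction_expression(m, {"g1": 1.0, "g2": 9.0})
    assert expr["B1a"] == 9.0


def test_reaction_expression_and_takes_min(tiny):
    from metnet.gpr import parse_gpr

    tiny.reactions[1].gpr = parse_gpr("g1 and g2")
    expr = map_reaction_expression(tiny, {"g1": 1.0, "g2": 9.0})
    assert expr["A2B"] == 1.0


def test_reaction_expression_nested(tiny):
    from metnet.gpr import parse_gpr

    tiny.reactions[1].gpr = parse_gpr("(g1 and (g2 or g3))")
    expr = map_reaction_expression(tiny, {"g1": 5.0, "g2": 2.0, "g3": 7.0})
    assert expr["A2B"] == 5.0


def test_unevidenced_reactions_map_to_none(tiny):
    expr = map_reaction_expression(tiny, {"g1": 1.0})
    assert all(v is None for v in expr.values())


# -- extraction --------------------------------------------------------------


def _expressed_toy():
    """Two-branch toy where branch 2 is unexpressed (redundant)."""
    toy = make_toy_model(ToySpec(n_branches=2, branch_yields=(0.5, 0.3)))
    gene_values = {g: (0.0 if "2" in g else 10.0) for g in toy.model.genes}
    rxn_expr = map_reaction_expression(toy.model, gene_values)
    cfg = ExtractionConfig(expression_threshold=5.0, required_fraction=0.9)
    return toy.model, rxn_expr, cfg


def test_gimme_keeps_everything_when_all_expressed(toy_branched):
    expr = {r.id: 10.0 for r in toy_branched.model.reactions}
    cfg = ExtractionConfig(expression_threshold=5.0)
    out = extract_gimme(toy_branched.model, expr, cfg)
    assert compare_models(out, toy_branched.model).empty


def test_gimme_removes_unexpressed_redundant_branch():
    """Hand LP on the 5-reaction core: the unexpressed branch carries no
    flux in the inconsistency-minimising solution, so it is removed and
    the biomass optimum is preserved."""
    model, rxn_expr, cfg = _expressed_toy()
    out = extract_gimme(model, rxn_expr, cfg)
    assert {r.id for r in out.reactions} == {
        "EX_sub(e)", "SUBt", "B1a", "B1b", "BIOMASS_toy"
    }
    assert solve_fba(out).objective_value == pytest.approx(5.0, abs=1e-8)
    # orphan metabolites and genes pruned
    assert "mid2_c" not in {m.id for m in out.metabolites}
    assert not any("2" in g for g in out.genes)


def test_gimme_functionality_floor_enforced():
    model, rxn_expr, _ = _expressed_toy()
    # leave only the unexpressed branch able to make biomass, then require
    # full functionality: the LP must keep it (no removal that breaks f)
    model = model.copy()
    model.get_reaction("B1a").upper_bound = 0.0
    cfg = ExtractionConfig(expression_threshold=5.0, required_fraction=1.0)
    out = extract_gimme(model, rxn_expr, cfg)
    assert solve_fba(out).objective_value == pytest.approx(3.0, abs=1e-8)
    assert out.has_reaction("B2a") and out.has_reaction("B2b")


def test_gimme_infeasible_floor_raises(toy_branched):
    m = toy_branched.model.copy()
    m.get_reaction("BIOMASS_toy").lower_bound = 10.0  # unreachable
    expr = {r.id: 0.0 for r in m.reactions}
    with pytest.raises(RuntimeError, match="infeasible"):
        extract_gimme(m, expr, ExtractionConfig(expression_threshold=5.0))


def _imat_score_oracle(model, high, low, eps):
    """Exhaustive oracle: best (#active high + #inactive low) over all
    activity patterns, each checked with one feasibility LP."""
    from scipy.optimize import linprog

    S, _, rxn_ids = model.stoichiometric_matrix()
    best = -1
    idx = {rid: j for j, rid in enumerate(rxn_ids)}
    for h_active in itertools.product([0, 1], repeat=len(high)):
        for l_off in itertools.product([0, 1], repeat=len(low)):
            lb = np.array([r.lower_bound for r in model.reactions])
            ub = np.array([r.upper_bound for r in model.reactions])
            ok = True
            for rid, active in zip(high, h_active):
                if active:  # demand forward flux ≥ eps (toys are irreversible)
                    j = idx[rid]
                    lb[j] = max(lb[j], eps)
                    if lb[j] > ub[j]:
                        ok = False
            for rid, off in zip(low, l_off):
                if off:
                    j = idx[rid]
                    lb[j] = ub[j] = 0.0
            if not ok:
                continue
            res = linprog(
                np.zeros(len(rxn_ids)), A_eq=S, b_eq=np.zeros(S.shape[0]),
                bounds=np.column_stack([lb, ub]), method="highs",
            )
            if res.status == 0:
                best = max(best, sum(h_active) + sum(l_off))
    return best


def test_imat_keeps_everything_when_all_high(toy_branched):
    expr = {r.id: 10.0 for r in toy_branched.model.reactions}
    cfg = ExtractionConfig(activity_epsilon=0.5)
    out = extract_imat(toy_branched.model, expr, cfg)
    assert compare_models(out, toy_branched.model).empty


def test_imat_matches_exhaustive_pattern_oracle():
    model, rxn_expr, cfg = _expressed_toy()
    evid = {r: x for r, x in rxn_expr.items() if x is not None}
    values = np.array(list(evid.values()))
    q_low = np.quantile(values, cfg.imat_low)
    q_high = np.quantile(values, cfg.imat_high)
    high = sorted(r for r, x in evid.items() if x >= q_high)
    low = sorted(r for r, x in evid.items() if x <= q_low and x < q_high)
    oracle_best = _imat_score_oracle(model, high, low, cfg.activity_epsilon)

    out = extract_imat(model, rxn_expr, cfg)
    # the MILP achieved the oracle's optimum: low reactions removed are
    # exactly those inactive in a best pattern
    removed = {r.id for r in model.reactions} - {r.id for r in out.reactions}
    assert removed <= set(low)
    assert oracle_best == len(high) + len(removed)


def test_gimme_and_imat_agree_on_toy():
    model, rxn_expr, cfg = _expressed_toy()
    g = extract_gimme(model, rxn_expr, cfg)
    i = extract_imat(model, rxn_expr, cfg)
    assert compare_models(g, i).empty


def test_extracted_model_is_submodel():
    model, rxn_expr, cfg = _expressed_toy()
    for out in (extract_gimme(model, rxn_expr, cfg), extract_imat(model, rxn_expr, cfg)):
        assert {r.id for r in out.reactions} <= {r.id for r in model.reactions}
        assert {m.id for m in out.metabolites} <= {m.id for m in model.metabolites}
        assert out.genes <= model.genes


def test_gimme_preserves_feasibility_floor():
    model, rxn_expr, cfg = _expressed_toy()
    base = solve_fba(model).objective_value
    out = extract_gimme(model, rxn_expr, cfg)
    assert solve_fba(out).objective_value >= cfg.required_fraction * base - 1e-8


# -- model diff --------------------------------------------------------------


def test_diff_of_model_with_itself_is_empty(toy_nested):
    assert compare_models(toy_nested.model, toy_nested.model).empty


def test_diff_lists_removed_reaction(toy_branched):
    m = toy_branched.model
    sub = m.with_reactions_removed({"B2a"})
    diff = compare_models(m, sub)
    assert diff.reactions_only_in_a == ["B2a"]
    assert not diff.reactions_only_in_b


def test_diff_detects_bound_change(toy_branched):
    m2 = toy_branched.model.copy()
    m2.get_reaction("SUBt").upper_bound = 7.0
    diff = compare_models(toy_branched.model, m2)
    assert diff.reactions_differing == ["SUBt"]


def test_diff_treats_equivalent_gprs_as_equal(tiny):
    from metnet.gpr import parse_gpr

    a = tiny.copy()
    b = tiny.copy()
    a.reactions[1].gpr = parse_gpr("g1 and (g2 or g3)")
    b.reactions[1].gpr = parse_gpr("(g3 or g2) and g1")
    assert compare_models(a, b).empty


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        ExtractionConfig(required_fraction=0.0)
    with pytest.raises(ValueError):
        ExtractionConfig(imat_low=0.8, imat_high=0.2)
    with pytest.raises(ValueError):
        ExtractionConfig(activity_epsilon=0.0)
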