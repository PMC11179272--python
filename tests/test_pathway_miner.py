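import numpy as np
import pytest

from pathminer.chem_core import FeatureSchema, FeatureVector
from pathminer.pathway_miner import (
    CombinationSolution,
    PutativeCompound,
    Query,
    brute_force_combinations,
    find_combinations,
    mine,
    order_and_match,
    query_delta,
    score_pathway,
)
from pathminer.reaction_kb import ReactionFeature, build_demo_kb

from conftest import brute_force_multisets

QUERY = Query(source="C00355", target="C04043", seed=42, exhaustive=True)


# ---------------------------------------------------------------------------
# query delta
# ---------------------------------------------------------------------------


def test_query_delta_composite(demo_kb):
    """L-DOPA (C9H11NO4) -> DHPAA (C8H8O3): the composite deamination +
    decarboxylation removes one carbon, one nitrogen, three hydrogens and one
    oxygen."""
    d = query_delta(QUERY, demo_kb)
    carbon = sum(v for k, v in d.counts.items() if k.startswith("C["))
    assert carbon == -1
    assert d["N"] == -1
    assert d["H"] == -3
    assert d["O"] == -1


def test_query_delta_zero_and_antisymmetry(demo_kb):
    q_same = Query(source="C00355", target="C00355")
    assert not query_delta(q_same, demo_kb)
    fwd = query_delta(QUERY, demo_kb)
    rev = query_delta(Query(source="C04043", target="C00355"), demo_kb)
    assert rev == -fwd


def test_query_delta_missing_compound(demo_kb):
    with pytest.raises(Exception, match="C99999"):
        query_delta(Query(source="C99999", target="C04043"), demo_kb)


# ---------------------------------------------------------------------------
# combination search
# ---------------------------------------------------------------------------


def test_find_combinations_demo_routes(demo_kb):
    d = query_delta(QUERY, demo_kb)
    sols = find_combinations(d, demo_kb, k_max=2, exhaustive=True)
    items = {s.items for s in sols}
    oxime = ((("RP001", "forward"), 1), (("RP002", "forward"), 1))
    conventional = ((("RP003", "forward"), 1), (("RP004", "forward"), 1))
    assert oxime in items
    assert conventional in items


def test_find_combinations_zero_delta(demo_kb, schema):
    zero = FeatureVector(schema)
    assert find_combinations(zero, demo_kb) == []
    assert find_combinations(zero, demo_kb, allow_empty=True) == [
        CombinationSolution(())
    ]


def test_find_combinations_infeasible_is_empty(demo_kb, schema):
    d = FeatureVector(schema, {"Se": 1})
    assert find_combinations(d, demo_kb, exhaustive=True) == []


def _random_library(rng, n_features, schema):
    keys = list(schema.keys)
    feats = []
    for j in range(n_features):
        nz = rng.integers(1, 4)
        counts = {}
        for k in rng.choice(len(keys), size=nz, replace=False):
            counts[keys[k]] = int(rng.integers(-2, 3)) or 1
        feats.append(ReactionFeature(f"R{j:03d}", "forward", FeatureVector(schema, counts)))
    return feats


@pytest.mark.parametrize("trial", range(12))
def test_ilp_matches_brute_force_on_random_libraries(trial):
    """Exhaustive ILP enumeration equals an independent depth-first oracle on
    random delta libraries (<= 40 deltas, k_max <= 3)."""
    schema = FeatureSchema(["a", "b", "c", "d", "e", "f"])
    rng = np.random.default_rng(1000 + trial)
    feats = _random_library(rng, int(rng.integers(5, 41)), schema)
    k_max = int(rng.integers(1, 4))
    c_max = int(rng.integers(1, 3))
    # make roughly half the trials feasible by construction
    if trial % 2 == 0:
        picks = rng.choice(len(feats), size=min(k_max, 2), replace=False)
        d = FeatureVector(schema)
        for p in picks:
            d = d + feats[p].delta
        if not d:
            d = feats[int(picks[0])].delta
    else:
        d = FeatureVector(schema, {"a": int(rng.integers(-3, 4)), "b": 1})
    if not d:
        return
    got = {
        s.items for s in find_combinations(d, feats, k_max=k_max, c_max=c_max, exhaustive=True)
    }
    expected = brute_force_multisets(d, feats, k_max, c_max)
    assert got == expected


def test_package_brute_force_agrees_with_ilp(demo_kb):
    d = query_delta(QUERY, demo_kb)
    assert find_combinations(d, demo_kb, k_max=3, exhaustive=True) == \
        brute_force_combinations(d, demo_kb, k_max=3)


def test_monotonicity_decoys_never_remove_solutions():
    kb_plain = build_demo_kb(42, include_decoys=False)
    kb_full = build_demo_kb(42, include_decoys=True)
    d = query_delta(QUERY, kb_plain)
    sols_plain = {s.items for s in find_combinations(d, kb_plain, exhaustive=True)}
    sols_full = {s.items for s in find_combinations(d, kb_full, exhaustive=True)}
    assert sols_plain <= sols_full


def test_sampled_mode_deterministic_and_subset_of_exhaustive(demo_kb):
    d = query_delta(QUERY, demo_kb)
    kwargs = dict(k_max=3, iterations=40, subset_size=5, seed=7)
    a = find_combinations(d, demo_kb, **kwargs)
    b = find_combinations(d, demo_kb, **kwargs)
    assert a == b
    full = set(find_combinations(d, demo_kb, exhaustive=True))
    assert set(a) <= full


# ---------------------------------------------------------------------------
# ordering and matching
# ---------------------------------------------------------------------------


def _solution(demo_kb, *pair_ids):
    return CombinationSolution.from_counts({(p, "forward"): 1 for p in pair_ids})


def test_oxime_order_admissible_and_matches_holdout(demo_kb):
    cands = order_and_match(_solution(demo_kb, "RP001", "RP002"), QUERY, demo_kb)
    assert len(cands) == 1  # only N-monooxygenation first survives
    cand = cands[0]
    assert [f.pair_id for f in cand.ordered_features] == ["RP001", "RP002"]
    assert cand.vectors[1] == demo_kb.vector("X-DHPAAOX")
    assert cand.intermediate_matches == ((),)  # holdout: no KB match


def test_reversed_oxime_order_pruned_by_negativity(demo_kb):
    """Applying the oxime-to-carbonyl delta to L-DOPA first would need an
    oxime group that L-DOPA does not have: some feature count goes negative."""
    f_dopa = demo_kb.vector("C00355")
    rp002 = next(f for f in demo_kb.delta_index if f.pair_id == "RP002")
    assert not (f_dopa + rp002.delta).is_nonnegative


def test_single_step_solution_has_one_ordering(demo_kb):
    q = Query(source="C00355", target="C03758")
    cands = order_and_match(_solution(demo_kb, "RP003"), q, demo_kb)
    assert len(cands) == 1
    assert cands[0].intermediate_matches == ()


def test_known_intermediate_is_matched(demo_kb):
    cands = order_and_match(_solution(demo_kb, "RP003", "RP004"), QUERY, demo_kb)
    ordered = [c for c in cands
               if [f.pair_id for f in c.ordered_features] == ["RP003", "RP004"]]
    assert ordered[0].intermediate_matches == (("C03758",),)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def test_exact_reaction_pathway_scores_one(demo_kb):
    cands = order_and_match(_solution(demo_kb, "RP003", "RP004"), QUERY, demo_kb)
    ordered = [c for c in cands
               if [f.pair_id for f in c.ordered_features] == ["RP003", "RP004"]]
    sp = score_pathway(ordered[0], demo_kb)
    assert sp.score == 1.0
    assert all(s.step_score == 1.0 for s in sp.steps)
    assert sp.n_putative == 0


def test_oxime_route_step1_exceeds_step2(demo_kb):
    cands = order_and_match(_solution(demo_kb, "RP001", "RP002"), QUERY, demo_kb)
    sp = score_pathway(cands[0], demo_kb)
    assert sp.steps[0].step_score > sp.steps[1].step_score
    assert all(0.0 <= s.step_score <= 1.0 for s in sp.steps)
    assert 0.0 <= sp.score <= 1.0
    assert isinstance(sp.steps[0].intermediate, PutativeCompound)


# ---------------------------------------------------------------------------
# mining
# ---------------------------------------------------------------------------


def test_mine_top_pathway_two_steps(demo_kb):
    paths = mine(QUERY, demo_kb)
    assert paths
    assert paths[0].n_steps == 2
    assert paths[0].score == 1.0  # the known DODC+MAO route is exact
    assert ("1.14.14.36", "1.2.3.1") in {p.ec_sequence for p in paths}


def test_mine_deterministic(demo_kb):
    q = Query(source="C00355", target="C04043", seed=11, iterations=30, subset_size=6)
    a = mine(q, demo_kb)
    b = mine(q, demo_kb)
    assert [p.to_dict() for p in a] == [p.to_dict() for p in b]


def test_mine_missing_compound_errors_before_search(demo_kb):
    with pytest.raises(KeyError, match="C99999"):
        mine(Query(source="C99999", target="C04043"), demo_kb)


def test_mine_exactness_invariant(demo_kb):
    """Every emitted pathway's vector chain runs from f(source) to f(target)
    with exact integer equality."""
    for p in mine(QUERY, demo_kb):
        v = demo_kb.vector("C00355")
        for s in p.steps:
            v = v + s.feature.delta
            assert v == s.vector_after
        assert v == demo_kb.vector("C04043")


def test_query_validation():
    with pytest.raises(ValueError):
        Query(source="a", target="b", max_steps=0)
    with pytest.raises(ValueError):
        Query(source="a", target="b", threshold=1.5)
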