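import itertools

import pytest

from kepfair import (
    EAConfig,
    KEPInstance,
    Matching,
    enumerate_cycles,
    extract_cycles,
    solve_by_enumeration,
    solve_ea,
    validate_matching,
)


def ea(cap, formulation="ea", **kw):
    return EAConfig(cycle_cap=cap, formulation=formulation, **kw)


def test_two_pair_exchange_selects_the_only_cycle(two_cycle_instance):
    m = solve_ea(two_cycle_instance, ea(2))
    assert m.objective_weight == pytest.approx(1.2)
    assert m.cycles == ((1, 2),)
    assert m.optimal


def test_triangle_is_infeasible_under_pairwise_cap(triangle_instance):
    m = solve_ea(triangle_instance, ea(2))
    assert m.objective_weight == 0.0 and m.cycles == ()
    m3 = solve_ea(triangle_instance, ea(3))
    assert m3.objective_weight == pytest.approx(1.8)
    assert m3.cycles == ((1, 2, 3),)


@pytest.mark.parametrize("formulation", ["ea", "cycle"])
@pytest.mark.parametrize("seed,cap", [(0, 2), (1, 3), (2, 4), (3, 3)])
def test_optimum_matches_enumeration_oracle(small_pool, formulation, seed, cap):
    inst = small_pool(10, seed)
    oracle_value, _ = solve_by_enumeration(enumerate_cycles(inst, cap), inst.weights)
    m = solve_ea(inst, ea(cap, formulation))
    assert m.objective_weight == pytest.approx(oracle_value, abs=1e-6)
    assert validate_matching(m, inst, cap) == []


def test_both_formulations_agree_beyond_the_oracle_ceiling(small_pool):
    inst = small_pool(18, 4)
    m_ea = solve_ea(inst, ea(3, "ea"))
    m_cycle = solve_ea(inst, ea(3, "cycle"))
    assert m_ea.objective_weight == pytest.approx(m_cycle.objective_weight, abs=1e-6)


def test_unit_weights_maximize_transplant_count(small_pool):
    inst = small_pool(10, 7)
    ones = {a: 1.0 for a in inst.arcs}
    m = solve_ea(inst, ea(3), weight_override=ones)
    oracle_count, _ = solve_by_enumeration(enumerate_cycles(inst, 3), ones)
    assert m.matched_pairs == pytest.approx(oracle_count)
    # the reported objective_weight still uses the instance weights
    assert m.objective_weight == pytest.approx(inst.total_weight(m.selected_arcs))
    assert m.objective_value == pytest.approx(oracle_count)


def test_optimum_is_monotone_in_the_cycle_cap(small_pool):
    inst = small_pool(9, 2)
    values = [solve_ea(inst, ea(cap)).objective_weight for cap in (2, 3, 4)]
    assert values == sorted(values)


def test_optimum_is_invariant_under_vertex_relabeling(small_pool):
    inst = small_pool(8, 6)
    perm = {old: new for new, old in enumerate([3, 1, 4, 8, 2, 7, 5, 6], start=1)}
    relabeled = KEPInstance.from_arcs(
        8,
        {(perm[i], perm[j]): w for (i, j), w in inst.weights.items()},
    )
    a = solve_ea(inst, ea(3))
    b = solve_ea(relabeled, ea(3))
    assert a.objective_weight == pytest.approx(b.objective_weight, abs=1e-6)


def test_weight_override_must_cover_every_arc(two_cycle_instance):
    with pytest.raises(ValueError, match="misses"):
        solve_ea(two_cycle_instance, ea(2), weight_override={(1, 2): 1.0})


def test_restricting_cycle_slots_caps_usable_cycle_leaders(small_pool):
    # with a single slot (leader vertex 1), only a cycle through vertex 1 fits
    inst = small_pool(8, 12)
    m = solve_ea(inst, ea(3, "ea", cycle_slots=1))
    assert len(m.cycles) <= 1
    if m.cycles:
        assert m.cycles[0][0] == 1


class TestExtractCycles:
    def test_empty(self):
        assert extract_cycles(frozenset()) == ()

    def test_single_and_disjoint_cycles(self):
        assert extract_cycles(frozenset({(1, 2), (2, 1)})) == ((1, 2),)
        arcs = frozenset({(1, 2), (2, 1), (3, 4), (4, 5), (5, 3)})
        assert extract_cycles(arcs) == ((1, 2), (3, 4, 5))

    @pytest.mark.parametrize(
        "arcs,vertex",
        [
            ({(1, 2)}, "1"),
            ({(1, 2), (1, 3), (2, 1), (3, 1)}, "1"),
            ({(1, 2), (3, 2), (2, 1)}, "2"),
        ],
    )
    def test_degree_violations_name_the_vertex(self, arcs, vertex):
        with pytest.raises(ValueError, match=f"vertex {vertex}"):
            extract_cycles(frozenset(arcs))


class TestValidateMatching:
    def test_feasible_matching_passes(self, two_cycle_instance):
        m = solve_ea(two_cycle_instance, ea(2))
        assert validate_matching(m, two_cycle_instance, 2) == []

    def test_overlong_cycle_is_flagged(self):
        weights = {(i, i % 4 + 1): 0.5 for i in range(1, 5)}
        inst = KEPInstance.from_arcs(4, weights)
        m = Matching(
            selected_arcs=frozenset(weights),
            cycles=((1, 2, 3, 4),),
            objective_weight=2.0,
        )
        problems = validate_matching(m, inst, cycle_cap=3)
        assert any("exceeds the cycle cap" in p for p in problems)

    def test_unknown_arc_is_flagged(self, two_cycle_instance):
        m = Matching(
            selected_arcs=frozenset({(1, 2), (2, 1), (9, 1)}),
            cycles=((1, 2),),
            objective_weight=1.2,
        )
        problems = validate_matching(m, two_cycle_instance, 2)
        assert any("does not exist" in p for p in problems)
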