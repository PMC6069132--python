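import math

import pytest

from kepfair import (
    AS_PRINTED_NODE_PENALTIES,
    REVERSED_NODE_PENALTIES,
    EAConfig,
    KEPInstance,
    PatientDonorPair,
    ScenarioSpec,
    arc_penalty,
    build_penalties,
    node_penalty,
    solve_ea,
    solve_stochastic,
    unfairness,
)

EA = EAConfig(cycle_cap=3, formulation="ea")


def test_arc_penalty_reference_values():
    assert arc_penalty(0.0, 15.0) == 0.0
    assert arc_penalty(7.5, 15.0) == pytest.approx(1.0 - math.exp(0.5))
    assert arc_penalty(15.0, 15.0) == pytest.approx(1.0 - math.e)


def test_arc_penalty_is_strictly_decreasing():
    grid = [0.0, 0.5, 1.0, 2.0, 5.0, 8.0, 13.3]
    values = [arc_penalty(u, 15.0) for u in grid]
    assert all(a > b for a, b in zip(values, values[1:]))


def test_arc_penalty_input_validation():
    with pytest.raises(ValueError):
        arc_penalty(-1.0, 15.0)
    with pytest.raises(ValueError):
        arc_penalty(1.0, 0.0)


def test_unfairness_is_received_donor_health_over_weight():
    pairs = [
        PatientDonorPair(1, "A", "O", 4, 4),
        PatientDonorPair(2, "O", "A", 2, 3),  # patient 2 receives w=W[2,4]=0.8
    ]
    inst = KEPInstance.from_pairs(pairs)
    u = unfairness(inst)
    assert u[(1, 2)] == pytest.approx(3 / 0.8)  # d_2 = 3
    assert u[(2, 1)] == pytest.approx(4 / inst.weights[(2, 1)])


def test_unfairness_rejects_nonpositive_weights():
    inst = KEPInstance.from_arcs(2, {(1, 2): 0.0, (2, 1): 0.5})
    with pytest.raises(ZeroDivisionError):
        unfairness(inst)


def test_node_penalty_follows_the_receiving_patients_group():
    pairs = [
        PatientDonorPair(1, "A", "O", 3, 4),
        PatientDonorPair(2, "AB", "O", 1, 2),
    ]
    inst = KEPInstance.from_pairs(pairs)
    printed = node_penalty(inst, AS_PRINTED_NODE_PENALTIES)
    assert printed[(2, 1)] == -1  # patient 1 is group 3
    assert printed[(1, 2)] == 0  # patient 2 is group 1
    reversed_ = node_penalty(inst, REVERSED_NODE_PENALTIES)
    assert reversed_[(1, 2)] == -2  # group 1 carries the harshest penalty
    assert reversed_[(2, 1)] == 0


def test_node_penalty_requires_all_groups():
    inst = KEPInstance.from_pairs(
        [PatientDonorPair(1, "A", "O", 1, 1), PatientDonorPair(2, "A", "O", 1, 1)]
    )
    with pytest.raises(ValueError, match="misses"):
        node_penalty(inst, {1: 0.0, 2: 0.0})


def test_scenario_spec_validation():
    with pytest.raises(ValueError):
        ScenarioSpec(p_node=0.3, p_arc=0.8)
    with pytest.raises(ValueError):
        ScenarioSpec(node_penalty_map={1: 1.0, 2: 0.0, 3: 0.0, 4: 0.0})
    with pytest.raises(ValueError):
        ScenarioSpec(arc_scale=0.0)


def test_adjusted_weight_combines_both_scenario_penalties(small_pool):
    inst = small_pool(8, 3)
    spec = ScenarioSpec()
    table = build_penalties(inst, spec)
    for a in inst.arcs:
        manual = (
            inst.weights[a]
            + spec.p_node * table.q_node[a]
            + spec.p_arc * (1.0 - math.exp(table.unfairness[a] / spec.arc_scale))
        )
        assert table.adjusted_weight[a] == pytest.approx(manual, abs=1e-12)
    # the worked-arithmetic check on the formula itself
    assert 0.8 + 0.2 * (-2.0) + 0.8 * arc_penalty(7.5, 15.0) == pytest.approx(
        -0.118977, abs=1e-6
    )


def test_zero_penalties_collapse_to_the_deterministic_model(small_pool):
    inst = small_pool(8, 5)
    spec = ScenarioSpec(node_penalty_map={g: 0.0 for g in (1, 2, 3, 4)}, arc_scale=1e9)
    sol = solve_stochastic(inst, EA, spec)
    det = solve_ea(inst, EA)
    assert sol.combined_objective == pytest.approx(det.objective_weight, abs=1e-6)
    assert sol.expected_penalty == pytest.approx(0.0, abs=1e-7)


def test_pure_arc_scenario_ignores_the_node_map(small_pool):
    inst = small_pool(7, 9)
    a = solve_stochastic(inst, EA, ScenarioSpec(p_node=0.0, p_arc=1.0))
    b = solve_stochastic(
        inst,
        EA,
        ScenarioSpec(
            p_node=0.0, p_arc=1.0, node_penalty_map=dict(AS_PRINTED_NODE_PENALTIES)
        ),
    )
    assert a.combined_objective == pytest.approx(b.combined_objective, abs=1e-9)


@pytest.mark.parametrize("seed", range(4))
def test_two_stage_milp_equals_adjusted_weight_reduction(small_pool, seed):
    """The explicit recourse MILP and the penalty-adjusted clearing
    model must reach the same optimum, with y* = x."""
    inst = small_pool(8, seed)
    spec = ScenarioSpec()
    explicit = solve_stochastic(inst, EA, spec, explicit_recourse=True)
    reduced = solve_stochastic(inst, EA, spec)
    assert explicit.combined_objective == pytest.approx(
        reduced.combined_objective, abs=1e-6
    )
    for sol in (explicit, reduced):
        x = {a: int(a in sol.matching.selected_arcs) for a in inst.arcs}
        assert sol.y_node == x
        assert sol.y_arc == x


def test_expected_penalty_never_improves_the_objective(small_pool):
    inst = small_pool(9, 8)
    det = solve_ea(inst, EA)
    sol = solve_stochastic(inst, EA, ScenarioSpec())
    assert sol.expected_penalty <= 1e-12
    assert sol.combined_objective <= det.objective_weight + 1e-9


def test_penalties_can_change_the_chosen_matching(small_pool):
    """There exist pools where the risk-priced model trades weight for
    fairness: the matchings differ and the stochastic one carries less
    total unfairness."""
    found = False
    for seed in range(60):
        inst = small_pool(6, seed)
        det = solve_ea(inst, EA)
        sol = solve_stochastic(inst, EA, ScenarioSpec())
        if not det.selected_arcs or det.selected_arcs == sol.matching.selected_arcs:
            continue
        u = sol.penalties.unfairness
        det_u = sum(u[a] for a in det.selected_arcs)
        if sol.unfairness_total < det_u - 1e-9:
            found = True
            break
    assert found, "no pool produced diverging deterministic/stochastic matchings"
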