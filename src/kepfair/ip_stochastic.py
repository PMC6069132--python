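"""Failure scenarios, penalties, and the two-stage stochastic model.

Two aggregate failure scenarios are priced into the clearing objective:

* **node failure** — the receiving patient's condition deteriorates.
  The penalty on arc ``(i, j)`` depends only on the health group of the
  patient in pair ``j``.
* **arc failure** — a pair backs out because the exchange feels unfair.
  The unfairness of arc ``(i, j)`` is ``u_ij = d_j / w_ij``: the health
  of the kidney pair ``j`` gives away divided by the quality of the
  transplant it receives.  The penalty grows exponentially,
  ``q_arc = 1 - exp(u / arc_scale)``.

The two-stage program keeps the deterministic first stage (which arcs
to transplant) and adds recourse variables ``y_ijk`` per arc and
scenario, coupled by ``x_ij <= y_ijk`` and priced at ``p_k * q_ijk``.
Because every penalty is non-positive, the optimum always has
``y* = x``, so the model reduces *exactly* to deterministic clearing
under penalty-adjusted weights ``w + p_node*q_node + p_arc*q_arc``; the
test suite verifies this reduction against the explicit two-stage MILP.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping

import numpy as np

from .ip_deterministic import EAConfig, SolverTimeoutError, _run_milp, _matching_from_x, solve_ea
from .model_types import Arc, KEPInstance, Matching

#: Penalty by patient health group, harshest for the sickest patients
#: (group 1), who are the most likely to become unable to undergo
#: surgery.  This is the default.
REVERSED_NODE_PENALTIES: Mapping[int, float] = {1: -2.0, 2: -1.0, 3: 0.0, 4: 0.0}

#: The alternative direction (penalizing the healthiest groups),
#: selectable for sensitivity analysis.
AS_PRINTED_NODE_PENALTIES: Mapping[int, float] = {1: 0.0, 2: 0.0, 3: -1.0, 4: -2.0}


@dataclass(frozen=True)
class ScenarioSpec:
    """Scenario probabilities and penalty parameters.

    ``p_node + p_arc`` must equal 1 (the scenario set is {node, arc}).
    ``arc_scale`` divides the unfairness indicator inside the
    exponential penalty; at the default 15 the penalty stays of order
    one over the realizable unfairness range (roughly 1 to 13).
    """

    p_node: float = 0.2
    p_arc: float = 0.8
    node_penalty_map: Mapping[int, float] = field(
        default_factory=lambda: dict(REVERSED_NODE_PENALTIES)
    )
    arc_scale: float = 15.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_node <= 1.0 and 0.0 <= self.p_arc <= 1.0):
            raise ValueError("scenario probabilities must lie in [0, 1]")
        if abs(self.p_node + self.p_arc - 1.0) > 1e-9:
            raise ValueError("p_node + p_arc must equal 1")
        missing = [g for g in (1, 2, 3, 4) if g not in self.node_penalty_map]
        if missing:
            raise ValueError(f"node penalty map misses health groups {missing}")
        if any(self.node_penalty_map[g] > 0 for g in (1, 2, 3, 4)):
            raise ValueError("node penalties must be non-positive")
        if self.arc_scale <= 0:
            raise ValueError("arc_scale must be positive")


@dataclass(frozen=True)
class PenaltyTable:
    """Per-arc scenario penalties and the resulting adjusted weights."""

    unfairness: Mapping[Arc, float]
    q_arc: Mapping[Arc, float]
    q_node: Mapping[Arc, float]
    adjusted_weight: Mapping[Arc, float]


def unfairness(instance: KEPInstance) -> Dict[Arc, float]:
    """Unfairness indicator ``u_ij = d_j / w_ij`` for every arc.

    ``d_j`` is the donor health of the *receiving* pair ``j`` — what the
    pair gives away — and ``w_ij`` what its patient gets back.
    """
    out: Dict[Arc, float] = {}
    for (i, j) in instance.arcs:
        w = instance.weights[(i, j)]
        if w <= 0:
            raise ZeroDivisionError(f"arc ({i}, {j}) has non-positive weight {w}")
        out[(i, j)] = instance.pair(j).donor_health / w
    return out


def arc_penalty(u: float, arc_scale: float) -> float:
    """Exponential arc-failure penalty ``1 - exp(u / arc_scale)``.

    Zero at ``u = 0`` and strictly decreasing in ``u``.
    """
    if u < 0:
        raise ValueError(f"unfairness must be non-negative, got {u}")
    if arc_scale <= 0:
        raise ValueError(f"arc_scale must be positive, got {arc_scale}")
    return 1.0 - math.exp(u / arc_scale)


def node_penalty(
    instance: KEPInstance, node_penalty_map: Mapping[int, float]
) -> Dict[Arc, float]:
    """Node-failure penalty per arc, set by the receiving patient's
    health group (the donor's health plays no role here)."""
    missing = [g for g in (1, 2, 3, 4) if g not in node_penalty_map]
    if missing:
        raise ValueError(f"node penalty map misses health groups {missing}")
    return {
        (i, j): float(node_penalty_map[instance.pair(j).patient_health])
        for (i, j) in instance.arcs
    }


def build_penalties(instance: KEPInstance, spec: ScenarioSpec) -> PenaltyTable:
    """Assemble all per-arc penalties and the adjusted weights
    ``w_ij + p_node*q_node + p_arc*q_arc``."""
    u = unfairness(instance)
    q_arc = {a: arc_penalty(u[a], spec.arc_scale) for a in instance.arcs}
    q_node = node_penalty(instance, spec.node_penalty_map)
    adjusted = {
        a: instance.weights[a] + spec.p_node * q_node[a] + spec.p_arc * q_arc[a]
        for a in instance.arcs
    }
    return PenaltyTable(u, q_arc, q_node, adjusted)


@dataclass(frozen=True)
class StochasticSolution:
    """First-stage matching plus the second-stage report."""

    matching: Matching
    first_stage_weight: float
    expected_penalty: float
    combined_objective: float
    unfairness_total: float
    penalties: PenaltyTable
    #: recourse variables per scenario; at every reported optimum
    #: ``y == x`` (slack y can only lower the objective; zero-penalty
    #: arcs are canonicalized to y = x)
    y_node: Mapping[Arc, int] = field(default_factory=dict)
    y_arc: Mapping[Arc, int] = field(default_factory=dict)


def _report(
    instance: KEPInstance, matching: Matching, spec: ScenarioSpec, table: PenaltyTable
) -> StochasticSolution:
    sel = matching.selected_arcs
    first = instance.total_weight(sel)
    penalty = sum(
        spec.p_node * table.q_node[a] + spec.p_arc * table.q_arc[a] for a in sel
    )
    y = {a: (1 if a in sel else 0) for a in instance.arcs}
    return StochasticSolution(
        matching=matching,
        first_stage_weight=first,
        expected_penalty=float(penalty),
        combined_objective=float(first + penalty),
        unfairness_total=float(sum(table.unfairness[a] for a in sel)),
        penalties=table,
        y_node=dict(y),
        y_arc=dict(y),
    )


def _solve_two_stage_milp(
    instance: KEPInstance, config: EAConfig, spec: ScenarioSpec, table: PenaltyTable
) -> StochasticSolution:
    """The explicit deterministic equivalent: first-stage clearing
    constraints plus binary ``y`` per arc and scenario with coupling
    ``x <= y``.  Built on the edge-assignment matrix, so it is meant for
    small pools (it exists to validate the adjusted-weight reduction)."""
    from .ip_deterministic import _admissible_slot_pairs

    n = instance.n_pairs
    arcs = list(instance.arcs)
    ids = [p.id for p in instance.pairs]
    admissible = _admissible_slot_pairs(instance, config.cycle_cap, ids)
    n_x = len(arcs)
    z_index = {pair: n_x + k for k, pair in enumerate(sorted(admissible))}
    y_node_off = n_x + len(z_index)
    y_arc_off = y_node_off + n_x
    n_var = y_arc_off + n_x

    c = np.zeros(n_var)
    for a_idx, a in enumerate(arcs):
        c[a_idx] = -instance.weights[a]
        c[y_node_off + a_idx] = -spec.p_node * table.q_node[a]
        c[y_arc_off + a_idx] = -spec.p_arc * table.q_arc[a]

    in_arcs: Dict[int, List[int]] = {i: [] for i in ids}
    out_arcs: Dict[int, List[int]] = {i: [] for i in ids}
    for a_idx, (i, j) in enumerate(arcs):
        out_arcs[i].append(a_idx)
        in_arcs[j].append(a_idx)

    rows: List[Dict[int, float]] = []
    lb: List[float] = []
    ub: List[float] = []

    def add(row: Dict[int, float], lo: float, hi: float) -> None:
        rows.append(row)
        lb.append(lo)
        ub.append(hi)

    slot_leaders = sorted({l for (_, l) in z_index})
    for i in ids:
        row = {a: 1.0 for a in in_arcs[i]}
        for a in out_arcs[i]:
            row[a] = row.get(a, 0.0) - 1.0
        add(row, 0.0, 0.0)
        if out_arcs[i]:
            add({a: 1.0 for a in out_arcs[i]}, 0.0, 1.0)
        row = {z_index[(i, l)]: 1.0 for l in slot_leaders if (i, l) in z_index}
        for a in in_arcs[i]:
            row[a] = row.get(a, 0.0) - 1.0
        add(row, 0.0, 0.0)
    for l in slot_leaders:
        add({z_index[(i, l)]: 1.0 for i in ids if (i, l) in z_index}, 0.0, float(config.cycle_cap))
        for i in ids:
            if i > l and (i, l) in z_index:
                add({z_index[(i, l)]: 1.0, z_index[(l, l)]: -1.0}, -np.inf, 0.0)
    for a_idx, (i, j) in enumerate(arcs):
        for l in slot_leaders:
            if l > min(i, j):
                continue
            zi, zj = (i, l) in z_index, (j, l) in z_index
            if zi and zj:
                add({z_index[(i, l)]: 1.0, a_idx: 1.0, z_index[(j, l)]: -1.0}, -np.inf, 1.0)
            elif zi:
                add({z_index[(i, l)]: 1.0, a_idx: 1.0}, -np.inf, 1.0)
    # recourse coupling: x_ij <= y_ijk for both scenarios
    for a_idx in range(n_x):
        add({a_idx: 1.0, y_node_off + a_idx: -1.0}, -np.inf, 0.0)
        add({a_idx: 1.0, y_arc_off + a_idx: -1.0}, -np.inf, 0.0)

    res, runtime = _run_milp(c, rows, lb, ub, n_var, config)
    if res.x is None:
        raise SolverTimeoutError(
            f"HiGHS returned no solution (status {res.status}: {res.message})",
            Matching.empty(),
        )
    matching = _matching_from_x(
        instance,
        arcs,
        res.x[:n_x],
        float(-res.fun),
        runtime,
        f"{config.solver_name}/ea-two-stage",
        optimal=res.status == 0,
    )
    if res.status != 0:
        raise SolverTimeoutError(
            f"time limit reached before optimality (status {res.status})", matching
        )
    # report with y canonicalized to x: negative penalties force y = x
    # at any optimum, and on zero-penalty arcs y is degenerate anyway
    return _report(instance, matching, spec, table)


def solve_stochastic(
    instance: KEPInstance,
    ea_config: EAConfig = EAConfig(),
    spec: ScenarioSpec = ScenarioSpec(),
    explicit_recourse: bool = False,
) -> StochasticSolution:
    """Solve the two-stage stochastic clearing model.

    By default the exact adjusted-weight reduction is used (the optimum
    always has ``y* = x`` since penalties are non-positive), which works
    at any pool size the deterministic solver handles.  With
    ``explicit_recourse=True`` the full deterministic-equivalent MILP
    with per-scenario ``y`` variables is built instead (small pools
    only; used to validate the reduction).
    """
    table = build_penalties(instance, spec)
    if explicit_recourse:
        return _solve_two_stage_milp(instance, ea_config, spec, table)
    matching = solve_ea(instance, ea_config, weight_override=table.adjusted_weight)
    return _report(instance, matching, spec, table)
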