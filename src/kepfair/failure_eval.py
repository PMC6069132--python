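"""Stress-testing solved matchings against failure events.

Two deterministic stress tests mirror the priced scenarios: a *node*
event in which every matched pair whose patient sits in the failing
health group becomes unable to undergo surgery, and an *arc* event in
which every selected transplant whose unfairness indicator exceeds a
threshold is refused.  All surgeries in an exchange cycle are
simultaneous, so a cycle containing any failed element is lost whole —
there is no partial execution and no re-matching afterwards.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .model_types import Arc, KEPInstance, Matching, cycle_arcs


@dataclass(frozen=True)
class FailureOutcome:
    """A matching after one failure event, with loss metrics.

    Conservation identities hold exactly: ``weight_after`` equals
    ``weight_before`` minus the broken cycles' arc weights, and
    ``broken_pairs = matched_pairs_before - matched_pairs_after``.
    """

    event_kind: str
    failed_elements: frozenset
    broken_cycles: Tuple[Tuple[int, ...], ...]
    surviving_matching: Matching
    weight_before: float
    weight_after: float
    matched_pairs_before: int
    matched_pairs_after: int

    @property
    def broken_pairs(self) -> int:
        return self.matched_pairs_before - self.matched_pairs_after

    @property
    def weight_lost(self) -> float:
        return self.weight_before - self.weight_after


def _break_cycles(
    matching: Matching,
    instance: KEPInstance,
    event_kind: str,
    failed_elements: frozenset,
    cycle_fails,
) -> FailureOutcome:
    broken = tuple(c for c in matching.cycles if cycle_fails(c))
    surviving = tuple(c for c in matching.cycles if not cycle_fails(c))
    surviving_arcs = frozenset(a for c in surviving for a in cycle_arcs(c))
    survivor = Matching(
        selected_arcs=surviving_arcs,
        cycles=surviving,
        objective_weight=instance.total_weight(surviving_arcs),
        objective_value=None,
        optimal=matching.optimal,
        solver=matching.solver,
    )
    return FailureOutcome(
        event_kind=event_kind,
        failed_elements=failed_elements,
        broken_cycles=broken,
        surviving_matching=survivor,
        weight_before=matching.objective_weight,
        weight_after=survivor.objective_weight,
        matched_pairs_before=matching.matched_pairs,
        matched_pairs_after=survivor.matched_pairs,
    )


def apply_node_failure(
    matching: Matching, instance: KEPInstance, failing_group: int = 1
) -> FailureOutcome:
    """Break every cycle containing a patient in ``failing_group``.

    All matched pairs whose *patient* health equals the failing group
    fail simultaneously (the event models the whole worst-health group
    becoming unfit for surgery).
    """
    failed = frozenset(
        v
        for c in matching.cycles
        for v in c
        if instance.pair(v).patient_health == failing_group
    )
    return _break_cycles(
        matching,
        instance,
        "node",
        failed,
        lambda c: any(v in failed for v in c),
    )


def apply_arc_failure(
    matching: Matching,
    instance: KEPInstance,
    unfairness: Mapping[Arc, float],
    threshold: float = 5.5,
) -> FailureOutcome:
    """Break every cycle containing a selected arc with unfairness
    strictly above ``threshold`` (an arc exactly at the threshold
    survives)."""
    failed = frozenset(a for a in matching.selected_arcs if unfairness[a] > threshold)
    return _break_cycles(
        matching,
        instance,
        "arc",
        failed,
        lambda c: any(a in failed for a in cycle_arcs(c)),
    )


def total_unfairness(matching: Matching, unfairness: Mapping[Arc, float]) -> float:
    """Sum of the unfairness indicator over the selected arcs."""
    return float(sum(unfairness[a] for a in matching.selected_arcs))


def threshold_sweep(
    matchings: Mapping[str, Matching],
    instance: KEPInstance,
    unfairness: Mapping[Arc, float],
    thresholds: Sequence[float],
) -> pd.DataFrame:
    """Arc-failure response curves over a grid of thresholds.

    For each (model label, threshold) the returned frame records the
    retained weight fraction ``weight_after / weight_before`` and the
    broken-pair fraction ``broken_pairs / matched_pairs_before`` (both
    defined as 1.0 and 0.0 respectively for empty matchings).
    """
    if len(thresholds) == 0:
        raise ValueError("thresholds must be non-empty")
    rows = []
    for label, matching in matchings.items():
        for t in thresholds:
            out = apply_arc_failure(matching, instance, unfairness, threshold=t)
            wb, pb = out.weight_before, out.matched_pairs_before
            rows.append(
                {
                    "model": label,
                    "threshold": float(t),
                    "weight_retention": out.weight_after / wb if wb > 0 else 1.0,
                    "broken_pair_fraction": out.broken_pairs / pb if pb > 0 else 0.0,
                }
            )
    return pd.DataFrame(rows)


def unfairness_distribution(
    solved: Iterable[Tuple[KEPInstance, Matching, Mapping[Arc, float]]],
    bins: Sequence[float] = tuple(np.arange(0.0, 15.0, 1.0)),
) -> Dict[str, object]:
    """Histogram and summary statistics of unfairness over selected arcs.

    ``solved`` yields (instance, matching, unfairness map) triples; the
    values of all selected arcs are pooled.
    """
    values: List[float] = []
    for _instance, matching, u in solved:
        values.extend(u[a] for a in matching.selected_arcs)
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return {"n": 0, "bin_edges": list(bins), "counts": [0] * (len(bins) - 1)}
    counts, edges = np.histogram(arr, bins=np.asarray(bins))
    q1, q2, q3 = np.percentile(arr, [25, 50, 75])
    return {
        "n": int(arr.size),
        "bin_edges": [float(e) for e in edges],
        "counts": [int(c) for c in counts],
        "min": float(arr.min()),
        "q1": float(q1),
        "median": float(q2),
        "q3": float(q3),
        "max": float(arr.max()),
        "mean": float(arr.mean()),
    }
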