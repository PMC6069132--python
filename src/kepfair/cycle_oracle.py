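"""Exact reference solver by explicit cycle enumeration.

This module is a correctness instrument, not a production solver: it
enumerates every simple directed cycle up to the cap and finds the
maximum-value vertex-disjoint packing by dynamic programming over
vertex subsets.  It is formulation-independent, so it serves as the
oracle for both integer-programming models on small pools (default
ceiling 15 pairs; the subset DP is exponential in pool size).
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, List, Mapping, Sequence, Tuple

from .model_types import Arc, KEPInstance, cycle_arcs

MAX_ORACLE_PAIRS = 15


@dataclass(frozen=True)
class CycleCatalog:
    """All simple directed cycles of length in [2, cycle_cap].

    Cycles are listed in canonical rotation (starting at their smallest
    vertex id) and sorted, so catalogs are stable across runs.
    """

    n_pairs: int
    cycle_cap: int
    cycles: Tuple[Tuple[int, ...], ...]

    def cycle_values(self, arc_values: Mapping[Arc, float]) -> List[float]:
        return [sum(arc_values[a] for a in cycle_arcs(c)) for c in self.cycles]


def enumerate_cycles(instance: KEPInstance, cycle_cap: int) -> CycleCatalog:
    """Enumerate simple directed cycles of length <= ``cycle_cap``.

    Each cycle appears exactly once: the search roots at every vertex
    ``l`` and only extends through vertices with larger ids, so ``l`` is
    the canonical starting (minimum) vertex.
    """
    if cycle_cap < 2:
        raise ValueError(f"cycle cap must be >= 2, got {cycle_cap}")
    succ: Dict[int, List[int]] = {p.id: [] for p in instance.pairs}
    for (i, j) in instance.arcs:
        succ[i].append(j)
    cycles: List[Tuple[int, ...]] = []
    for root in sorted(succ):
        stack: List[Tuple[int, Tuple[int, ...]]] = [(root, (root,))]
        while stack:
            v, path = stack.pop()
            for u in succ[v]:
                if u == root and len(path) >= 2:
                    cycles.append(path)
                elif u > root and u not in path and len(path) < cycle_cap:
                    stack.append((u, path + (u,)))
    return CycleCatalog(instance.n_pairs, cycle_cap, tuple(sorted(cycles)))


def solve_by_enumeration(
    catalog: CycleCatalog, arc_values: Mapping[Arc, float]
) -> Tuple[float, List[Tuple[int, ...]]]:
    """Maximum-total-value vertex-disjoint cycle packing, solved exactly.

    Dynamic program over vertex subsets: for the unresolved set ``S``,
    either its smallest vertex stays unmatched or it joins one of the
    catalog cycles fully contained in ``S``.  Returns the optimal value
    and the chosen cycles.  Guarded by :data:`MAX_ORACLE_PAIRS`.
    """
    if catalog.n_pairs > MAX_ORACLE_PAIRS:
        raise ValueError(
            f"enumeration oracle is limited to {MAX_ORACLE_PAIRS} pairs "
            f"(got {catalog.n_pairs}); use the IP solvers for larger pools"
        )
    values = catalog.cycle_values(arc_values)
    # cycles indexed by their minimum vertex, as bitmasks (bit = id - 1)
    by_min: Dict[int, List[Tuple[int, float, int]]] = {}
    for idx, (cyc, val) in enumerate(zip(catalog.cycles, values)):
        mask = 0
        for v in cyc:
            mask |= 1 << (v - 1)
        by_min.setdefault(cyc[0], []).append((mask, val, idx))

    @lru_cache(maxsize=None)
    def best(S: int) -> Tuple[float, Tuple[int, ...]]:
        if S == 0:
            return 0.0, ()
        low = (S & -S).bit_length()  # smallest unresolved vertex id
        # option 1: leave it unmatched
        val, chosen = best(S & ~(1 << (low - 1)))
        # option 2: cover it with a cycle whose minimum vertex is `low`
        for mask, cval, idx in by_min.get(low, ()):
            if mask & S == mask:
                sub_val, sub_chosen = best(S & ~mask)
                if cval + sub_val > val:
                    val, chosen = cval + sub_val, (idx,) + sub_chosen
        return val, chosen

    value, chosen_idx = best((1 << catalog.n_pairs) - 1)
    best.cache_clear()
    return value, [catalog.cycles[i] for i in chosen_idx]
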