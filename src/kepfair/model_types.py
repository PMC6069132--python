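"""Core domain types for kidney exchange pools.

A kidney exchange program (KEP) pool is a set of incompatible
patient-donor pairs.  Pair ``i`` can feed pair ``j`` (directed arc
``(i, j)``) when donor *i*'s blood group may donate to patient *j*'s
blood group; the arc weight ``w_ij`` grades how good that transplant is
expected to be, as a function of the two pairs' health statuses.  Health
statuses are coarse groups 1-4, higher meaning healthier.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Tuple

Arc = Tuple[int, int]

BLOOD_GROUPS: Tuple[str, ...] = ("A", "B", "O", "AB")

#: Standard ABO donation rules: O is the universal donor, AB the
#: universal recipient.  Rh factor and crossmatch are out of scope.
_DONATES_TO: Dict[str, FrozenSet[str]] = {
    "O": frozenset({"O", "A", "B", "AB"}),
    "A": frozenset({"A", "AB"}),
    "B": frozenset({"B", "AB"}),
    "AB": frozenset({"AB"}),
}

#: Compatibility weight by (patient health group, donor health group).
#: Row = patient group 1..4, column = donor group 1..4.  Values lie in
#: [0.3, 1.0] and are non-decreasing in both arguments: transplants
#: between healthier participants are graded closer to 1.
HEALTH_WEIGHT_TABLE: Tuple[Tuple[float, ...], ...] = (
    (0.30, 0.40, 0.50, 0.70),
    (0.40, 0.60, 0.70, 0.80),
    (0.50, 0.70, 0.85, 0.90),
    (0.70, 0.80, 0.90, 1.00),
)

HEALTH_GROUPS: Tuple[int, ...] = (1, 2, 3, 4)


def abo_compatible(donor_blood: str, patient_blood: str) -> bool:
    """Return ``True`` if a donor of the given ABO group may donate to
    the patient's group.

    Raises :class:`ValueError` for unknown blood groups.
    """
    if donor_blood not in _DONATES_TO:
        raise ValueError(f"unknown donor blood group: {donor_blood!r}")
    if patient_blood not in _DONATES_TO:
        raise ValueError(f"unknown patient blood group: {patient_blood!r}")
    return patient_blood in _DONATES_TO[donor_blood]


def weight_lookup(patient_health: int, donor_health: int) -> float:
    """Compatibility weight for a transplant from a donor in health
    group ``donor_health`` to a patient in group ``patient_health``.
    """
    if patient_health not in HEALTH_GROUPS:
        raise ValueError(f"patient health group out of range: {patient_health!r}")
    if donor_health not in HEALTH_GROUPS:
        raise ValueError(f"donor health group out of range: {donor_health!r}")
    return HEALTH_WEIGHT_TABLE[patient_health - 1][donor_health - 1]


@dataclass(frozen=True)
class PatientDonorPair:
    """One incompatible patient-donor pair (a vertex of the KEP graph).

    ``id`` is 1-based and unique within a pool.  Health statuses are in
    {1, 2, 3, 4}; higher means healthier.
    """

    id: int
    patient_blood: str
    donor_blood: str
    patient_health: int
    donor_health: int

    def __post_init__(self) -> None:
        if self.id < 1:
            raise ValueError(f"pair id must be a positive integer, got {self.id}")
        for label, blood in (("patient", self.patient_blood), ("donor", self.donor_blood)):
            if blood not in BLOOD_GROUPS:
                raise ValueError(f"unknown {label} blood group: {blood!r}")
        for label, health in (("patient", self.patient_health), ("donor", self.donor_health)):
            if health not in HEALTH_GROUPS:
                raise ValueError(f"{label} health group out of range: {health!r}")


@dataclass(frozen=True)
class KEPInstance:
    """A KEP compatibility graph: pairs, directed arcs and arc weights.

    Arcs are stored in a fixed sorted order so that serialization is
    reproducible.  For instances built from pair data the arc set and
    weights are fully determined by ABO compatibility and the health
    weight table; explicit-arc instances (arbitrary arcs/weights) are
    also supported for file-based workflows.
    """

    pairs: Tuple[PatientDonorPair, ...]
    arcs: Tuple[Arc, ...]
    weights: Mapping[Arc, float] = field(hash=False)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.pairs]
        if sorted(ids) != list(range(1, len(ids) + 1)):
            raise ValueError("pair ids must be unique and contiguous from 1")
        valid = set(ids)
        for (i, j) in self.arcs:
            if i == j:
                raise ValueError(f"self-loop arc ({i}, {j}) is not allowed")
            if i not in valid or j not in valid:
                raise ValueError(f"arc ({i}, {j}) references an unknown pair id")
            if (i, j) not in self.weights:
                raise ValueError(f"arc ({i}, {j}) has no weight")

    @classmethod
    def from_pairs(cls, pairs: Iterable[PatientDonorPair]) -> "KEPInstance":
        """Build the compatibility graph implied by the pair data: arc
        ``(i, j)`` exists iff donor *i* is ABO-compatible with patient
        *j*, weighted by the health table for (patient j, donor i).
        """
        pairs = tuple(sorted(pairs, key=lambda p: p.id))
        arcs: List[Arc] = []
        weights: Dict[Arc, float] = {}
        for pi in pairs:
            for pj in pairs:
                if pi.id == pj.id:
                    continue
                if abo_compatible(pi.donor_blood, pj.patient_blood):
                    a = (pi.id, pj.id)
                    arcs.append(a)
                    weights[a] = weight_lookup(pj.patient_health, pi.donor_health)
        return cls(pairs=pairs, arcs=tuple(sorted(arcs)), weights=weights)

    @classmethod
    def from_arcs(
        cls,
        n_pairs: int,
        weights: Mapping[Arc, float],
        pairs: Optional[Iterable[PatientDonorPair]] = None,
    ) -> "KEPInstance":
        """Build an instance from an explicit weighted arc list.

        When ``pairs`` is omitted, placeholder pairs (blood group O/O,
        health 1/1) are created; such instances support the clearing
        models but not health-dependent penalties.
        """
        if pairs is None:
            pairs = [
                PatientDonorPair(i, "O", "O", 1, 1) for i in range(1, n_pairs + 1)
            ]
        return cls(
            pairs=tuple(sorted(pairs, key=lambda p: p.id)),
            arcs=tuple(sorted(weights)),
            weights=dict(weights),
        )

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def pair(self, pair_id: int) -> PatientDonorPair:
        return self.pairs[pair_id - 1]

    def total_weight(self, arcs: Iterable[Arc]) -> float:
        return float(sum(self.weights[a] for a in arcs))


@dataclass(frozen=True)
class Matching:
    """A feasible clearing solution: vertex-disjoint directed cycles.

    ``selected_arcs`` is exactly the union of the cycles' arcs; every
    vertex has in-degree = out-degree in {0, 1}.  ``objective_weight``
    is the sum of instance weights over the selected arcs — even when a
    model was driven by an alternative arc valuation, in which case that
    driving value is reported in ``objective_value``.
    """

    selected_arcs: FrozenSet[Arc]
    cycles: Tuple[Tuple[int, ...], ...]
    objective_weight: float
    objective_value: Optional[float] = None
    optimal: bool = True
    solver: str = ""
    runtime_s: float = 0.0

    @property
    def matched_pairs(self) -> int:
        return sum(len(c) for c in self.cycles)

    @staticmethod
    def empty() -> "Matching":
        return Matching(frozenset(), (), 0.0, objective_value=0.0)


def cycle_arcs(cycle: Tuple[int, ...]) -> List[Arc]:
    """Arcs traversed by a cycle given as a vertex sequence."""
    return [(cycle[k], cycle[(k + 1) % len(cycle)]) for k in range(len(cycle))]


def canonical_rotation(cycle: Iterable[int]) -> Tuple[int, ...]:
    """Rotate a cycle's vertex sequence to start at its smallest id."""
    seq = tuple(cycle)
    k = seq.index(min(seq))
    return seq[k:] + seq[:k]
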