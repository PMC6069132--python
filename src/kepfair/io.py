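"""File round-trips: instance CSV/JSON, explicit-arc CSV, solution JSON.

All formats are plain text.  Floats in reports are written with 6
significant digits; instance weights are re-derived from pair data on
load, so pair CSV round-trips are lossless.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Union

from .ip_stochastic import StochasticSolution
from .model_types import Arc, KEPInstance, Matching, PatientDonorPair

PAIR_HEADER = "pair_id,patient_blood,donor_blood,patient_health,donor_health"
ARC_HEADER = "from_pair,to_pair,weight"

PathLike = Union[str, Path]


class ParseError(ValueError):
    def __init__(self, path: PathLike, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.line_no = line_no


def write_instance_csv(instance: KEPInstance, path: PathLike) -> None:
    lines = [PAIR_HEADER]
    for p in instance.pairs:
        lines.append(
            f"{p.id},{p.patient_blood},{p.donor_blood},{p.patient_health},{p.donor_health}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_instance_csv(path: PathLike) -> KEPInstance:
    """Read a pair CSV; arcs and weights are derived on load."""
    text = Path(path).read_text().strip().splitlines()
    if not text or text[0].strip() != PAIR_HEADER:
        raise ParseError(path, 1, f"expected header {PAIR_HEADER!r}")
    pairs = []
    for line_no, line in enumerate(text[1:], start=2):
        if not line.strip():
            continue
        fields = [f.strip() for f in line.split(",")]
        if len(fields) != 5:
            raise ParseError(path, line_no, f"expected 5 fields, got {len(fields)}")
        try:
            pairs.append(
                PatientDonorPair(
                    int(fields[0]), fields[1], fields[2], int(fields[3]), int(fields[4])
                )
            )
        except ValueError as exc:
            raise ParseError(path, line_no, str(exc)) from exc
    return KEPInstance.from_pairs(pairs)


def read_arc_csv(path: PathLike) -> KEPInstance:
    """Read an explicit weighted arc list (no pair attributes)."""
    text = Path(path).read_text().strip().splitlines()
    if not text or text[0].strip() != ARC_HEADER:
        raise ParseError(path, 1, f"expected header {ARC_HEADER!r}")
    weights: Dict[Arc, float] = {}
    n = 0
    for line_no, line in enumerate(text[1:], start=2):
        if not line.strip():
            continue
        fields = [f.strip() for f in line.split(",")]
        if len(fields) != 3:
            raise ParseError(path, line_no, f"expected 3 fields, got {len(fields)}")
        try:
            i, j, w = int(fields[0]), int(fields[1]), float(fields[2])
        except ValueError as exc:
            raise ParseError(path, line_no, str(exc)) from exc
        weights[(i, j)] = w
        n = max(n, i, j)
    return KEPInstance.from_arcs(n, weights)


def instance_to_json_dict(instance: KEPInstance) -> dict:
    return {
        "pairs": [
            {
                "pair_id": p.id,
                "patient_blood": p.patient_blood,
                "donor_blood": p.donor_blood,
                "patient_health": p.patient_health,
                "donor_health": p.donor_health,
            }
            for p in instance.pairs
        ],
        "arcs": [[i, j, instance.weights[(i, j)]] for (i, j) in instance.arcs],
    }


def write_instance_json(instance: KEPInstance, path: PathLike) -> None:
    Path(path).write_text(json.dumps(instance_to_json_dict(instance), indent=1) + "\n")


def read_instance_json(path: PathLike) -> KEPInstance:
    data = json.loads(Path(path).read_text())
    pairs = [
        PatientDonorPair(
            d["pair_id"],
            d["patient_blood"],
            d["donor_blood"],
            d["patient_health"],
            d["donor_health"],
        )
        for d in data["pairs"]
    ]
    if "arcs" in data:
        weights = {(int(i), int(j)): float(w) for i, j, w in data["arcs"]}
        return KEPInstance.from_arcs(len(pairs), weights, pairs=pairs)
    return KEPInstance.from_pairs(pairs)


def matching_to_json_dict(matching: Matching) -> dict:
    return {
        "objective_weight": round(matching.objective_weight, 9),
        "objective_value": None
        if matching.objective_value is None
        else round(matching.objective_value, 9),
        "cycles": [list(c) for c in matching.cycles],
        "selected_arcs": sorted([i, j] for (i, j) in matching.selected_arcs),
        "optimal": matching.optimal,
        "solver": matching.solver,
        "runtime_s": round(matching.runtime_s, 4),
    }


def write_solution_json(matching: Matching, path: PathLike, **extra) -> None:
    payload = matching_to_json_dict(matching)
    payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_solution_json(path: PathLike) -> Matching:
    data = json.loads(Path(path).read_text())
    cycles = tuple(tuple(c) for c in data["cycles"])
    return Matching(
        selected_arcs=frozenset((i, j) for i, j in data["selected_arcs"]),
        cycles=cycles,
        objective_weight=float(data["objective_weight"]),
        objective_value=None
        if data.get("objective_value") is None
        else float(data["objective_value"]),
        optimal=bool(data.get("optimal", True)),
        solver=str(data.get("solver", "")),
        runtime_s=float(data.get("runtime_s", 0.0)),
    )


def stochastic_solution_json_dict(sol: StochasticSolution) -> dict:
    payload = matching_to_json_dict(sol.matching)
    payload.update(
        {
            "first_stage_weight": round(sol.first_stage_weight, 9),
            "expected_penalty": round(sol.expected_penalty, 9),
            "combined_objective": round(sol.combined_objective, 9),
            "unfairness_total": round(sol.unfairness_total, 9),
        }
    )
    return payload
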