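"""Seeded synthetic pool generator.

Pools mimic a national-registry draw: blood groups A/B/O/AB with
probabilities 0.3/0.3/0.3/0.1 (South Korean distribution), patient and
donor health groups uniform on {1, 2, 3, 4}, all drawn independently.
By default each pair is conditioned to be internally ABO-incompatible
(that is what brings a pair into an exchange pool); the switch matters
for absolute pool statistics because conditioning removes every O-donor
pair — an O donor is compatible with any patient — so study-replication
runs may turn it off (see ``experiments``).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Tuple

import numpy as np

from .model_types import BLOOD_GROUPS, HEALTH_GROUPS, KEPInstance, PatientDonorPair, abo_compatible

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class GeneratorConfig:
    """Sampling design for one synthetic pool.

    ``blood_probs`` is ordered like :data:`~kepfair.model_types.BLOOD_GROUPS`
    (A, B, O, AB); ``health_probs`` covers groups 1..4.
    """

    n_pairs: int = 50
    blood_probs: Tuple[float, float, float, float] = (0.3, 0.3, 0.3, 0.1)
    health_probs: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    enforce_within_pair_incompatibility: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError(f"a pool needs at least 2 pairs, got {self.n_pairs}")
        for name, probs in (("blood_probs", self.blood_probs), ("health_probs", self.health_probs)):
            arr = np.asarray(probs, dtype=float)
            if arr.shape != (4,) or (arr < 0).any() or abs(arr.sum() - 1.0) > _PROB_TOL:
                raise ValueError(f"{name} must be 4 non-negative probabilities summing to 1")


def generate_pool(config: GeneratorConfig) -> KEPInstance:
    """Draw one pool and derive its compatibility graph.

    Identical ``config`` (including seed) reproduces the identical
    instance.  With incompatibility conditioning on, each pair's
    (patient, donor) blood groups are redrawn jointly until the donor
    cannot donate within the pair; health statuses are unaffected
    (within-pair compatibility is a blood-group property here).
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    pairs: List[PatientDonorPair] = []
    for pid in range(1, config.n_pairs + 1):
        while True:
            patient_blood = str(rng.choice(BLOOD_GROUPS, p=config.blood_probs))
            donor_blood = str(rng.choice(BLOOD_GROUPS, p=config.blood_probs))
            if not config.enforce_within_pair_incompatibility:
                break
            if not abo_compatible(donor_blood, patient_blood):
                break
        patient_health = int(rng.choice(HEALTH_GROUPS, p=config.health_probs))
        donor_health = int(rng.choice(HEALTH_GROUPS, p=config.health_probs))
        pairs.append(
            PatientDonorPair(pid, patient_blood, donor_blood, patient_health, donor_health)
        )
    return KEPInstance.from_pairs(pairs)


def generate_batch(config: GeneratorConfig, n_datasets: int) -> List[KEPInstance]:
    """Generate independent pools from deterministic sub-seeds.

    Dataset ``k`` uses ``SeedSequence(config.seed).spawn()[k]`` folded to
    an integer seed, so streams are independent and the whole batch is
    reproducible from ``config.seed`` alone.
    """
    if n_datasets < 1:
        raise ValueError(f"n_datasets must be >= 1, got {n_datasets}")
    children = np.random.SeedSequence(config.seed).spawn(n_datasets)
    out = []
    for child in children:
        sub_seed = int(child.generate_state(1, np.uint32)[0])
        out.append(generate_pool(replace(config, seed=sub_seed)))
    return out
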