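import pytest

from kepfair import GeneratorConfig, KEPInstance, PatientDonorPair, generate_pool


@pytest.fixture
def small_pool():
    """Factory for small dense random pools (no incompatibility
    conditioning, so the graphs are well connected)."""

    def make(n_pairs: int, seed: int) -> KEPInstance:
        return generate_pool(
            GeneratorConfig(
                n_pairs=n_pairs, seed=seed, enforce_within_pair_incompatibility=False
            )
        )

    return make


@pytest.fixture
def two_cycle_instance():
    """Two pairs forming a single feasible 2-cycle with weights 0.5/0.7."""
    return KEPInstance.from_arcs(2, {(1, 2): 0.5, (2, 1): 0.7})


@pytest.fixture
def triangle_instance():
    """Three pairs whose only cycle is the directed 3-cycle 1->2->3->1."""
    return KEPInstance.from_arcs(3, {(1, 2): 0.5, (2, 3): 0.6, (3, 1): 0.7})


def make_pair(pid, patient_health=4, donor_health=4, patient_blood="A", donor_blood="A"):
    return PatientDonorPair(pid, patient_blood, donor_blood, patient_health, donor_health)
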