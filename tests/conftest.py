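import numpy as np
import pytest
from hypothesis import settings

import hoofbeat as hb

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort() -> hb.Cohort:
    """3 ibex-like + 3 goat-like individuals, 5 min each, at 40 Hz."""
    cfg = hb.SimulationConfig(
        n_individuals={"ibex": 3, "goat": 3},
        sexes={"ibex": ("male", "female", "female"), "goat": ("female",) * 3},
        total_duration_s=300.0,
        seed=42,
    )
    return hb.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return hb.cohort_feature_table(small_cohort).reset_index(drop=True)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def two_behaviour_species(**overrides) -> hb.SpeciesProfile:
    """Minimal species with one static and one locomotion behaviour."""
    kwargs = dict(
        species="test",
        behaviours=(
            hb.BehaviourProfile("standing", pitch_deg=0.0, roll_deg=0.0,
                                stride_hz=0.0, amp_g=(0.005, 0.005, 0.005)),
            hb.BehaviourProfile("walking", pitch_deg=0.0, roll_deg=0.0,
                                stride_hz=1.4, amp_g=(0.18, 0.10, 0.28),
                                harmonic_ratio=0.4, is_locomotion=True,
                                weight=1.0),
        ),
        individual_sd=0.0,
    )
    kwargs.update(overrides)
    return hb.SpeciesProfile(**kwargs)
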