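import numpy as np
import pytest

from fingerrsa.synthetic import (
    BehavioralSimConfig,
    SimulationConfig,
    simulate_behavior,
    simulate_patterns,
)


@pytest.fixture(scope="session")
def small_behavior():
    """Reduced-size behavioral simulation for unit tests (full-size
    recordings are exercised in the end-to-end checks)."""
    config = BehavioralSimConfig(
        n_objects=3,
        n_kin_trials_per_object=2,
        kin_duration_s=1.5,
        n_emg_trials=2,
        emg_duration_s=0.25,
        n_landmark_trials=8,
        seed=7,
    )
    return config, simulate_behavior(config)


@pytest.fixture(scope="session")
def small_dataset():
    """One subject/region activity dataset with a known generating model."""
    config = SimulationConfig(
        n_subjects=1, n_voxels=60, seed=5, regions=("precentral",)
    )
    return config, simulate_patterns(config)[("sub01", "precentral")]
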