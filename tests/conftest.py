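"""Shared fixtures: small synthetic cohorts generated once per session."""

import numpy as np
import pytest

from vestgait.segmentation import build_cycle_dataset
from vestgait.synthetic import SyntheticCohortConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """2 subjects/group, 6 s trials, strong group effect; fast to segment."""
    config = SyntheticCohortConfig(
        n_per_group=2, trial_duration_s=6.0, group_amplitude_effect=0.5, seed=42
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_cohort):
    return build_cycle_dataset(tiny_cohort, "level_walk_short", "head")


@pytest.fixture(scope="session")
def small_cohort():
    """4 subjects/group, strong effect; for LOOCV-level tests."""
    config = SyntheticCohortConfig(
        n_per_group=4, trial_duration_s=6.0, group_amplitude_effect=0.5, seed=7
    )
    return generate_cohort(config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
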