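"""Shared fixtures: small synthetic cohorts generated at test time."""

import numpy as np
import pytest

from bdtaskfmri import pipeline
from bdtaskfmri.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Small grid, strong localized effect: fast but fully recoverable."""
    return SimConfig(
        grid_shape=(16, 16, 16),
        n_volumes=100,
        n_regions=8,
        n_events_per_condition=10,
        effect_rois=("region_01", "region_02", "region_03"),
        effect_size=3.0,
        noise_sd=1.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def strong_cohort(small_config):
    """8 remission + 8 HC subjects with a strong effect in three regions."""
    subjects, truth, atlas = simulate_cohort(small_config, {"remission": 8, "HC": 8})
    return subjects, truth, atlas


@pytest.fixture(scope="session")
def prepared_strong(small_config, strong_cohort):
    """Preprocessed cohort with first-level Go-NoGo z-maps."""
    subjects, truth, atlas = strong_cohort
    config = pipeline.RunConfig(
        sim=small_config,
        contrasts=("Go-NoGo",),
        classifiers=("random_forest",),
        n_boot=500,
        seed=7,
    )
    prepared, qc = pipeline.prepare_cohort(subjects, atlas, config, ("remission",))
    return prepared, qc, config, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
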