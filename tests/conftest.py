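"""Shared fixtures.

The default synthetic cohort (8 subjects x 2 conditions, 30 lifts) is
expensive enough (~15 s to generate, segment and featurize) that it is
built once per session and shared by the segmentation, statistics,
benchmark and trend tests.
"""

import numpy as np
import pytest

from emgrisk import SimulationConfig, generate_cohort, segment_recording
from emgrisk.spectral import cohort_features

#: One fixed seed for the session-scoped study cohort.
COHORT_SEED = 1


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=COHORT_SEED)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def default_rois(default_cohort):
    return [segment_recording(rec) for rec in default_cohort]


@pytest.fixture(scope="session")
def feature_table(default_cohort, default_rois):
    return cohort_features(default_cohort, default_rois)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
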