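"""Shared fixtures: small, fast synthetic trials with known ground truth."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from synstand import (  # noqa: E402
    TrialConfig,
    make_ground_truth_synergies,
    preprocess_trial,
    synthesize_trial,
)


@pytest.fixture(scope="session")
def truth3():
    return make_ground_truth_synergies(k_true=3, seed=7)


@pytest.fixture(scope="session")
def small_cfg():
    # 6 short cycles keep unit tests fast; full-length (15-cycle) trials are
    # exercised where the property under test needs them.
    return TrialConfig(n_cycles=6, cycle_duration_mean=1.2, seed=7)


@pytest.fixture(scope="session")
def small_trial(truth3, small_cfg):
    return synthesize_trial(truth3, small_cfg)


@pytest.fixture(scope="session")
def small_matrix(small_trial):
    return preprocess_trial(small_trial, condition="30s")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
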