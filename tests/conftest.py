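"""Shared fixtures: the packaged truth and small reusable datasets."""

import numpy as np
import pytest

from prostimm import (
    NoiseModel,
    Regimen,
    default_truth,
    generate_dataset,
    predict_all_regimens,
    simulate,
)


@pytest.fixture(scope="session")
def truth():
    return default_truth()


@pytest.fixture(scope="session")
def noise_free_ds(truth):
    """Single-replicate, zero-noise dataset: values equal the model."""
    return generate_dataset(truth, NoiseModel(sigma=0.0, replicates=1), seed=1)


@pytest.fixture(scope="session")
def noisy_ds(truth):
    """Realistic dataset: sigma = 0.15, 5 replicates per box."""
    return generate_dataset(truth, NoiseModel(sigma=0.15, replicates=5), seed=3)


@pytest.fixture(scope="session")
def sx_trajectory(truth):
    return simulate(truth, Regimen.from_label("SX"))


@pytest.fixture(scope="session")
def regimen_outcomes(truth):
    """All-16-regimen outcome table under the packaged truth."""
    return predict_all_regimens(truth)


@pytest.fixture(scope="session")
def truth_bounds(truth):
    """A moderately wide search box around the truth for fast GA tests."""
    return (truth.values * 0.5, truth.values * 1.5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
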