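"""Shared fixtures: one small phantom patient and its preprocessed slices.

Session-scoped because snake extraction and slice generation dominate the
suite's cost; tests must not mutate these objects.
"""

import numpy as np
import pytest

from metseg.phantom import PhantomConfig, generate_patient
from metseg.pipeline import preprocess_patient
from metseg.preprocessing import SnakeParams


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    return PhantomConfig(seed=11, slices_per_patient=24)


@pytest.fixture(scope="session")
def patient(small_config):
    return generate_patient(small_config, 0)


@pytest.fixture(scope="session")
def processed_pairs(patient):
    """List of (ProcessedSlice, truth mask on the 256 grid) for one patient."""
    return preprocess_patient(patient, SnakeParams())


def random_mask(rng: np.random.Generator, shape=(32, 32), p=0.2) -> np.ndarray:
    return rng.random(shape) < p
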