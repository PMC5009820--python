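"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mutclust.scoring import MutationScoreMatrix
from mutclust.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort shared across tests."""
    return generate_cohort(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def small_config():
    """A compact cohort configuration for fast end-to-end tests."""
    return SyntheticConfig(
        n_genes=120, n_patients=60, n_clusters=3, background_sparsity=0.90, seed=23
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture
def tiny_matrix():
    """Handwritten 4-gene x 4-patient matrix for exact-value tests."""
    data = pd.DataFrame(
        [
            [5.0, 5.0, 5.0, 5.0],
            [1.0, 2.0, 3.0, 4.0],
            [0.0, 0.0, 6.0, 0.0],
            [2.0, 0.0, 0.0, 8.0],
        ],
        index=["GA", "GB", "GC", "GD"],
        columns=["P1", "P2", "P3", "P4"],
    )
    return MutationScoreMatrix(data)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
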