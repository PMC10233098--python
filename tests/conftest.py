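import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from kinvae import (
    CohortConfig,
    NetworkConfig,
    VAEClassifier,
    sample_feature_table,
)


def random_trajectory(rng, n=10, dt=0.025):
    """A valid random trajectory with nonzero displacements."""
    from kinvae import Trajectory

    t = np.arange(n) * dt
    x = np.cumsum(rng.uniform(0.5, 5.0, n) * rng.choice([-1, 1], n))
    y = np.cumsum(rng.uniform(0.5, 5.0, n) * rng.choice([-1, 1], n))
    return Trajectory("P0", 0, 0, t, x, y)


@pytest.fixture(scope="session")
def small_table():
    """A small but clearly separated feature-table cohort (200 rows)."""
    return sample_feature_table(CohortConfig(n_per_group=20, n_tasks=5, seed=42))


@pytest.fixture(scope="session")
def small_config():
    return NetworkConfig(latent_dim=2, epochs=150, seed=0)


@pytest.fixture(scope="session")
def small_results(small_table, small_config):
    return VAEClassifier(small_table, small_config).fit(seed=0)
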