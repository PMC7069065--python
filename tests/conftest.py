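import numpy as np
import pytest

import msnkit
from msnkit import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def table_4x5():
    """Fixed 4-region x 5-feature raw table for brute-force Pearson checks."""
    return np.array(
        [
            [1.3, 1200.0, 3100.0, 0.12, 0.0009],
            [2.1, 900.0, 2800.0, 0.18, 0.0011],
            [1.7, 1500.0, 3600.0, 0.09, 0.0007],
            [2.6, 700.0, 2500.0, 0.21, 0.0012],
        ]
    )


@pytest.fixture(scope="session")
def matrix_5node_a():
    """Fixed symmetric zero-diagonal 5-node weight matrix."""
    m = np.zeros((5, 5))
    vals = {
        (0, 1): 0.62, (0, 2): -0.13, (0, 3): 0.35, (0, 4): 0.05,
        (1, 2): 0.48, (1, 3): -0.27, (1, 4): 0.71,
        (2, 3): 0.14, (2, 4): -0.52,
        (3, 4): 0.33,
    }
    for (i, j), v in vals.items():
        m[i, j] = m[j, i] = v
    return m


@pytest.fixture(scope="session")
def matrix_5node_b():
    m = np.zeros((5, 5))
    vals = {
        (0, 1): 0.55, (0, 2): 0.08, (0, 3): 0.29, (0, 4): -0.11,
        (1, 2): 0.41, (1, 3): -0.19, (1, 4): 0.64,
        (2, 3): 0.22, (2, 4): -0.47,
        (3, 4): 0.18,
    }
    for (i, j), v in vals.items():
        m[i, j] = m[j, i] = v
    return m


@pytest.fixture(scope="session")
def small_cohort():
    """Default-parameter cohort shared across tests (n=20, fixed seed)."""
    return generate_cohort(CohortConfig(n_subjects=20, seed=42))


def make_feature_table(values, subject_id="sub-0001", session="test"):
    """Wrap an array in a FeatureTable with generic labels."""
    values = np.asarray(values, dtype=float)
    n_regions, n_features = values.shape
    return msnkit.FeatureTable(
        subject_id=subject_id,
        session=session,
        values=values,
        region_labels=tuple(f"region_{i:03d}" for i in range(n_regions)),
        feature_labels=tuple(f"F{i}" for i in range(n_features)),
    )
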