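import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from empanet.synthetic import CohortConfig, cohort_frame, generate_cohort


@pytest.fixture(scope="session")
def study_cohort():
    """One study-sized cohort (116 subjects) shared across tests."""
    records = generate_cohort(CohortConfig(seed=20240))
    return records, cohort_frame(records)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def two_cliques(k: int = 5) -> np.ndarray:
    """Two disconnected complete graphs K_k."""
    return np.kron(np.eye(2), np.ones((k, k))) - np.eye(2 * k)


def ring_of_cliques(n_cliques: int = 8, k: int = 5) -> np.ndarray:
    adj = np.kron(np.eye(n_cliques), np.ones((k, k))) - np.eye(n_cliques * k)
    for c in range(n_cliques):
        i = c * k + k - 1
        j = ((c + 1) % n_cliques) * k
        adj[i, j] = adj[j, i] = 1
    return adj
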