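import warnings

import numpy as np
import pytest

from clustalign import (ExpressionMatrix, SimConfig, SNNGraph, normalize_counts,
                        simulate_pair)

# marker-detection warnings on tiny clusters are expected in small fixtures
warnings.filterwarnings("ignore", message="cluster .* too small")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def small_sim_config(**kw):
    """Down-scaled study conditions for fast unit tests."""
    base = dict(n_genes=300, n_cells=150, n_shared_types=3,
                n_private_per_batch=1, markers_per_type=15)
    base.update(kw)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_pair():
    return simulate_pair(small_sim_config(), seed=7)


@pytest.fixture
def random_expression(rng):
    """30 genes × 10 cells of raw counts with strictly positive colsums."""
    counts = rng.poisson(2.0, size=(30, 10)).astype(float)
    counts[0] += 1  # guard against all-zero cells
    return ExpressionMatrix(
        counts,
        [f"g{i}" for i in range(30)],
        [f"c{i}" for i in range(10)],
        batch_id="test",
    )


def lognorm(x):
    return normalize_counts(x)


def ring_graph(n, w=1.0):
    """Unit-weight ring; simple deterministic graph for modularity tests."""
    a = np.zeros((n, n))
    for i in range(n):
        a[i, (i + 1) % n] = a[(i + 1) % n, i] = w
    return SNNGraph(a, [f"n{i}" for i in range(n)])
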