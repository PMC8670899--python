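import numpy as np
import pytest

from gtvdmri import (
    GradientTable,
    NoiseSpec,
    PhantomConfig,
    SpatioAngularGraph,
    add_noise,
    make_gradient_table,
    simulate_phantom,
)


def path_graph(weights) -> SpatioAngularGraph:
    """A path graph on len(weights)+1 nodes with the given edge weights."""
    n = len(weights) + 1
    edges = [[i, i + 1] for i in range(n - 1)]
    return SpatioAngularGraph(np.zeros((n, 4), dtype=np.int64), edges, weights)


def random_graph(rng, n_nodes=None, connected=True) -> SpatioAngularGraph:
    """A random small weighted graph (spanning path plus random chords)."""
    n = int(n_nodes if n_nodes is not None else rng.integers(2, 9))
    edges = [[i - 1, i] for i in range(1, n)] if connected else []
    for _ in range(int(rng.integers(0, n))):
        a, b = sorted(rng.choice(n, size=2, replace=False).tolist())
        if [a, b] not in edges:
            edges.append([a, b])
    if not edges:
        edges = [[0, min(1, n - 1)]] if n > 1 else []
    w = rng.uniform(0.1, 1.0, size=len(edges))
    return SpatioAngularGraph(np.zeros((n, 4), dtype=np.int64), edges, w)


@pytest.fixture(scope="session")
def gtab30():
    return make_gradient_table(30, 1000.0, include_b0=True, seed=0)


@pytest.fixture(scope="session")
def small_phantom(gtab30):
    """A 9^3 crossing-fiber phantom pair (clean, noisy at sigma = 10% of s0)."""
    cfg = PhantomConfig(dims=(9, 9, 9))
    clean = simulate_phantom(cfg, gtab30)
    noisy = add_noise(clean, NoiseSpec(model="gaussian", sigma=100.0, seed=5))
    return clean, noisy


@pytest.fixture(scope="session")
def dw_table():
    """A pure diffusion-weighted table (no b=0) with 6 directions."""
    return make_gradient_table(6, 1000.0, include_b0=False, seed=1)
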