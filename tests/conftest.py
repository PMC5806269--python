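"""Shared fixtures: tiny hand-built networks and one mid-size benchmark."""

import numpy as np
import pytest

from idlp import (
    AssociationMatrix,
    IndexedNetwork,
    align_universe,
    generate_benchmark,
    normalize,
    SyntheticConfig,
)


@pytest.fixture
def two_node_net():
    return IndexedNetwork(["g1", "g2"], np.array([[0.0, 1.0], [1.0, 0.0]]))


@pytest.fixture
def path3_net():
    """3-node path g1-g2-g3."""
    W = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
    return IndexedNetwork(["g1", "g2", "g3"], W)


def random_instance(rng, n=6, m=5, density=0.6):
    """Random symmetric normalized-like operator pair + binary associations."""
    A = (rng.random((n, n)) < density).astype(float)
    W1 = np.triu(A, 1)
    W1 = W1 + W1.T
    # guarantee positive degrees by wiring a path
    for i in range(n - 1):
        W1[i, i + 1] = W1[i + 1, i] = 1.0
    B = rng.random((m, m))
    W2 = np.triu(B, 1) + np.triu(B, 1).T
    np.fill_diagonal(W2, 1.0)
    Y = (rng.random((n, m)) < 0.3).astype(float)
    if Y.sum() == 0:
        Y[0, 0] = 1.0
    gene_ids = [f"g{i}" for i in range(n)]
    pheno_ids = [f"p{j}" for j in range(m)]
    g_net = IndexedNetwork(gene_ids, W1)
    p_net = IndexedNetwork(pheno_ids, W2)
    assoc = AssociationMatrix(gene_ids, pheno_ids, Y)
    return g_net, p_net, assoc


@pytest.fixture(scope="session")
def bench_50x40():
    """The mid-size synthetic fixture used for solver convergence tests."""
    cfg = SyntheticConfig(
        n_genes=50, n_phenotypes=40, n_modules=5, seed=42
    )
    return generate_benchmark(cfg)


@pytest.fixture(scope="session")
def aligned_50x40(bench_50x40):
    return align_universe(
        bench_50x40.gene_net, bench_50x40.pheno_net, bench_50x40.train_assoc
    )


@pytest.fixture(scope="session")
def normalized_50x40(aligned_50x40):
    g, p, a = aligned_50x40
    return normalize(g), normalize(p), a
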