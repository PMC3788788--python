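import numpy as np
import pandas as pd
import pytest

from miractive import (
    EdgeList,
    ExpressionMatrix,
    NormalizedDEMatrix,
    build_influence_matrix,
    synthetic_target_network,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_expression():
    """3 genes x 2 samples, positive floats."""
    return ExpressionMatrix(
        pd.DataFrame(
            [[1.5, 2.0], [8.0, 4.0], [0.5, 1.0]],
            index=["g1", "g2", "g3"],
            columns=["s1", "s2"],
        )
    )


@pytest.fixture
def toy_edges():
    return EdgeList.from_pairs([("m1", "g1"), ("m1", "g3"), ("m2", "g2")])


@pytest.fixture
def toy_design(toy_edges):
    return build_influence_matrix(toy_edges, ["g1", "g2", "g3", "g4"], ["m1", "m2"])


@pytest.fixture(scope="session")
def small_network():
    """A 20-miRNA / ~400-gene synthetic bipartite target network."""
    edges = synthetic_target_network(20, 400, seed=11)
    return build_influence_matrix(edges, edges.genes, edges.mirnas)


def random_instance(rng, n_genes=20, n_mirnas=5, density=0.3, noise=0.1):
    """A small random -1/0 design with a sparse signal, for solver oracles."""
    X = -(rng.random((n_genes, n_mirnas)) < density).astype(float)
    # ensure no empty columns
    for j in range(n_mirnas):
        if not X[:, j].any():
            X[rng.integers(n_genes), j] = -1.0
    beta = np.zeros(n_mirnas)
    k = max(1, n_mirnas // 2)
    idx = rng.choice(n_mirnas, size=k, replace=False)
    beta[idx] = rng.uniform(1, 3, size=k) * rng.choice([-1.0, 1.0], size=k)
    y = X @ beta + noise * rng.normal(size=n_genes)
    return np.asfortranarray(X), y


def de_matrix(values, feature_prefix="m", patient_prefix="p"):
    values = np.asarray(values, dtype=float)
    return NormalizedDEMatrix(
        pd.DataFrame(
            values,
            index=[f"{feature_prefix}{i}" for i in range(values.shape[0])],
            columns=[f"{patient_prefix}{j}" for j in range(values.shape[1])],
        )
    )
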