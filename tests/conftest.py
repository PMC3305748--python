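import numpy as np
import pytest

from eqcm import (
    ClinicalTable,
    ExpressionMatrix,
    ModuleSpec,
    SyntheticConfig,
    WeightedNetwork,
    generate,
)


def make_network(weights, names=None):
    """Dense symmetric network from a weight matrix (diagonal ignored)."""
    W = np.asarray(weights, dtype=float)
    n = W.shape[0]
    names = names or [f"g{i}" for i in range(n)]
    return WeightedNetwork(names, np.maximum(W, W.T))


def random_network(rng, n):
    W = rng.random((n, n))
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)
    return WeightedNetwork([f"g{i:02d}" for i in range(n)], W)


def clique_network(blocks, n_total, weight=0.9):
    """Zero-background network with uniform-weight cliques at given index blocks."""
    W = np.zeros((n_total, n_total))
    for block in blocks:
        for i in block:
            for j in block:
                if i != j:
                    W[i, j] = weight
    return WeightedNetwork([f"g{i:02d}" for i in range(n_total)], W)


@pytest.fixture(scope="session")
def small_dataset():
    """60 genes x 80 samples, one 12-gene prognostic module (|PCC| .85, HR 3)."""
    cfg = SyntheticConfig(
        n_genes=60,
        n_samples=80,
        modules=(ModuleSpec(12, 0.85, 3.0),),
        censoring_fraction=0.3,
        rng_seed=0,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def null_dataset():
    """120 genes x 100 samples with survival independent of expression."""
    cfg = SyntheticConfig(
        n_genes=120,
        n_samples=100,
        modules=(ModuleSpec(12, 0.85, 1.0),),
        censoring_fraction=0.3,
        rng_seed=0,
    )
    return generate(cfg)


@pytest.fixture()
def tiny_expr():
    rng = np.random.default_rng(42)
    vals = rng.standard_normal((10, 6))
    return ExpressionMatrix(
        [f"g{i}" for i in range(10)], [f"s{i}" for i in range(6)], vals
    )


@pytest.fixture()
def tiny_clinical():
    rng = np.random.default_rng(7)
    times = rng.exponential(300.0, size=6)
    events = np.array([True, False, True, True, False, True])
    return ClinicalTable([f"s{i}" for i in range(6)], times, events)
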