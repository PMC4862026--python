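import numpy as np
import pytest

from mccp import (
    AnnotationCatalog,
    CatalogEntry,
    RatioMatrix,
    ReferenceSet,
    SimulationParams,
    TrainingConfig,
    simulate_dataset,
    train_multiclassifier,
)


@pytest.fixture
def toy_matrix():
    """6 proteins x 5 experiments with missing counts {5,4,3,2,1,0} per row."""
    vals = np.arange(30, dtype=float).reshape(6, 5)
    for i in range(6):
        vals[i, i:] = np.nan  # row i observes i cells, misses 5 - i
    return RatioMatrix(
        [f"P{i}" for i in range(6)], [f"e{j}" for j in range(5)], vals
    )


@pytest.fixture
def toy_catalog():
    return AnnotationCatalog(
        entries={
            "P1": CatalogEntry({"mitochondrion"}, 5),
            "P2": CatalogEntry({"mitochondrion", "cytosol"}, 5),
            "P3": CatalogEntry({"mitochondrion"}, 2),
            "P4": CatalogEntry({"nucleus"}, 5),
            "P5": CatalogEntry({"mitochondrion"}, None),
        },
        source="toy",
    )


def separable_data(n_per_class=50, n_features=8, gap=4.0, seed=0, missing=0.0):
    """Two classes separated on feature 0 by a wide margin."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, size=(2 * n_per_class, n_features))
    y = np.array([1] * n_per_class + [0] * n_per_class)
    X[:n_per_class, 0] += gap
    if missing:
        X[rng.random(X.shape) < missing] = np.nan
    return X, y


def matrix_from_arrays(X, prefix="P"):
    n, p = X.shape
    return RatioMatrix(
        [f"{prefix}{i:04d}" for i in range(n)], [f"e{j:02d}" for j in range(p)], X
    )


@pytest.fixture(scope="session")
def small_recovery():
    """A scaled-down planted-organelle pipeline run, shared across tests."""
    params = SimulationParams(
        n_proteins=400, n_experiments=20, organelle_fraction=0.1, seed=11
    )
    matrix, truth = simulate_dataset(params)
    org = truth.organelle_ids()
    ref = ReferenceSet(
        positives=org & set(matrix.protein_ids),
        negative_pool=set(matrix.protein_ids) - org,
    )
    cfg = TrainingConfig(n_trees=100, k_classifiers=3, master_seed=11)
    result = train_multiclassifier(matrix, ref, cfg)
    return params, matrix, truth, ref, cfg, result
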