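import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/_oracles.py

from heatclust import (
    DistanceMatrix,
    ExpressionMatrix,
    FixtureSpec,
    PhenotypeColumn,
    PhenotypeTable,
    agglomerate,
    make_fixture,
)


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    return ExpressionMatrix(
        rng.normal(size=(20, 10)),
        [f"G{i}" for i in range(20)],
        [f"S{j}" for j in range(10)],
    )


@pytest.fixture
def planted():
    """Well-separated 2-cluster synthetic dataset."""
    return make_fixture(FixtureSpec(n_genes=60, n_samples=24, seed=7))


@pytest.fixture
def tiny_phenotypes() -> PhenotypeTable:
    return PhenotypeTable(
        ["S1", "S2", "S3", "S4"],
        [
            PhenotypeColumn("TN", "categorical", ["Positive", "Negative", "Positive", None]),
            PhenotypeColumn("age", "continuous", [41.0, 61.0, float("nan"), 89.0]),
        ],
    )


def random_distance_matrix(rng: np.random.Generator, n: int, dim: int = 4) -> DistanceMatrix:
    """Euclidean distances between random points (so all linkages are well posed)."""
    X = rng.random((n, dim))
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    return DistanceMatrix([f"e{i}" for i in range(n)], d)


def random_tree(rng: np.random.Generator, n: int, linkage: str = "average"):
    return agglomerate(random_distance_matrix(rng, n), linkage)
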