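import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from phenoforest.annotations_io import FeatureMatrix
from phenoforest.trait_curation import BinaryTraitDataset

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def tiny_matrix() -> FeatureMatrix:
    """4 strains × 3 features, hand-constructed."""
    data = pd.DataFrame(
        [[1, 0, 1], [0, 1, 1], [1, 1, 0], [0, 0, 0]],
        index=["G1", "G2", "G3", "G4"],
        columns=["PF00001", "PF00002", "PF00003"],
    )
    return FeatureMatrix(data)


@pytest.fixture
def tiny_dataset() -> BinaryTraitDataset:
    return BinaryTraitDataset(
        "toy", frozenset({"G1", "G3"}), frozenset({"G2", "G4"})
    )


@pytest.fixture
def separable_panel():
    """500 strains, 50 features; feature PF00001 present iff positive."""
    rng = np.random.default_rng(42)
    n, m = 500, 50
    strains = [f"S{i:04d}" for i in range(n)]
    features = [f"PF{j + 1:05d}" for j in range(m)]
    y = np.arange(n) % 2 == 0
    X = (rng.random((n, m)) < 0.3).astype(np.int8)
    X[:, 0] = y.astype(np.int8)
    matrix = FeatureMatrix(pd.DataFrame(X, index=strains, columns=features))
    dataset = BinaryTraitDataset(
        "planted",
        frozenset(s for s, v in zip(strains, y) if v),
        frozenset(s for s, v in zip(strains, y) if not v),
    )
    return matrix, dataset, pd.Series(y, index=strains)
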