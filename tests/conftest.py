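import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose oracles.py

from wlmgs import ExpressionMatrix, LabeledDataset


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 samples x 2 genes with easy hand-checkable values."""
    return ExpressionMatrix(
        np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]),
        ("s1", "s2", "s3"),
        ("g1", "g2"),
    )


@pytest.fixture
def separable_1d() -> LabeledDataset:
    """Two tight 1-D clusters, one per class: no between-class k-NN edge."""
    mat = ExpressionMatrix(
        np.array([[0.0], [0.1], [10.0], [10.1]]),
        ("s1", "s2", "s3", "s4"),
        ("g1",),
    )
    return LabeledDataset(mat, ("A", "A", "B", "B"))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)


def random_dataset(rng, m=8, n=5, n_classes=2) -> LabeledDataset:
    mat = ExpressionMatrix(
        rng.normal(size=(m, n)),
        tuple(f"s{i}" for i in range(m)),
        tuple(f"g{j}" for j in range(n)),
    )
    return LabeledDataset(mat, tuple(f"c{i % n_classes}" for i in range(m)))
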