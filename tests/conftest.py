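from pathlib import Path

import numpy as np
import pytest

from ecchain import MultiLabelDataset, SyntheticSpec, generate

DATA_DIR = Path(__file__).parent / "data"

TOY_FEATURES = np.array(
    [
        [1.0, 2.5, -0.5],
        [0.0, 1.0, 3.25],
        [-2.0, 0.5, 1.5],
        [4.0, -1.25, 0.0],
    ]
)
TOY_LABELS = np.array([[1, 0], [0, 0], [1, 1], [0, 1]])


@pytest.fixture
def toy_paths():
    return DATA_DIR / "toy.arff", DATA_DIR / "toy.xml"


@pytest.fixture
def toy_dataset():
    return MultiLabelDataset(
        TOY_FEATURES.copy(), TOY_LABELS.copy(), ["f1", "f2", "f3"], ["l1", "l2"]
    )


@pytest.fixture
def copy_label_dataset():
    """Two labels where l2 is an exact copy of l1 (a separable root)."""
    return generate(
        SyntheticSpec(n=300, p=10, m=2, dependency_graph=((0, 1, 0.0),), seed=11)
    )


def separable_1d(n: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """One feature, label = 1 iff feature >= 0 (with a margin around 0)."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(-1.0, 1.0, size=n)
    x = np.where(np.abs(x) < 0.05, x + np.sign(x + 1e-9) * 0.1, x)
    return x[:, None], (x >= 0).astype(np.int64)
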