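"""Random forests of fixed-shape flat trees with majority voting.

Each tree is trained on its own bootstrap sample drawn from a per-tree
random stream derived from the forest's root stream by the tree index, so
the trained model is identical whatever order (or concurrency schedule)
the trees are built in.  Trees vote hard — a tree votes positive when its
leaf fraction is >= 0.5 — and the forest's label is the majority, with the
0.5 tie going to positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tree import (
    FlatTree,
    TreeParams,
    as_seed_sequence,
    predict_tree,
    predict_tree_batch,
    substream,
    train_tree,
)

__all__ = ["ForestModel", "train_forest", "predict_forest", "predict_forest_batch"]


@dataclass
class ForestModel:
    trees: list[FlatTree]
    forest_size: int
    params: TreeParams
    trained_feature_count: int

    def __post_init__(self) -> None:
        if len(self.trees) != self.forest_size:
            raise ValueError("len(trees) must equal forest_size")


def train_forest(
    data: np.ndarray,
    target: np.ndarray,
    forest_size: int,
    params: TreeParams,
    rng_root: int | np.random.SeedSequence,
) -> ForestModel:
    """Train ``forest_size`` trees, one independent stream per tree."""
    data = np.asarray(data, dtype=np.float64)
    if data.shape[0] < 1:
        raise ValueError("cannot train a forest on an empty dataset")
    if forest_size < 1:
        raise ValueError("forest_size must be >= 1")
    root = as_seed_sequence(rng_root)
    trees = [
        train_tree(data, target, params, substream(root, t)) for t in range(forest_size)
    ]
    return ForestModel(trees, forest_size, params, data.shape[1])


def predict_forest(forest: ForestModel, instance: np.ndarray) -> tuple[float, int]:
    """Vote fraction and hard label for one instance.

    Each tree casts a hard vote (leaf fraction >= 0.5); the returned
    fraction is the share of positive votes and the hard label is 1 when
    that share is >= 0.5.
    """
    x = np.asarray(instance, dtype=np.float64)
    if x.shape != (forest.trained_feature_count,):
        raise ValueError(
            f"instance has shape {x.shape}; forest expects "
            f"({forest.trained_feature_count},)"
        )
    votes = sum(1 for t in forest.trees if predict_tree(t, x) >= 0.5)
    fraction = votes / forest.forest_size
    return fraction, int(fraction >= 0.5)


def predict_forest_batch(
    forest: ForestModel, instances: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`predict_forest` over a matrix of instances."""
    X = np.asarray(instances, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != forest.trained_feature_count:
        raise ValueError(
            f"instances have shape {X.shape}; forest expects width "
            f"{forest.trained_feature_count}"
        )
    votes = np.zeros(X.shape[0], dtype=np.int64)
    for t in forest.trees:
        votes += predict_tree_batch(t, X) >= 0.5
    fraction = votes / forest.forest_size
    return fraction, (fraction >= 0.5).astype(np.int64)
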