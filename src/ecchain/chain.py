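"""Classifier Chains and their ensemble (ECC) over random-forest bases.

A classifier chain fixes a permutation of the label set and trains one
binary forest per position; the forest at position ``i`` sees the original
features augmented by the *true* upstream labels during training and by
the *predicted* upstream hard labels during classification, so label
interdependencies propagate down the chain.

The ensemble (ECC) trains ``k`` chains, each with its own uniformly random
label order and its own full-size bootstrap of the training instances, and
combines them by per-label voting: an instance gets label ``j`` when the
fraction of chains predicting ``j`` positive reaches the vote threshold
(default 0.5; a vote exactly at the threshold counts as positive).

A binary-relevance baseline (independent per-label forests, chains
disabled) is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forest import ForestModel, predict_forest_batch, train_forest
from .io_mulan import MultiLabelDataset
from .tree import TreeParams, as_seed_sequence, substream

__all__ = [
    "ChainModel",
    "ECCModel",
    "train_chain",
    "predict_chain",
    "predict_chain_batch",
    "train_ecc",
    "predict_ecc",
    "train_binary_relevance",
    "predict_binary_relevance",
]

DEFAULT_ENSEMBLE_SIZE = 20
DEFAULT_FOREST_SIZE = 64
DEFAULT_THRESHOLD = 0.5


@dataclass
class ChainModel:
    """One classifier chain: a label order plus one forest per position."""

    order: np.ndarray  # permutation of {0..m-1}
    forests: list[ForestModel]
    p: int
    m: int

    def __post_init__(self) -> None:
        order = np.asarray(self.order)
        if sorted(order.tolist()) != list(range(self.m)):
            raise ValueError("order must be a permutation of {0..m-1}")
        for i, f in enumerate(self.forests):
            if f.trained_feature_count != self.p + i:
                raise ValueError(
                    f"forest {i} trained on {f.trained_feature_count} columns, "
                    f"expected {self.p + i}"
                )


@dataclass
class ECCModel:
    """An ensemble of classifier chains with a per-label vote threshold."""

    chains: list[ChainModel]
    threshold: float
    p: int
    m: int
    label_names: list[str] = field(default_factory=list)
    feature_names: list[str] = field(default_factory=list)
    params: TreeParams = field(default_factory=TreeParams)
    forest_size: int = DEFAULT_FOREST_SIZE

    @property
    def k(self) -> int:
        return len(self.chains)

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError("an ensemble needs at least one chain")
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError("threshold must lie in (0, 1]")
        for c in self.chains:
            if c.p != self.p or c.m != self.m:
                raise ValueError("all chains must share p and m")


def train_chain(
    dataset: MultiLabelDataset,
    order: np.ndarray,
    forest_size: int,
    params: TreeParams,
    rng_stream: int | np.random.SeedSequence,
) -> ChainModel:
    """Train one chain in the given label order.

    The forest at position ``i`` is trained on ``[features | true labels at
    order[0..i-1]]`` with target ``labels[:, order[i]]``; its random stream
    is derived from ``rng_stream`` by the position index.
    """
    order = np.asarray(order, dtype=np.int64)
    m = dataset.m
    if sorted(order.tolist()) != list(range(m)):
        raise ValueError(f"order {order.tolist()} is not a permutation of 0..{m - 1}")
    root = as_seed_sequence(rng_stream)
    augmented = np.asarray(dataset.features, dtype=np.float64)
    forests: list[ForestModel] = []
    for i, lab in enumerate(order):
        target = dataset.labels[:, lab]
        forests.append(
            train_forest(augmented, target, forest_size, params, substream(root, i))
        )
        if i + 1 < m:
            augmented = np.column_stack(
                [augmented, dataset.labels[:, lab].astype(np.float64)]
            )
    return ChainModel(order, forests, dataset.p, m)


def predict_chain_batch(chain: ChainModel, instances: np.ndarray) -> np.ndarray:
    """Predict all labels for a matrix of instances, chain order inside.

    Hard labels predicted at earlier positions are appended to the working
    feature block before later positions are evaluated; the returned matrix
    is rearranged back to canonical label order.
    """
    X = np.asarray(instances, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != chain.p:
        raise ValueError(f"instances have shape {X.shape}; chain expects width {chain.p}")
    out = np.empty((X.shape[0], chain.m), dtype=np.int64)
    working = X
    for i, lab in enumerate(chain.order):
        _, hard = predict_forest_batch(chain.forests[i], working)
        out[:, lab] = hard
        if i + 1 < chain.m:
            working = np.column_stack([working, hard.astype(np.float64)])
    return out


def predict_chain(chain: ChainModel, instance: np.ndarray) -> np.ndarray:
    """Binary label vector (canonical order) for a single instance."""
    x = np.asarray(instance, dtype=np.float64)
    if x.shape != (chain.p,):
        raise ValueError(f"instance has shape {x.shape}; chain expects ({chain.p},)")
    return predict_chain_batch(chain, x[None, :])[0]


def _bootstrap(dataset: MultiLabelDataset, rows: np.ndarray) -> MultiLabelDataset:
    return MultiLabelDataset(
        dataset.features[rows],
        dataset.labels[rows],
        dataset.feature_names,
        dataset.label_names,
    )


def train_ecc(
    dataset: MultiLabelDataset,
    ensemble_size: int = DEFAULT_ENSEMBLE_SIZE,
    forest_size: int = DEFAULT_FOREST_SIZE,
    params: TreeParams | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    seed: int = 0,
    bootstrap_chains: bool = True,
) -> ECCModel:
    """Train an Ensemble of Classifier Chains.

    Each chain ``c`` draws, from a stream derived from ``(seed, c)``, a
    uniform random label order and a full-size bootstrap resample of the
    instances, then trains on that resample.  ``bootstrap_chains=False``
    trains every chain on the full dataset (useful to study the ensemble
    without resampling variation).
    """
    if ensemble_size < 1:
        raise ValueError("ensemble_size must be >= 1")
    dataset.validate()
    if params is None:
        params = TreeParams()
    n, m = dataset.n, dataset.m
    chains: list[ChainModel] = []
    for c in range(ensemble_size):
        chain_stream = substream(seed, c)
        rng = np.random.default_rng(chain_stream)
        order = rng.permutation(m)
        train_data = dataset
        if bootstrap_chains:
            rows = rng.integers(0, n, size=n)
            train_data = _bootstrap(dataset, rows)
        chains.append(train_chain(train_data, order, forest_size, params, chain_stream))
    return ECCModel(
        chains=chains,
        threshold=threshold,
        p=dataset.p,
        m=m,
        label_names=list(dataset.label_names),
        feature_names=list(dataset.feature_names),
        params=params,
        forest_size=forest_size,
    )


def predict_ecc(
    model: ECCModel, instances: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vote fractions and thresholded labels for a matrix of instances.

    ``vote_matrix[i, j]`` is the fraction of chains predicting label ``j``
    positive for instance ``i``; ``label_matrix = vote_matrix >= threshold``
    elementwise.  Rows are processed independently and nothing is mutated.
    """
    X = np.asarray(instances, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.p:
        raise ValueError(f"instances have shape {X.shape}; model expects width {model.p}")
    counts = np.zeros((X.shape[0], model.m), dtype=np.int64)
    for chain in model.chains:
        counts += predict_chain_batch(chain, X)
    votes = counts / model.k
    return votes, (votes >= model.threshold).astype(np.int64)


# ---------------------------------------------------------------------------
# binary-relevance baseline (chains disabled)

def train_binary_relevance(
    dataset: MultiLabelDataset,
    forest_size: int,
    params: TreeParams,
    seed: int = 0,
) -> list[ForestModel]:
    """One independent forest per label on the raw features."""
    dataset.validate()
    return [
        train_forest(
            dataset.features,
            dataset.labels[:, j],
            forest_size,
            params,
            substream(seed, j),
        )
        for j in range(dataset.m)
    ]


def predict_binary_relevance(
    forests: list[ForestModel], instances: np.ndarray
) -> np.ndarray:
    """Hard label matrix from independent per-label forests."""
    X = np.asarray(instances, dtype=np.float64)
    cols = [predict_forest_batch(f, X)[1] for f in forests]
    return np.column_stack(cols)
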