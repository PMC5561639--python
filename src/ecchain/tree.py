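"""Fixed-shape binary decision trees in a flat heap-ordered array.

Every tree has exactly ``2**(depth+1) - 1`` node slots regardless of the
training data, so a node's children live at the arithmetically computed
positions ``2*i + 1`` and ``2*i + 2`` and no pointer structure is needed.
Training never copies the data matrix: the only per-node state is a slice
of a shared instance-index array, partitioned in place at each split.

Splits are greedy CART-style: Gini impurity, thresholds at midpoints
between consecutive distinct feature values, ``mtry`` candidate features
redrawn per node, ties broken by lowest feature index then lowest
threshold so that (data, params, seed) fully determines the tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "LEAF",
    "TreeParams",
    "FlatTree",
    "child_index",
    "heap_depth",
    "gini_impurity",
    "best_split",
    "train_tree",
    "predict_tree",
    "predict_tree_batch",
    "as_seed_sequence",
    "substream",
]

#: Sentinel stored in ``split_feature`` marking a leaf slot.
LEAF = -1


# ---------------------------------------------------------------------------
# reproducible stream derivation

def as_seed_sequence(stream: int | np.random.SeedSequence) -> np.random.SeedSequence:
    """Coerce an integer seed or SeedSequence into a SeedSequence."""
    if isinstance(stream, np.random.SeedSequence):
        return stream
    return np.random.SeedSequence(int(stream))


def substream(stream: int | np.random.SeedSequence, *key: int) -> np.random.SeedSequence:
    """Derive a child stream by extending the spawn key.

    The (seed, chain, position, tree) counter hierarchy makes every task's
    randomness a pure function of its coordinates, so models are identical
    under any build schedule.
    """
    ss = as_seed_sequence(stream)
    return np.random.SeedSequence(
        entropy=ss.entropy, spawn_key=tuple(ss.spawn_key) + tuple(int(k) for k in key)
    )


# ---------------------------------------------------------------------------
# types

@dataclass(frozen=True)
class TreeParams:
    """Shape and split-search parameters shared by every tree in a model.

    Parameters
    ----------
    depth : int
        Fixed maximal depth (root at depth 0); the node array always has
        ``2**(depth+1) - 1`` slots.  Default 10 (2047 slots).
    mtry : int or None
        Candidate features drawn (without replacement) at each node.
        ``None`` resolves to ``floor(sqrt(p))``, minimum 1, at train time.
    min_node_size : int
        Nodes with fewer training instances are frozen as leaves.
    """

    depth: int = 10
    mtry: Optional[int] = None
    min_node_size: int = 1

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")

    def resolve_mtry(self, n_features: int) -> int:
        if self.mtry is not None:
            return min(self.mtry, n_features)
        return max(1, int(np.sqrt(n_features)))

    @property
    def n_nodes(self) -> int:
        return 2 ** (self.depth + 1) - 1


@dataclass
class FlatTree:
    """A complete fixed-depth tree as three parallel node arrays.

    ``split_feature[i] == LEAF`` marks leaf slots; ``pos_fraction[i]`` is
    the fraction of positive training instances that reached node ``i``
    (slots never reached inherit their parent's value).
    """

    split_feature: np.ndarray  # int64, length 2**(depth+1)-1
    split_threshold: np.ndarray  # float64
    pos_fraction: np.ndarray  # float64 in [0, 1]
    depth: int
    n_features: int

    @property
    def n_nodes(self) -> int:
        return self.split_feature.shape[0]


# ---------------------------------------------------------------------------
# node arithmetic and impurity

def child_index(node_index: int, side: str) -> int:
    """Heap-layout child address: left = 2i+1, right = 2i+2."""
    if node_index < 0:
        raise ValueError("node_index must be nonnegative")
    if side == "left":
        return 2 * node_index + 1
    if side == "right":
        return 2 * node_index + 2
    raise ValueError(f"side must be 'left' or 'right', got {side!r}")


def heap_depth(node_index: int) -> int:
    """Depth of a node in the implicit heap (root at depth 0)."""
    return (node_index + 1).bit_length() - 1


def gini_impurity(n_pos: int, n_neg: int) -> float:
    """Gini impurity ``1 - q**2 - (1-q)**2`` of a binary node."""
    n = n_pos + n_neg
    if n < 1:
        raise ValueError("gini_impurity of an empty node is undefined")
    q = n_pos / n
    return 1.0 - q * q - (1.0 - q) * (1.0 - q)


# ---------------------------------------------------------------------------
# split search

def best_split(
    instance_indices: np.ndarray,
    candidate_features: Iterable[int],
    data: np.ndarray,
    target: np.ndarray,
) -> Optional[tuple[int, float, float]]:
    """Greedy exhaustive split search over the candidate features.

    Considers every midpoint between consecutive distinct sorted values of
    each candidate feature (restricted to ``instance_indices``) and returns
    ``(feature, threshold, impurity_decrease)`` maximizing the weighted
    Gini decrease, or ``None`` when no split decreases impurity.  Ties go
    to the lowest feature index, then the lowest threshold.
    """
    idx = np.asarray(instance_indices)
    if idx.size == 0:
        raise ValueError("best_split on an empty index slice")
    y = target[idx]
    n = idx.size
    n_pos = int(y.sum())
    parent = gini_impurity(n_pos, n - n_pos)

    best: Optional[tuple[float, int, float]] = None
    for f in sorted(int(f) for f in set(candidate_features)):
        v = data[idx, f]
        order = np.argsort(v, kind="stable")
        sv = v[order]
        sy = y[order]
        cuts = np.nonzero(sv[:-1] < sv[1:])[0]
        if cuts.size == 0:
            continue
        cum_pos = np.cumsum(sy)
        n_left = cuts + 1
        pos_left = cum_pos[cuts].astype(np.float64)
        n_right = n - n_left
        pos_right = n_pos - pos_left
        ql = pos_left / n_left
        qr = pos_right / n_right
        gini_l = 1.0 - ql * ql - (1.0 - ql) * (1.0 - ql)
        gini_r = 1.0 - qr * qr - (1.0 - qr) * (1.0 - qr)
        decrease = parent - (n_left / n) * gini_l - (n_right / n) * gini_r
        j = int(np.argmax(decrease))  # first max -> lowest threshold
        if decrease[j] > 0.0 and (best is None or decrease[j] > best[0]):
            threshold = (sv[cuts[j]] + sv[cuts[j] + 1]) / 2.0
            best = (float(decrease[j]), f, float(threshold))
    if best is None:
        return None
    return best[1], best[2], best[0]


# ---------------------------------------------------------------------------
# training and prediction

def train_tree(
    data: np.ndarray,
    target: np.ndarray,
    params: TreeParams,
    rng_stream: int | np.random.SeedSequence | np.random.Generator,
) -> FlatTree:
    """Train one fixed-shape tree on a bootstrap sample.

    The root working set is a bootstrap (n draws with replacement) realized
    as a reordered index array; each split partitions its index slice in
    place into contiguous left/right segments — the data matrix itself is
    never copied or reordered.
    """
    data = np.asarray(data, dtype=np.float64)
    target = np.asarray(target)
    n, p = data.shape
    if n < 1:
        raise ValueError("cannot train a tree on an empty dataset")
    if target.shape[0] != n:
        raise ValueError("data and target row counts differ")

    if isinstance(rng_stream, np.random.Generator):
        rng = rng_stream
    else:
        rng = np.random.default_rng(as_seed_sequence(rng_stream))

    depth = params.depth
    n_nodes = params.n_nodes
    split_feature = np.full(n_nodes, LEAF, dtype=np.int64)
    split_threshold = np.zeros(n_nodes, dtype=np.float64)
    pos_fraction = np.full(n_nodes, np.nan, dtype=np.float64)
    mtry = params.resolve_mtry(p)

    idx = rng.integers(0, n, size=n)  # bootstrap as an index permutation
    stack: list[tuple[int, int, int]] = [(0, 0, n)]
    while stack:
        node, lo, hi = stack.pop()
        seg = idx[lo:hi]
        seg_y = target[seg]
        pos_fraction[node] = float(seg_y.mean())
        if heap_depth(node) == depth or (hi - lo) < params.min_node_size:
            continue
        candidates = rng.choice(p, size=mtry, replace=False)
        found = best_split(seg, candidates, data, target)
        if found is None:
            continue
        f, thr, _ = found
        mask = data[seg, f] <= thr
        idx[lo:hi] = np.concatenate([seg[mask], seg[~mask]])
        split_feature[node] = f
        split_threshold[node] = thr
        mid = lo + int(mask.sum())
        # push right first so the left child is processed first (preorder)
        stack.append((child_index(node, "right"), mid, hi))
        stack.append((child_index(node, "left"), lo, mid))

    # slots never reached by a training instance inherit the parent's fraction
    for i in range(1, n_nodes):
        if np.isnan(pos_fraction[i]):
            pos_fraction[i] = pos_fraction[(i - 1) // 2]

    return FlatTree(split_feature, split_threshold, pos_fraction, depth, p)


def predict_tree(tree: FlatTree, instance: np.ndarray) -> float:
    """Descend from the root and return the leaf's positive fraction.

    Takes the left child when ``instance[feature] <= threshold``; visits at
    most ``depth + 1`` nodes and mutates nothing.
    """
    x = np.asarray(instance, dtype=np.float64)
    if x.shape != (tree.n_features,):
        raise ValueError(
            f"instance has {x.shape} values; tree expects {tree.n_features}"
        )
    i = 0
    while tree.split_feature[i] != LEAF:
        f = tree.split_feature[i]
        i = child_index(i, "left" if x[f] <= tree.split_threshold[i] else "right")
    return float(tree.pos_fraction[i])


def predict_tree_batch(tree: FlatTree, instances: np.ndarray) -> np.ndarray:
    """Vectorized descent for a matrix of instances; one fraction per row."""
    X = np.asarray(instances, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != tree.n_features:
        raise ValueError(
            f"instances have shape {X.shape}; tree expects width {tree.n_features}"
        )
    nodes = np.zeros(X.shape[0], dtype=np.int64)
    for _ in range(tree.depth):
        feats = tree.split_feature[nodes]
        active = feats != LEAF
        if not active.any():
            break
        sel = np.nonzero(active)[0]
        x = X[sel, feats[sel]]
        go_right = x > tree.split_threshold[nodes[sel]]
        nodes[sel] = 2 * nodes[sel] + 1 + go_right
    return tree.pos_fraction[nodes]
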