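"""Synthetic multi-label datasets with controllable label dependencies.

The generator emulates the core structure that makes classifier chains
worthwhile: some labels ("roots") are determined by the features, while
others are noisy copies of an upstream label — the way resistance against
one drug can be strongly indicative of resistance against a related one.

Root labels are linear-threshold functions of a block of signal features
plus optional Gaussian noise; each dependent label copies its single
source label and flips every bit independently with the edge's flip
probability.  Everything is a pure function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_mulan import MultiLabelDataset, ValidationError

__all__ = ["SyntheticSpec", "generate"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic multi-label dataset.

    ``dependency_graph`` is a list of ``(source, target, flip_prob)`` edges
    over label indices; it must be acyclic and no label may have more than
    one source.  Labels without an incoming edge are roots driven by
    ``signal_features_per_root_label`` standard-normal features summed and
    thresholded at zero (plus noise with standard deviation ``noise_sd``).
    """

    n: int
    p: int
    m: int
    dependency_graph: tuple[tuple[int, int, float], ...] = field(default_factory=tuple)
    signal_features_per_root_label: int = 3
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.p < 1 or self.m < 1:
            raise ValueError("n, p, m must all be >= 1")
        if self.signal_features_per_root_label < 1:
            raise ValueError("signal_features_per_root_label must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        object.__setattr__(self, "dependency_graph", tuple(
            (int(s), int(t), float(f)) for s, t, f in self.dependency_graph
        ))
        for s, t, f in self.dependency_graph:
            if not (0 <= s < self.m and 0 <= t < self.m):
                raise ValueError(f"edge ({s},{t}) references a label outside 0..{self.m - 1}")
            if not (0.0 <= f < 0.5):
                raise ValueError(f"flip probability {f} outside [0, 0.5)")


def _topological_order(spec: SyntheticSpec) -> list[int]:
    """Kahn's algorithm over the label dependency DAG."""
    targets = [t for _, t, _ in spec.dependency_graph]
    if len(set(targets)) != len(targets):
        raise ValidationError("a label may have at most one source edge")
    in_deg = {j: 0 for j in range(spec.m)}
    out_edges: dict[int, list[int]] = {j: [] for j in range(spec.m)}
    for s, t, _ in spec.dependency_graph:
        in_deg[t] += 1
        out_edges[s].append(t)
    ready = sorted(j for j, d in in_deg.items() if d == 0)
    order: list[int] = []
    while ready:
        j = ready.pop(0)
        order.append(j)
        for t in sorted(out_edges[j]):
            in_deg[t] -= 1
            if in_deg[t] == 0:
                ready.append(t)
    if len(order) != spec.m:
        raise ValidationError("dependency_graph contains a cycle")
    return order


def generate(spec: SyntheticSpec) -> MultiLabelDataset:
    """Draw a dataset from the spec; identical for identical seeds."""
    order = _topological_order(spec)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    X = rng.standard_normal((spec.n, spec.p))
    labels = np.zeros((spec.n, spec.m), dtype=np.int64)
    source_of = {t: (s, f) for s, t, f in spec.dependency_graph}

    s_per = spec.signal_features_per_root_label
    root_rank = 0
    for j in order:
        if j in source_of:
            src, flip = source_of[j]
            flips = rng.random(spec.n) < flip
            labels[:, j] = labels[:, src] ^ flips
        else:
            cols = [(root_rank * s_per + c) % spec.p for c in range(s_per)]
            score = X[:, cols].sum(axis=1)
            if spec.noise_sd > 0:
                score = score + rng.normal(0.0, spec.noise_sd, spec.n)
            labels[:, j] = (score > 0).astype(np.int64)
            root_rank += 1

    feature_names = [f"f{i + 1}" for i in range(spec.p)]
    label_names = [f"l{j + 1}" for j in range(spec.m)]
    return MultiLabelDataset(X, labels, feature_names, label_names).validate()
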