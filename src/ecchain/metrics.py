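"""Multi-label evaluation: per-label accuracy, Hamming loss, subset accuracy."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MetricsReport", "evaluate"]


@dataclass
class MetricsReport:
    """Evaluation of a binary prediction matrix against the truth.

    ``hamming_loss`` is the fraction of disagreeing label cells (hence
    ``1 - mean(per_label_accuracy)``); ``subset_accuracy`` is the fraction
    of instances whose entire label vector is exactly right.
    """

    per_label_accuracy: np.ndarray  # (m,) in [0, 1]
    hamming_loss: float
    subset_accuracy: float
    n_eval: int

    def as_text(self, label_names: list[str] | None = None) -> str:
        """Key-value block plus a per-label tab-separated table."""
        m = len(self.per_label_accuracy)
        names = label_names if label_names is not None else [f"label_{j}" for j in range(m)]
        lines = [
            f"n_eval\t{self.n_eval}",
            f"hamming_loss\t{self.hamming_loss:.6f}",
            f"subset_accuracy\t{self.subset_accuracy:.6f}",
            "",
            "label\taccuracy",
        ]
        lines += [f"{name}\t{acc:.6f}" for name, acc in zip(names, self.per_label_accuracy)]
        return "\n".join(lines)


def evaluate(pred: np.ndarray, truth: np.ndarray) -> MetricsReport:
    """Compare two binary n x m matrices cell-by-cell and row-by-row."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    if pred.ndim != 2 or pred.shape[0] < 1:
        raise ValueError("need a nonempty n x m matrix pair")
    agree = pred == truth
    per_label = agree.mean(axis=0)
    return MetricsReport(
        per_label_accuracy=per_label,
        hamming_loss=float(1.0 - agree.mean()),
        subset_accuracy=float(agree.all(axis=1).mean()),
        n_eval=pred.shape[0],
    )
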