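"""Margin loss and classification metrics.

The margin loss drives each trial's target-class capsule norm above
``m_plus`` and every other class norm below ``m_minus``:

    loss = T_n * max(0, m+ - ||u_n||)^2 + lam * (1 - T_n) * max(0, ||u_n|| - m-)^2

summed over classes and averaged over the batch. Accuracy follows the
standard confusion-matrix definition with *perception* (class 1) as the
positive class and *imagination* (class 0) as the negative class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, astensor
from .errors import ConfigurationError, DomainError, ShapeError


@dataclass
class MarginLossParams:
    m_plus: float = 0.9
    m_minus: float = 0.1
    lam: float = 0.5

    def __post_init__(self):
        if not (0.0 <= self.m_minus < self.m_plus <= 1.0):
            raise ConfigurationError(
                f"need 0 <= m_minus < m_plus <= 1, got m-={self.m_minus}, m+={self.m_plus}"
            )
        if self.lam <= 0:
            raise ConfigurationError(f"lam must be positive, got {self.lam}")


def one_hot(labels, n_classes: int = 2) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    eye = np.eye(n_classes)
    return eye[labels]


def margin_loss(norms, targets, params: MarginLossParams | None = None) -> Tensor:
    """Mean margin loss over a batch of per-class capsule norms.

    ``norms``: (batch, n_classes) capsule lengths in [0, 1];
    ``targets``: one-hot (batch, n_classes).
    """
    params = params or MarginLossParams()
    norms = astensor(norms)
    targets = np.asarray(targets, dtype=np.float64)
    if norms.shape != targets.shape:
        raise ShapeError(f"norms {norms.shape} vs targets {targets.shape}")
    if norms.data.min() < -1e-6 or norms.data.max() > 1.0 + 1e-6:
        raise DomainError(
            f"capsule norms must lie in [0, 1]; got range "
            f"[{norms.data.min():.6g}, {norms.data.max():.6g}]"
        )
    T = Tensor(targets)
    pos = (params.m_plus - norms).relu() ** 2.0
    neg = (norms - params.m_minus).relu() ** 2.0
    per_class = T * pos + params.lam * (1.0 - T) * neg
    return per_class.sum(axis=1).mean()


@dataclass
class ConfusionCounts:
    """Binary confusion counts; perception (label 1) is positive."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(predicted, labels) -> ConfusionCounts:
    predicted = np.asarray(predicted, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if predicted.shape != labels.shape:
        raise ShapeError(f"predictions {predicted.shape} vs labels {labels.shape}")
    bad = set(np.unique(predicted)) | set(np.unique(labels))
    if not bad <= {0, 1}:
        raise DomainError(f"labels/predictions must be binary, got values {sorted(bad)}")
    return ConfusionCounts(
        tp=int(np.sum((predicted == 1) & (labels == 1))),
        tn=int(np.sum((predicted == 0) & (labels == 0))),
        fp=int(np.sum((predicted == 1) & (labels == 0))),
        fn=int(np.sum((predicted == 0) & (labels == 1))),
    )


def accuracy(counts: ConfusionCounts) -> float:
    """Classification accuracy as a percentage."""
    if counts.total == 0:
        raise DomainError("accuracy undefined for zero evaluated trials")
    return 100.0 * (counts.tp + counts.tn) / counts.total
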