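"""Weighted multilabel sigmoid cross-entropy with L2 regularization.

The training objective for the symptom classifier: per class j with weight
p_j, per sample i with logit x_ij and binary label y_ij,

    loss = (1/N) * sum_j sum_i -[ y_ij * p_j * log sigmoid(x_ij)
                                  + (1 - y_ij) * log(1 - sigmoid(x_ij)) ]
           + lambda * sum ||params||^2

Only the positive term carries the class weight, so p_j > 1 penalizes
missed positives of a rare class harder than false alarms. With p_j = 1
and lambda = 0 this is plain mean binary cross-entropy summed over
classes. Computed through softplus so large-magnitude logits neither
overflow nor lose the gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LossConfig", "multilabel_loss", "multilabel_loss_grad", "class_weights_from_labels"]


@dataclass
class LossConfig:
    """class_weights: positive weight p_j per class; l2_coefficient: lambda >= 0."""

    class_weights: np.ndarray = field(default_factory=lambda: np.ones(2))
    l2_coefficient: float = 1e-4

    def __post_init__(self):
        self.class_weights = np.asarray(self.class_weights, dtype=float)
        if np.any(self.class_weights <= 0):
            raise ValueError("class weights must be positive")
        if self.l2_coefficient < 0:
            raise ValueError("l2_coefficient must be >= 0")


def _softplus(x: np.ndarray) -> np.ndarray:
    # log(1 + e^x), stable for both signs
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


def multilabel_loss(
    logits: np.ndarray,
    labels: np.ndarray,
    cfg: LossConfig,
    params: "list[np.ndarray] | None" = None,
) -> float:
    """Scalar loss for a (N, C) batch of logits and 0/1 labels.

    params: arrays entering the L2 penalty (weights of the network);
    omit or pass [] for the bare data term.
    """
    logits = np.asarray(logits, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if logits.shape != labels.shape or logits.ndim != 2:
        raise ValueError(f"shape mismatch: logits {logits.shape}, labels {labels.shape}")
    n, c = logits.shape
    if cfg.class_weights.shape[0] != c:
        raise ValueError(f"{cfg.class_weights.shape[0]} class weights for {c} classes")
    p = cfg.class_weights[None, :]
    # -log sigmoid(x) = softplus(-x); -log(1 - sigmoid(x)) = softplus(x)
    data = labels * p * _softplus(-logits) + (1.0 - labels) * _softplus(logits)
    total = float(data.sum() / n)
    if cfg.l2_coefficient > 0 and params:
        total += cfg.l2_coefficient * float(sum(np.sum(w.astype(float) ** 2) for w in params))
    return total


def multilabel_loss_grad(
    logits: np.ndarray, labels: np.ndarray, cfg: LossConfig
) -> np.ndarray:
    """Gradient of the data term w.r.t. the logits, shape (N, C).

    d/dx [y p softplus(-x) + (1-y) softplus(x)]
      = -y p (1 - sigmoid(x)) + (1-y) sigmoid(x)
    (the L2 term's gradient, 2*lambda*w, is applied directly to the
    parameters by the training loop).
    """
    logits = np.asarray(logits, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n = logits.shape[0]
    p = cfg.class_weights[None, :]
    sig = np.where(
        logits >= 0,
        1.0 / (1.0 + np.exp(-np.clip(logits, -500, None))),
        np.exp(np.clip(logits, None, 500)) / (1.0 + np.exp(np.clip(logits, None, 500))),
    )
    return (-labels * p * (1.0 - sig) + (1.0 - labels) * sig) / n


def class_weights_from_labels(labels: np.ndarray, cap: float = 10.0) -> np.ndarray:
    """Inverse positive-frequency class weights from a (N, C) label matrix.

    p_j = N / (number of positives in class j), capped; classes with no
    positives get the cap. Balances rare symptoms in the loss.
    """
    labels = np.asarray(labels, dtype=float)
    n = labels.shape[0]
    pos = labels.sum(axis=0)
    with np.errstate(divide="ignore"):
        w = np.where(pos > 0, n / np.maximum(pos, 1e-12), cap)
    return np.minimum(w, cap)
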