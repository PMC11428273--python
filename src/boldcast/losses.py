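"""The hybrid forecasting loss: adversarial + supervised terms.

The generator objective is the weighted sum

    L_G = lambda_ae * L_ae + lambda_t * L_t + lambda_dis * L_dis + lambda_g * L_g

with defaults (50, 3, 1, 1):

* ``L_ae`` — Euclidean distance between forecast and truth per window
  (the unsquared L2 norm, not MSE), averaged over the batch;
* ``L_t`` — trend loss: mean absolute difference of the sign of adjacent-step
  increments, anchored at the last observed value; 0 when every predicted
  increment has the true direction, 2 when every one is opposite;
* ``L_dis`` — distribution loss: absolute difference of the window means;
* ``L_g`` — sigmoid cross-entropy of the discriminator's fake-window logits
  against the all-ones label (fool-the-discriminator term).

The discriminator minimizes sigmoid cross-entropy of fake logits against 0
plus real logits against 1.

These are the evaluation/reporting forms on plain numpy arrays. Training uses
differentiable counterparts (see :mod:`boldcast.training`); the only
difference is a tanh surrogate for the zero-gradient sign function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossWeights",
    "sigmoid_cross_entropy",
    "generator_adv_loss",
    "discriminator_loss",
    "absolute_error_loss",
    "sign",
    "trend_loss",
    "distribution_loss",
    "generator_total_loss",
]


@dataclass(frozen=True)
class LossWeights:
    """Weights of the generator objective; defaults (50, 3, 1, 1)."""

    lambda_ae: float = 50.0
    lambda_t: float = 3.0
    lambda_dis: float = 1.0
    lambda_g: float = 1.0

    def __post_init__(self) -> None:
        if min(self.lambda_ae, self.lambda_t, self.lambda_dis, self.lambda_g) < 0:
            raise ValueError("loss weights must be non-negative")


def sigmoid_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> float:
    """-sum_i [b_i log sig(a_i) + (1-b_i) log(1-sig(a_i))], stable for large |a|.

    Uses the standard rearrangement max(a,0) - a*b + log(1+e^-|a|) so the
    value never overflows.
    """
    a = np.asarray(logits, dtype=np.float64)
    b = np.asarray(labels, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("logits and labels must have the same shape")
    if not np.all((b == 0.0) | (b == 1.0)):
        raise ValueError("labels must be in {0, 1}")
    return float(np.sum(np.maximum(a, 0.0) - a * b + np.log1p(np.exp(-np.abs(a)))))


def generator_adv_loss(logits_fake: np.ndarray) -> float:
    """Cross-entropy of D's fake-window logits against the all-ones label."""
    a = np.asarray(logits_fake, dtype=np.float64)
    return sigmoid_cross_entropy(a, np.ones_like(a))


def discriminator_loss(logits_fake: np.ndarray, logits_real: np.ndarray) -> float:
    """sce(fake, 0) + sce(real, 1)."""
    fa = np.asarray(logits_fake, dtype=np.float64)
    re = np.asarray(logits_real, dtype=np.float64)
    return sigmoid_cross_entropy(fa, np.zeros_like(fa)) \
        + sigmoid_cross_entropy(re, np.ones_like(re))


def _as_batch(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=np.float64)
    return y[None, :] if y.ndim == 1 else y


def absolute_error_loss(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Per-window Euclidean distance ||y - y_hat||_2, mean over the batch."""
    y, y_hat = _as_batch(y), _as_batch(y_hat)
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have the same shape")
    return float(np.mean(np.linalg.norm(y - y_hat, axis=-1)))


def sign(x: float, y: float) -> int:
    """1 if x > y, 0 if x == y, -1 if x < y."""
    return int(np.sign(x - y))


def trend_loss(y: np.ndarray, y_hat: np.ndarray,
               anchor: float | np.ndarray) -> float:
    """Mean |sign(predicted increment) - sign(true increment)| over the horizon.

    The first increment is measured against ``anchor`` (the last observed
    value before the forecast window), the rest between adjacent horizon
    steps. Lies in [0, 2].
    """
    y, y_hat = _as_batch(y), _as_batch(y_hat)
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have the same shape")
    if y.shape[1] < 1:
        raise ValueError("horizon must be >= 1")
    anchor = np.broadcast_to(np.asarray(anchor, dtype=np.float64),
                             (y.shape[0],))
    y_ext = np.concatenate([anchor[:, None], y], axis=1)
    yh_ext = np.concatenate([anchor[:, None], y_hat], axis=1)
    s_true = np.sign(np.diff(y_ext, axis=1))
    s_pred = np.sign(np.diff(yh_ext, axis=1))
    return float(np.mean(np.mean(np.abs(s_pred - s_true), axis=1)))


def distribution_loss(y: np.ndarray, y_hat: np.ndarray) -> float:
    """|mean(y) - mean(y_hat)| per window, mean over the batch."""
    y, y_hat = _as_batch(y), _as_batch(y_hat)
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have the same shape")
    return float(np.mean(np.abs(y.mean(axis=1) - y_hat.mean(axis=1))))


def generator_total_loss(y: np.ndarray, y_hat: np.ndarray,
                         disc_logits_fake: np.ndarray,
                         weights: LossWeights = LossWeights(),
                         anchor: float | np.ndarray = 0.0) -> float:
    """The weighted generator objective L_G (evaluation form)."""
    return (weights.lambda_ae * absolute_error_loss(y, y_hat)
            + weights.lambda_t * trend_loss(y, y_hat, anchor)
            + weights.lambda_dis * distribution_loss(y, y_hat)
            + weights.lambda_g * generator_adv_loss(disc_logits_fake))
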