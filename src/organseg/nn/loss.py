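"""Soft-Dice training loss.

Per sample and per class,

    dice = (2 * sum(p*t) + eps) / (sum(p) + sum(t) + eps)

with eps = 1e-5 (the same smoothing constant used by the evaluation Dice
score) and the sums over the spatial axes; the loss is one minus the
mean over all (sample, class) pairs, with equal weights.  Averaging per
sample rather than over a pooled batch keeps the gradient of a rare
class at full strength on the slices where it appears — pooling the
batch dilutes small organs by every other slice's probability mass.
A sample where both the class's prediction and target are empty scores
dice ~ 1 through eps and contributes almost no gradient.  The loss lies
in [0, 1) and is differentiable in the probabilities.
"""

from __future__ import annotations

import numpy as np

__all__ = ["soft_dice_loss", "soft_dice_grad"]

EPS = 1e-5


def _terms(probs: np.ndarray, targets: np.ndarray):
    """Per-(sample, class) intersection and sums.

    4D input is (N, C, H, W); anything else is treated as (C, ...) with
    one implicit sample.
    """
    if probs.shape != targets.shape:
        raise ValueError(f"shape mismatch {probs.shape} vs {targets.shape}")
    spatial = tuple(range(2, probs.ndim)) if probs.ndim == 4 else tuple(
        range(1, probs.ndim)
    )
    t = targets.astype(probs.dtype)
    inter = (probs * t).sum(axis=spatial)
    psum = probs.sum(axis=spatial)
    tsum = t.sum(axis=spatial)
    return inter, psum, tsum, t, spatial


def soft_dice_loss(probs: np.ndarray, targets: np.ndarray, eps: float = EPS) -> float:
    """Soft-Dice loss; ``probs`` and ``targets`` are (N, C, H, W), or a
    single sample with classes on axis 0."""
    inter, psum, tsum, _, _ = _terms(probs, targets)
    dice = (2.0 * inter + eps) / (psum + tsum + eps)
    return float(1.0 - dice.mean())


def soft_dice_grad(
    probs: np.ndarray, targets: np.ndarray, eps: float = EPS
) -> tuple[float, np.ndarray]:
    """Loss value and its gradient with respect to the probabilities."""
    inter, psum, tsum, t, spatial = _terms(probs, targets)
    denom = psum + tsum + eps
    num = 2.0 * inter + eps
    loss = float(1.0 - (num / denom).mean())
    # d dice / d p = (2*t*denom - num) / denom^2, per (sample, class)
    shape = denom.shape + (1,) * len(spatial)
    denom_b = denom.reshape(shape)
    num_b = num.reshape(shape)
    grad = -(2.0 * t * denom_b - num_b) / (denom_b**2) / denom.size
    return loss, grad.astype(probs.dtype)
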