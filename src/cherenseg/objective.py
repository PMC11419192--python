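"""Compound segmentation objective: weighted Dice plus cross-entropy.

The training loss is L = lambda_dice * L_Dice + lambda_ce * L_CE evaluated
on sigmoid probabilities (not logits).  With a single-channel sigmoid
output, cross-entropy is the binary cross-entropy; a two-channel softmax
formulation would be mathematically identical.  Defaults lambda_dice = 1
and lambda_ce = 0.1 are the weighting found to train best.

Both losses are differentiable in the prediction; ``seg_loss_grad``
returns the exact analytic gradient used by the trainer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class LossConfig:
    lambda_dice: float = 1.0
    lambda_ce: float = 0.1
    eps: float = 1e-5       # Dice ratio smoothing
    delta: float = 1e-7     # probability clip before the logarithm
    # optional per-class weight hook (1, 1 = the unweighted objective)
    pos_weight: float = 1.0
    neg_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda_dice < 0 or self.lambda_ce < 0:
            raise ValueError("loss weights must be non-negative")
        if self.eps <= 0 or self.delta <= 0:
            raise ValueError("eps and delta must be positive")


def _as_batch(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=np.float64)
    if a.ndim == 2:
        a = a[None]
    return a.reshape(a.shape[0], -1)


def _check_shapes(yp: np.ndarray, yt: np.ndarray) -> None:
    if np.shape(yp) != np.shape(yt):
        raise ValueError(
            f"prediction shape {np.shape(yp)} != target shape {np.shape(yt)}"
        )


def dice_loss(yp: np.ndarray, yt: np.ndarray, eps: float = 1e-5) -> float:
    """Soft Dice loss 1 - (2*sum(yp*yt) + eps) / (sum(yp) + sum(yt) + eps),
    computed per sample and averaged over the batch."""
    _check_shapes(yp, yt)
    p, t = _as_batch(yp), _as_batch(yt)
    inter = (p * t).sum(axis=1)
    denom = p.sum(axis=1) + t.sum(axis=1)
    return float(np.mean(1.0 - (2.0 * inter + eps) / (denom + eps)))


def dice_loss_grad(yp: np.ndarray, yt: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    _check_shapes(yp, yt)
    shape = np.shape(yp)
    p, t = _as_batch(yp), _as_batch(yt)
    b = p.shape[0]
    inter = (p * t).sum(axis=1, keepdims=True)
    denom = p.sum(axis=1, keepdims=True) + t.sum(axis=1, keepdims=True)
    g = -(2.0 * t * (denom + eps) - (2.0 * inter + eps)) / (denom + eps) ** 2 / b
    return g.reshape(shape)


def ce_loss(
    yp: np.ndarray, yt: np.ndarray, delta: float = 1e-7,
    pos_weight: float = 1.0, neg_weight: float = 1.0,
) -> float:
    """Pixel-mean binary cross-entropy on probabilities, clipped away from
    {0, 1} by delta before the logarithm."""
    _check_shapes(yp, yt)
    p = np.clip(np.asarray(yp, dtype=np.float64), delta, 1.0 - delta)
    t = np.asarray(yt, dtype=np.float64)
    ll = pos_weight * t * np.log(p) + neg_weight * (1.0 - t) * np.log(1.0 - p)
    return float(-ll.mean())


def ce_loss_grad(
    yp: np.ndarray, yt: np.ndarray, delta: float = 1e-7,
    pos_weight: float = 1.0, neg_weight: float = 1.0,
) -> np.ndarray:
    _check_shapes(yp, yt)
    p = np.clip(np.asarray(yp, dtype=np.float64), delta, 1.0 - delta)
    t = np.asarray(yt, dtype=np.float64)
    n = p.size
    g = (-pos_weight * t / p + neg_weight * (1.0 - t) / (1.0 - p)) / n
    # clipped region has zero slope
    inside = (np.asarray(yp) > delta) & (np.asarray(yp) < 1.0 - delta)
    return g * inside


def seg_loss(yp: np.ndarray, yt: np.ndarray, cfg: LossConfig | None = None) -> float:
    """lambda_dice * Dice loss + lambda_ce * cross-entropy."""
    cfg = cfg or LossConfig()
    total = 0.0
    if cfg.lambda_dice:
        total += cfg.lambda_dice * dice_loss(yp, yt, cfg.eps)
    if cfg.lambda_ce:
        total += cfg.lambda_ce * ce_loss(
            yp, yt, cfg.delta, cfg.pos_weight, cfg.neg_weight
        )
    return total


def seg_loss_grad(
    yp: np.ndarray, yt: np.ndarray, cfg: LossConfig | None = None
) -> np.ndarray:
    """Exact gradient of ``seg_loss`` with respect to the probabilities."""
    cfg = cfg or LossConfig()
    g = np.zeros(np.shape(yp))
    if cfg.lambda_dice:
        g += cfg.lambda_dice * dice_loss_grad(yp, yt, cfg.eps)
    if cfg.lambda_ce:
        g += cfg.lambda_ce * ce_loss_grad(
            yp, yt, cfg.delta, cfg.pos_weight, cfg.neg_weight
        )
    return g
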