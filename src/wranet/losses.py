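"""Training objectives: binary cross-entropy, soft Dice, and their mixture.

The network head emits probabilities, so every loss here consumes
probabilities directly (no logits).  The Dice loss uses soft probabilities
without thresholding; its smoothing factor ``lambda`` guards the empty-mask
denominator.  The hybrid objective is the weighted sum

    L = alpha * L_BCE + beta * L_Dice,   defaults alpha = 0.4, beta = 0.6,

which balances the pixel-wise calibration of cross-entropy against the
overlap-driven, class-imbalance-robust Dice term.

Note a documented degeneracy: on a perfectly predicted *empty* mask the soft
Dice loss is 1, not 0 (its numerator vanishes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor

__all__ = ["LossConfig", "bce_loss", "dice_loss", "hybrid_loss"]


@dataclass(frozen=True)
class LossConfig:
    """Weights and numerical guards of the hybrid objective."""

    alpha_weight: float = 0.4
    beta_weight: float = 0.6
    lambda_smooth: float = 1.0
    epsilon: float = 1e-7

    def __post_init__(self):
        if not 0.0 <= self.alpha_weight <= 1.0 or not 0.0 <= self.beta_weight <= 1.0:
            raise ValueError("loss weights must lie in [0, 1]")
        if self.lambda_smooth <= 0:
            raise ValueError("lambda_smooth must be positive")
        if not 0.0 < self.epsilon < 0.5:
            raise ValueError("epsilon must be a small positive probability clamp")


def _prepare(p, y):
    p_t = p if isinstance(p, Tensor) else Tensor(np.asarray(p, dtype=np.float64))
    y_a = y.data if isinstance(y, Tensor) else np.asarray(y)
    y_a = y_a.astype(p_t.data.dtype, copy=False)   # keep the graph's precision
    if p_t.shape != y_a.shape:
        raise ValueError(f"prediction shape {p_t.shape} != target shape {y_a.shape}")
    if not np.all((y_a == 0.0) | (y_a == 1.0)):
        raise ValueError("target mask must be binary (0/1)")
    return p_t, Tensor(y_a), isinstance(p, Tensor)


def bce_loss(p, y, epsilon: float = 1e-7):
    """Mean binary cross-entropy over all pixels; p clamped to [eps, 1-eps]."""
    p_t, y_t, keep = _prepare(p, y)
    p_c = p_t.clip(epsilon, 1.0 - epsilon)
    loss = -(y_t * p_c.log() + (1.0 - y_t) * (1.0 - p_c).log()).mean()
    return loss if keep else loss.item()


def dice_loss(p, y, lambda_smooth: float = 1.0):
    """Soft Dice loss ``1 - 2*sum(p*y) / (sum(p + y) + lambda)``."""
    p_t, y_t, keep = _prepare(p, y)
    inter = (p_t * y_t).sum()
    denom = (p_t + y_t).sum() + lambda_smooth
    loss = 1.0 - 2.0 * inter / denom
    return loss if keep else loss.item()


def hybrid_loss(p, y, config: LossConfig = LossConfig()):
    """Weighted BCE + Dice mixture (the segmentation training objective)."""
    p_t, _, keep = _prepare(p, y)
    loss = (config.alpha_weight * bce_loss(p_t, y, config.epsilon)
            + config.beta_weight * dice_loss(p_t, y, config.lambda_smooth))
    return loss if keep else loss.item()
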