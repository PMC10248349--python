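"""Residual attention gate for skip connections.

The gate produces a single-channel, per-pixel attention coefficient
``alpha in (0, 1)`` from the decoder (gating) feature ``x_g`` and the encoder
(skip) feature ``x_l``:

    alpha = sigmoid( phi( relu( BN(W_g x_g) + BN(W_l x_l) ) ) )

with 1x1 projections ``W_g``/``W_l`` to a common intermediate width (here the
skip channel count), and ``phi`` a biased 1x1 projection to one channel.  The
skip feature is recalibrated and passed on with a residual term:

    x_hat = alpha * x_l          (alpha broadcast over channels)
    x_out = x_hat + x_l = (1 + alpha) * x_l

so the gate can only scale the skip path between 1x and 2x — it attenuates
nothing to zero, which keeps gradients flowing through shallow features.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor
from .nn import BatchNorm2d, Conv2d, Module

__all__ = ["AttentionGate", "attention_coefficients", "ram_forward"]


class AttentionGate(Module):
    """Residual attention module for one skip level."""

    def __init__(self, gating_channels: int, skip_channels: int,
                 rng: np.random.Generator, inter_channels: int | None = None):
        super().__init__()
        if inter_channels is None:
            inter_channels = skip_channels      # keep capacity proportional to depth
        if inter_channels < 1:
            raise ValueError("intermediate channel count must be >= 1")
        self.proj_gate = Conv2d(gating_channels, inter_channels, 1, rng)
        self.proj_skip = Conv2d(skip_channels, inter_channels, 1, rng)
        self.norm_gate = BatchNorm2d(inter_channels)
        self.norm_skip = BatchNorm2d(inter_channels)
        self.phi = Conv2d(inter_channels, 1, 1, rng)

    @staticmethod
    def _check(x_g: Tensor, x_l: Tensor) -> None:
        if x_g.shape[-2:] != x_l.shape[-2:]:
            raise ValueError(
                f"gating and skip features must share spatial size, got "
                f"{x_g.shape[-2:]} vs {x_l.shape[-2:]}"
            )

    def coefficients(self, x_g: Tensor, x_l: Tensor) -> Tensor:
        """Per-pixel attention map of shape (N, 1, H, W), values in (0, 1)."""
        self._check(x_g, x_l)
        summed = self.norm_gate(self.proj_gate(x_g)) + self.norm_skip(self.proj_skip(x_l))
        return self.phi(summed.relu()).sigmoid()

    def forward(self, x_g: Tensor, x_l: Tensor) -> Tensor:
        """Recalibrated skip feature with residual: (1 + alpha) * x_l."""
        alpha = self.coefficients(x_g, x_l)
        return alpha * x_l + x_l


def _lift(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def attention_coefficients(x_g, x_l, gate: AttentionGate) -> np.ndarray:
    """Functional wrapper: the alpha map as a plain array."""
    return gate.coefficients(_lift(x_g), _lift(x_l)).data


def ram_forward(x_g, x_l, gate: AttentionGate) -> np.ndarray:
    """Functional wrapper: the gated-plus-residual skip feature as an array."""
    return gate(_lift(x_g), _lift(x_l)).data
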