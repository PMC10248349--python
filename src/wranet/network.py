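"""The WRANet architecture: a U-shaped encoder/decoder whose downsampling is
the LL subband of a discrete wavelet transform and whose skip connections are
recalibrated by residual attention gates.

Layout (depth 4, base 64):

    encoder   conv_block(in -> 64)   -> pool -> conv_block(128) -> pool
              -> conv_block(256)     -> pool -> conv_block(512) -> pool
    bottleneck conv_block(1024)
    decoder   4 x [bilinear x2 + 3x3 conv halving channels -> attention gate
                   on the matching skip -> concat -> conv_block]
    head      1x1 conv to 1 channel + sigmoid

Each conv_block is two (3x3 conv -> BN -> ReLU) stages.  ``downsample`` may
be ``"wavelet"`` (default) or ``"maxpool"`` for the pooling ablation; the
attention gates can be disabled (plain skip concatenation) — both switches
leave every shape contract unchanged, and the wavelet choice does not change
the parameter count.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .attention import AttentionGate
from .autograd import Tensor, concat
from .nn import (
    Adam,
    BatchNorm2d,
    Conv2d,
    MaxPool2d,
    Module,
    WaveletPool2d,
    bilinear_upsample2,
)
from .wavelets import WaveletSpec, build_filter_bank

__all__ = ["NetworkConfig", "ConvBlock", "UpsampleBlock", "WRANet",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    The channel ladder is ``base_channels * (1, 2, 4, 8)`` across the four
    encoder levels with a ``base_channels * 16`` bottleneck — i.e. the
    64/128/256/512/1024 ladder when ``base_channels`` is 64.
    """

    in_channels: int = 1
    base_channels: int = 64
    depth: int = 4
    wavelet: str = "sym6"
    downsample: str = "wavelet"      # "wavelet" | "maxpool"
    use_attention: bool = True

    def __post_init__(self):
        if self.in_channels not in (1, 3):
            raise ValueError("in_channels must be 1 (grayscale) or 3 (RGB)")
        if self.base_channels < 1 or self.depth < 1:
            raise ValueError("base_channels and depth must be positive")
        if self.downsample not in ("wavelet", "maxpool"):
            raise ValueError("downsample must be 'wavelet' or 'maxpool'")
        WaveletSpec.from_name(self.wavelet)   # validate eagerly

    @property
    def size_multiple(self) -> int:
        return 2 ** self.depth

    @property
    def channel_ladder(self) -> tuple:
        return tuple(self.base_channels * 2 ** i for i in range(self.depth + 1))


class ConvBlock(Module):
    """Two (3x3 conv -> BN -> ReLU) stages; spatial size preserved."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(in_channels, out_channels, 3, rng)
        self.norm1 = BatchNorm2d(out_channels)
        self.conv2 = Conv2d(out_channels, out_channels, 3, rng)
        self.norm2 = BatchNorm2d(out_channels)

    def forward(self, x: Tensor) -> Tensor:
        x = self.norm1(self.conv1(x)).relu()
        return self.norm2(self.conv2(x)).relu()


class UpsampleBlock(Module):
    """Bilinear x2 upsampling, then a 3x3 conv halving the channel count,
    then BN and ReLU: (C, H, W) -> (C/2, 2H, 2W)."""

    def __init__(self, in_channels: int, rng: np.random.Generator):
        super().__init__()
        if in_channels % 2:
            raise ValueError("upsample block requires an even channel count")
        self.conv = Conv2d(in_channels, in_channels // 2, 3, rng)
        self.norm = BatchNorm2d(in_channels // 2)

    def forward(self, x: Tensor) -> Tensor:
        return self.norm(self.conv(bilinear_upsample2(x))).relu()


class WRANet(Module):
    """Wavelet residual attention network producing per-pixel probabilities."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        ladder = config.channel_ladder            # e.g. (64, 128, 256, 512, 1024)

        self.enc_blocks = []
        chans = config.in_channels
        for c in ladder[:-1]:
            self.enc_blocks.append(ConvBlock(chans, c, rng))
            chans = c
        if config.downsample == "wavelet":
            bank = build_filter_bank(config.wavelet)
            self.pool = WaveletPool2d(bank)
        else:
            self.pool = MaxPool2d()
        self.bottleneck = ConvBlock(ladder[-2], ladder[-1], rng)

        self.up_blocks = []
        self.gates = []
        self.dec_blocks = []
        for c in reversed(ladder[:-1]):           # 512, 256, 128, 64
            self.up_blocks.append(UpsampleBlock(2 * c, rng))
            self.gates.append(AttentionGate(c, c, rng) if config.use_attention else None)
            self.dec_blocks.append(ConvBlock(2 * c, c, rng))
        self.head = Conv2d(ladder[0], 1, 1, rng)

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected input of shape (N, {self.config.in_channels}, H, W), "
                f"got {x.shape}"
            )
        m = self.config.size_multiple
        h, w = x.shape[2], x.shape[3]
        if h % m or w % m:
            raise ValueError(
                f"spatial size {h}x{w} must be divisible by {m} "
                f"(depth-{self.config.depth} network)"
            )
        return x

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(self._check_input(x))
        else:
            self._check_input(x.data)
        skips = []
        for block in self.enc_blocks:
            x = block(x)
            skips.append(x)
            x = self.pool(x)
        x = self.bottleneck(x)
        for up, gate, dec, skip in zip(self.up_blocks, self.gates,
                                       self.dec_blocks, reversed(skips)):
            x = up(x)
            gated = gate(x, skip) if gate is not None else skip
            x = dec(concat([gated, x], axis=1))
        return self.head(x).sigmoid()

    def predict_proba(self, x: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Probability maps (N, 1, H, W) in evaluation mode (running stats)."""
        x = self._check_input(x)
        was_training = self.training
        self.eval()
        try:
            chunks = [self.forward(x[i:i + batch_size]).data
                      for i in range(0, len(x), batch_size)]
        finally:
            self.train(was_training)
        return np.concatenate(chunks, axis=0)


def save_checkpoint(model: WRANet, path) -> None:
    """Parameter archive (.npz) plus a JSON sidecar with the config."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.named_state())
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(
        {"network": asdict(model.config), "version": __version__}, indent=2))


def load_checkpoint(path) -> WRANet:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    model = WRANet(NetworkConfig(**meta["network"]))
    with np.load(path) as archive:
        model.load_state(dict(archive))
    return model
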