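"""Neural-network layers and the Adam optimizer on top of the autodiff engine.

Layers follow the usual conventions: NCHW feature maps, 3x3 same-padding or
1x1 convolutions, batch normalization with running statistics, bilinear x2
upsampling with half-pixel centres, 2x2 max pooling, and LL-only wavelet
pooling built from the periodized analysis matrices.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autograd import Tensor
from .wavelets import FilterBank, _analysis_matrix

__all__ = [
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "WaveletPool2d",
    "MaxPool2d",
    "bilinear_upsample2",
    "Adam",
]


class Module:
    """Minimal parameter container with train/eval mode propagation."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self):
        params = []
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Tensor) and v.requires_grad:
                    params.append(v)
        return params

    def named_state(self):
        """Flat name -> array mapping of parameters and buffers (for I/O)."""
        state = {}
        for i, m in enumerate(self.modules()):
            for name, v in m.__dict__.items():
                if isinstance(v, Tensor) and v.requires_grad:
                    state[f"{i}.{type(m).__name__}.{name}"] = v.data
                elif isinstance(v, np.ndarray):
                    state[f"{i}.{type(m).__name__}.{name}"] = v
        return state

    def load_state(self, state: dict) -> None:
        for key, arr in self.named_state().items():
            if key not in state:
                raise KeyError(f"checkpoint is missing parameter {key!r}")
            if state[key].shape != arr.shape:
                raise ValueError(
                    f"shape mismatch for {key!r}: checkpoint {state[key].shape} "
                    f"vs model {arr.shape}"
                )
            arr[...] = state[key]

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def param_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _conv3x3_raw(x: np.ndarray, weight: np.ndarray, bias=None):
    """Same-padding stride-1 3x3 correlation; returns output and im2col."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))      # (N,C,H,W,3,3)
    col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)
    out = col @ weight.reshape(weight.shape[0], -1).T
    if bias is not None:
        out = out + bias
    return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2), col


class Conv2d(Module):
    """3x3 same-padding or 1x1 convolution, stride 1, Kaiming-uniform init."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        if kernel_size not in (1, 3):
            raise ValueError("only 1x1 and 3x3 kernels are supported")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        fan_in = in_channels * kernel_size * kernel_size
        bound = np.sqrt(6.0 / fan_in)
        self.weight = Tensor(
            rng.uniform(-bound, bound,
                        (out_channels, in_channels, kernel_size, kernel_size)
                        ).astype(np.float32),
            requires_grad=True,
        )
        self.bias = (Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True)
                     if bias else None)

    def forward(self, x: Tensor) -> Tensor:
        if self.kernel_size == 1:
            n, c, h, w = x.shape
            flat = x.reshape(n, c, h * w).transpose((0, 2, 1))     # (N,HW,C)
            wmat = self.weight.reshape(self.out_channels, c)
            out = flat @ wmat.transpose((1, 0))
            if self.bias is not None:
                out = out + self.bias
            return out.transpose((0, 2, 1)).reshape(n, self.out_channels, h, w)
        return self._conv3(x)

    def _conv3(self, x: Tensor) -> Tensor:
        weight, bias = self.weight, self.bias
        bias_data = bias.data if bias is not None else None
        out_data, col = _conv3x3_raw(x.data, weight.data, bias_data)
        prev = (x, weight) + ((bias,) if bias is not None else ())
        out = Tensor(out_data, _prev=prev)

        def bwd(g):
            n, co, h, w = g.shape
            gmat = g.transpose(0, 2, 3, 1).reshape(n * h * w, co)
            if weight.requires_grad:
                dw = gmat.T @ col
                weight._accumulate(dw.reshape(weight.shape))
            if bias is not None and bias.requires_grad:
                bias._accumulate(gmat.sum(axis=0))
            if x.requires_grad:
                wflip = weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
                dx, _ = _conv3x3_raw(g, wflip)
                x._accumulate(dx)

        out._backward = bwd
        return out


class BatchNorm2d(Module):
    """Per-channel batch normalization with affine transform and running
    statistics (biased batch variance; eval mode uses the running stats)."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones((1, num_features, 1, 1), dtype=np.float32),
                            requires_grad=True)
        self.beta = Tensor(np.zeros((1, num_features, 1, 1), dtype=np.float32),
                           requires_grad=True)
        self.running_mean = np.zeros((1, num_features, 1, 1), dtype=np.float32)
        self.running_var = np.ones((1, num_features, 1, 1), dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        axes = (0, 2, 3)
        training = self.training
        if training:
            mu = x.data.mean(axis=axes, keepdims=True)
            var = x.data.var(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mu).astype(
                self.running_mean.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(
                self.running_var.dtype)
        else:
            mu, var = self.running_mean, self.running_var
        istd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu) * istd
        gamma, beta = self.gamma, self.beta
        out = Tensor(gamma.data * xhat + beta.data, _prev=(x, gamma, beta))

        def bwd(g):
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).sum(axis=axes, keepdims=True))
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=axes, keepdims=True))
            if x.requires_grad:
                scale = gamma.data * istd
                if training:
                    gm = g.mean(axis=axes, keepdims=True)
                    gxm = (g * xhat).mean(axis=axes, keepdims=True)
                    x._accumulate(scale * (g - gm - xhat * gxm))
                else:
                    x._accumulate(scale * g)

        out._backward = bwd
        return out


class WaveletPool2d(Module):
    """Downsampling by the LL subband of a single-level periodized 2D DWT.

    Linear in the input, so gradients flow through the transposed analysis
    matrices automatically; detail subbands are never formed.
    """

    def __init__(self, bank: FilterBank):
        super().__init__()
        self.bank = bank

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[-2], x.shape[-1]
        if h % 2 or w % 2:
            raise ValueError(f"spatial size {h}x{w} must be even for wavelet pooling")
        dtype = x.data.dtype
        cl = Tensor(_analysis_matrix(self.bank.analysis_low, h).astype(dtype))
        rl = Tensor(_analysis_matrix(self.bank.analysis_low, w).astype(dtype))
        return cl @ x @ rl.transpose((1, 0))


class MaxPool2d(Module):
    """2x2 max pooling, stride 2 (the conventional pooling ablation)."""

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial size {h}x{w} must be even for 2x2 pooling")
        v = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = v.reshape(n, c, h // 2, w // 2, 4)
        idx = flat.argmax(axis=-1)
        out = Tensor(np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0], _prev=(x,))

        def bwd(g):
            if not x.requires_grad:
                return
            gw = np.zeros_like(flat)
            np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
            gx = gw.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            x._accumulate(gx.reshape(n, c, h, w))

        out._backward = bwd
        return out


_UPSAMPLE_CACHE: dict = {}


def _upsample_matrix(n: int) -> np.ndarray:
    """(2n, n) bilinear x2 interpolation with half-pixel centres, edge clamp."""
    mat = _UPSAMPLE_CACHE.get(n)
    if mat is None:
        mat = np.zeros((2 * n, n))
        src = (np.arange(2 * n) + 0.5) / 2.0 - 0.5
        j0 = np.floor(src).astype(int)
        frac = src - j0
        for i in range(2 * n):
            a = min(max(j0[i], 0), n - 1)
            b = min(max(j0[i] + 1, 0), n - 1)
            mat[i, a] += 1.0 - frac[i]
            mat[i, b] += frac[i]
        mat.setflags(write=False)
        _UPSAMPLE_CACHE[n] = mat
    return mat


def bilinear_upsample2(x: Tensor) -> Tensor:
    """Bilinear x2 upsampling of a (..., H, W) tensor (separable, linear)."""
    h, w = x.shape[-2], x.shape[-1]
    dtype = x.data.dtype if isinstance(x, Tensor) else np.asarray(x).dtype
    uh = Tensor(_upsample_matrix(h).astype(dtype))
    uw = Tensor(_upsample_matrix(w).astype(dtype))
    return uh @ x @ uw.transpose((1, 0))


class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 5e-4):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
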