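"""Wavelet filter banks and the single-level 2D discrete wavelet transform.

This module provides the downsampling primitive of the network: feature maps
are decomposed into the four DWT subbands (LL, LH, HL, HH) with periodized
boundary handling, and only the low-frequency LL subband is propagated.

Conventions
-----------
* Low-pass coefficients come from the standard published tables (PyWavelets);
  high-pass filters are *derived* from them by the quadrature-mirror
  recurrence ``h_i = (-1)^i l~_{2n+1-i}`` rather than read from tables.
* Analysis filtering is ``y[k] = sum_i f_i x[(2k + i) mod N]`` — circular
  (periodized) extension followed by keeping even-indexed outputs — so one
  level of an H x W input yields exactly H/2 x W/2 coefficients for every
  supported filter length.
* Orientation naming: ``lh`` means row (horizontal) high-pass followed by
  column low-pass, i.e. horizontal detail; ``hl`` is the vertical detail;
  ``hh`` the diagonal detail.  Rows are transformed first.
* Normalisation is orthonormal (``sum(l) = sqrt(2)``), so one 2D level maps a
  constant image ``c`` to a constant LL of ``2c`` and conserves energy for
  orthogonal families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pywt

__all__ = [
    "WAVELET_NAMES",
    "WaveletSpec",
    "FilterBank",
    "SubbandSet",
    "build_filter_bank",
    "validate_bank",
    "dwt2",
    "idwt2",
    "wavelet_downsample",
    "render_subband_grid",
]

ORTHOGONAL_FAMILIES = ("haar", "db", "sym")
BIORTHOGONAL_FAMILIES = ("bior", "rbio")
BIORTHOGONAL_ORDERS = ("1.1", "2.2", "3.3", "4.4")

#: The supported wavelet registry: Haar, Daubechies and Symlet orders 2-7,
#: and the four biorthogonal / reverse-biorthogonal variants.
WAVELET_NAMES = (
    ("haar",)
    + tuple(f"db{s}" for s in range(2, 8))
    + tuple(f"sym{s}" for s in range(2, 8))
    + tuple(f"bior{o}" for o in BIORTHOGONAL_ORDERS)
    + tuple(f"rbio{o}" for o in BIORTHOGONAL_ORDERS)
)


class UnsupportedWaveletError(ValueError):
    """Raised for a wavelet family/order outside the supported registry."""


def _unsupported(name: object) -> UnsupportedWaveletError:
    return UnsupportedWaveletError(
        f"unsupported wavelet {name!r}; valid choices are haar, db1-db7, "
        f"sym1-sym7, bior{{{','.join(BIORTHOGONAL_ORDERS)}}}, "
        f"rbio{{{','.join(BIORTHOGONAL_ORDERS)}}} "
        f"(registry names: {', '.join(WAVELET_NAMES)})"
    )


@dataclass(frozen=True)
class WaveletSpec:
    """A wavelet family plus its scale/order.

    ``order`` is the integer scale S for orthogonal families (filter length
    2S, S in 1..7; haar forces S = 1, and db1/sym1 coincide with haar) or the
    printed "p.q" string for the biorthogonal families (1.1, 2.2, 3.3, 4.4).
    """

    family: str
    order: Union[int, str] = 1

    def __post_init__(self) -> None:
        if self.family not in ORTHOGONAL_FAMILIES + BIORTHOGONAL_FAMILIES:
            raise _unsupported(self.family)
        if self.family in ORTHOGONAL_FAMILIES:
            try:
                s = int(self.order)
            except (TypeError, ValueError):
                raise _unsupported(f"{self.family}{self.order}") from None
            if not 1 <= s <= 7 or (self.family == "haar" and s != 1):
                raise _unsupported(f"{self.family}{self.order}")
            object.__setattr__(self, "order", s)
        else:
            if str(self.order) not in BIORTHOGONAL_ORDERS:
                raise _unsupported(f"{self.family}{self.order}")
            object.__setattr__(self, "order", str(self.order))

    @classmethod
    def from_name(cls, name: str) -> "WaveletSpec":
        name = str(name).strip().lower()
        if name == "haar":
            return cls("haar", 1)
        for fam in ("db", "sym", "bior", "rbio"):
            if name.startswith(fam):
                return cls(fam, name[len(fam):])
        raise _unsupported(name)

    @property
    def name(self) -> str:
        return "haar" if self.family == "haar" else f"{self.family}{self.order}"

    @property
    def is_orthogonal(self) -> bool:
        return self.family in ORTHOGONAL_FAMILIES

    @property
    def pywt_name(self) -> str:
        # db1 and sym1 are the Haar filter; PyWavelets spells it "haar"/"db1".
        if self.is_orthogonal and self.order == 1:
            return "haar"
        return self.name


@dataclass(frozen=True)
class FilterBank:
    """Analysis and synthesis filter pairs for one wavelet."""

    analysis_low: np.ndarray
    analysis_high: np.ndarray
    synthesis_low: np.ndarray
    synthesis_high: np.ndarray
    spec: WaveletSpec

    def __post_init__(self) -> None:
        for f in ("analysis_low", "analysis_high", "synthesis_low", "synthesis_high"):
            arr = np.asarray(getattr(self, f), dtype=np.float64)
            arr.setflags(write=False)
            object.__setattr__(self, f, arr)

    def __len__(self) -> int:
        return len(self.analysis_low)


@dataclass(frozen=True)
class SubbandSet:
    """The four single-level 2D-DWT outputs of a feature map."""

    ll: np.ndarray
    lh: np.ndarray
    hl: np.ndarray
    hh: np.ndarray

    def __post_init__(self) -> None:
        shapes = {b.shape for b in (self.ll, self.lh, self.hl, self.hh)}
        if len(shapes) != 1:
            raise ValueError(f"subband shapes differ: {sorted(map(str, shapes))}")

    @property
    def shape(self):
        return self.ll.shape


def _qmf(dual_low: np.ndarray) -> np.ndarray:
    """High-pass from the (dual) low-pass: h_i = (-1)^i l_{2n+1-i}.

    With filter length L = 2(n+1) the window n = L/2 - 1 is the unique choice
    keeping every referenced index valid, giving h_i = (-1)^i l_{L-1-i}.
    """
    L = len(dual_low)
    i = np.arange(L)
    return (-1.0) ** i * dual_low[L - 1 - i]


def build_filter_bank(spec: Union[WaveletSpec, str]) -> FilterBank:
    """Construct the analysis/synthesis filter bank for one wavelet.

    Low-pass filters are taken from the published coefficient tables; both
    high-pass filters are derived by the quadrature-mirror recurrence from
    the *dual* low-pass (for orthogonal wavelets the bank is self-dual).
    """
    if isinstance(spec, str):
        spec = WaveletSpec.from_name(spec)
    w = pywt.Wavelet(spec.pywt_name)
    # dec_lo is stored time-reversed relative to rec_lo; flip it so that both
    # low-pass filters share the convolution orientation of this module.
    l = np.asarray(w.dec_lo, dtype=np.float64)[::-1]
    l_dual = np.asarray(w.rec_lo, dtype=np.float64)
    return FilterBank(
        analysis_low=l,
        analysis_high=_qmf(l_dual),
        synthesis_low=l_dual,
        synthesis_high=_qmf(l),
        spec=spec,
    )


def validate_bank(bank: FilterBank) -> dict:
    """Numeric residuals of every filter-bank identity (pure report).

    Keys always present: ``qmf_analysis`` / ``qmf_synthesis`` (recurrence
    residuals), ``dual_delta`` (shifted dual-orthogonality, exact for
    orthogonal banks too), ``cross_low_high``.  Orthogonal banks additionally
    report ``unit_energy`` (|sum l^2 - 1|) and ``dc_gain`` (|sum l - sqrt2|).
    The caller decides pass/fail; 1e-8 is the conventional gate.
    """
    l = bank.analysis_low
    h = bank.analysis_high
    lt = bank.synthesis_low
    ht = bank.synthesis_high
    L = len(l)
    shifts = range(-(L // 2) + 1, L // 2)

    def corr2(a, b, m):
        k = np.arange(L)
        valid = (k + 2 * m >= 0) & (k + 2 * m < L)
        return float(np.sum(a[k[valid]] * b[k[valid] + 2 * m]))

    dual_delta = max(
        abs(corr2(l, lt, m) - (1.0 if m == 0 else 0.0)) for m in shifts
    )
    cross = max(abs(corr2(h, lt, m)) for m in shifts)
    report = {
        "qmf_analysis": float(np.abs(h - _qmf(lt)).max()),
        "qmf_synthesis": float(np.abs(ht - _qmf(l)).max()),
        "dual_delta": float(dual_delta),
        "cross_low_high": float(cross),
    }
    if bank.spec.is_orthogonal:
        report["unit_energy"] = float(abs(np.sum(l * l) - 1.0))
        report["dc_gain"] = float(abs(np.sum(l) - np.sqrt(2.0)))
        report["qmf_cross_product"] = float(abs(np.sum(l * h)))
    return report


# ---------------------------------------------------------------------------
# Periodized analysis/synthesis as small dense matrices.  Feature-map sides
# are <= a few hundred, so the decimated circulant operators are cheap to
# materialise and the transform becomes two BLAS matmuls per subband; the
# same matrices double as the linear operator used for backpropagation.

_MATRIX_CACHE: dict = {}


def _analysis_matrix(filt: np.ndarray, n: int) -> np.ndarray:
    key = (filt.tobytes(), n)
    mat = _MATRIX_CACHE.get(key)
    if mat is None:
        mat = np.zeros((n // 2, n))
        for k in range(n // 2):
            for i, fi in enumerate(filt):
                mat[k, (2 * k + i) % n] += fi
        mat.setflags(write=False)
        _MATRIX_CACHE[key] = mat
    return mat


def analysis_matrices(bank: FilterBank, height: int, width: int):
    """(row_low, row_high, col_low, col_high) periodized operators."""
    return (
        _analysis_matrix(bank.analysis_low, width),
        _analysis_matrix(bank.analysis_high, width),
        _analysis_matrix(bank.analysis_low, height),
        _analysis_matrix(bank.analysis_high, height),
    )


def _check_input(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    if x.ndim < 2:
        raise ValueError(f"expected at least 2 dimensions (H, W), got shape {x.shape}")
    h, w = x.shape[-2], x.shape[-1]
    if h < 2 or w < 2 or h % 2 or w % 2:
        raise ValueError(f"spatial size {h}x{w} must be even in both axes")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    return x


def dwt2(x: np.ndarray, bank: FilterBank) -> SubbandSet:
    """Single-level periodized 2D DWT of a (..., H, W) array.

    Rows are filtered and decimated first (low and high pass), then columns,
    yielding the four subbands at half resolution per axis.  Leading axes
    (channels, batch) transform independently.
    """
    x = _check_input(x).astype(np.float64, copy=False)
    h, w = x.shape[-2], x.shape[-1]
    rl, rh, cl, ch = analysis_matrices(bank, h, w)
    row_low = x @ rl.T     # (..., H, W/2)
    row_high = x @ rh.T
    return SubbandSet(
        ll=cl @ row_low,
        lh=cl @ row_high,   # horizontal detail: row high-pass, column low-pass
        hl=ch @ row_low,    # vertical detail
        hh=ch @ row_high,   # diagonal detail
    )


def idwt2(subbands: SubbandSet, bank: FilterBank) -> np.ndarray:
    """Inverse of :func:`dwt2` (synthesis bank); exact reconstruction.

    Exists for verification (round-trip tests) and subband visualisation —
    the network itself discards the detail subbands.
    """
    ll = np.asarray(subbands.ll, dtype=np.float64)
    h2, w2 = ll.shape[-2], ll.shape[-1]
    sl_w = _analysis_matrix(bank.synthesis_low, 2 * w2)
    sh_w = _analysis_matrix(bank.synthesis_high, 2 * w2)
    sl_h = _analysis_matrix(bank.synthesis_low, 2 * h2)
    sh_h = _analysis_matrix(bank.synthesis_high, 2 * h2)
    row_low = sl_h.T @ ll + sh_h.T @ subbands.hl
    row_high = sl_h.T @ subbands.lh + sh_h.T @ subbands.hh
    return row_low @ sl_w + row_high @ sh_w


def wavelet_downsample(x: np.ndarray, bank: FilterBank) -> np.ndarray:
    """LL-only downsampling: keep the low-frequency subband, drop the rest.

    This is the network's pooling replacement — a linear, hence everywhere
    differentiable, operator mapping (..., H, W) to (..., H/2, W/2) with the
    channel count unchanged.  High-frequency detail (where additive
    high-frequency noise concentrates) is discarded.
    """
    x = _check_input(x).astype(np.float64, copy=False)
    h, w = x.shape[-2], x.shape[-1]
    rl, _, cl, _ = analysis_matrices(bank, h, w)
    return cl @ (x @ rl.T)


def render_subband_grid(image: np.ndarray, bank: FilterBank) -> np.ndarray:
    """Render the LL/LH/HL/HH decomposition as one 2x2 uint8 grid image.

    Each panel is min-max scaled independently (a flat panel renders as 0).
    Input is a single-channel (H, W) image.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 3 and image.shape[0] in (1, 3):
        image = image.mean(axis=0)
    if image.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {image.shape}")
    sb = dwt2(image, bank)

    def scale(panel):
        lo, hi = panel.min(), panel.max()
        if hi - lo < 1e-12:
            return np.zeros_like(panel, dtype=np.uint8)
        return np.round(255.0 * (panel - lo) / (hi - lo)).astype(np.uint8)

    top = np.concatenate([scale(sb.ll), scale(sb.lh)], axis=1)
    bottom = np.concatenate([scale(sb.hl), scale(sb.hh)], axis=1)
    return np.concatenate([top, bottom], axis=0)
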