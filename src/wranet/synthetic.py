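"""Synthetic pseudo-tumor segmentation data.

Generates grayscale (or RGB) images of bright, irregular lesion-like blobs —
randomly deformed ellipses with a soft radial intensity profile — on a dark,
smoothly textured background, plus configurable additive noise.  The blob
footprint defines the binary ground-truth mask.  Lesion diameters are drawn
from a configurable pixel range; three presets mirror the clinical size
strata (> 7 mm, 3-7 mm, < 3 mm) at a fixed documented scale of 2 px/mm on a
64 x 64 frame.

Everything is deterministic under the spec's seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "SIZE_PRESETS",
    "SyntheticSpec",
    "SegmentationSample",
    "generate_dataset",
    "add_noise",
    "write_dataset",
    "read_dataset",
]

#: Lesion-diameter presets in pixels at 2 px/mm: large > 7 mm, medium 3-7 mm,
#: small < 3 mm.  Ranges are clipped at 3 px so a lesion is always resolvable.
SIZE_PRESETS = {
    "large": (14.0, 24.0),
    "medium": (6.0, 14.0),
    "small": (3.0, 6.0),
}

NOISE_MODELS = ("none", "gaussian", "checkerboard", "salt_pepper")


@dataclass(frozen=True)
class SyntheticSpec:
    n_samples: int = 100
    image_size: int = 64
    channels: int = 1
    lesion_diameter_range: Tuple[float, float] = (8.0, 20.0)
    lesions_per_image: Tuple[int, int] = (1, 3)
    background_texture: float = 0.08
    noise_model: str = "gaussian"
    noise_magnitude: float = 0.03
    seed: int = 0
    allow_empty: bool = False

    def __post_init__(self):
        problems = []
        if self.n_samples < 1:
            problems.append("n_samples must be >= 1")
        if self.image_size < 16 or self.image_size % 16:
            problems.append("image_size must be a positive multiple of 16")
        if self.channels not in (1, 3):
            problems.append("channels must be 1 or 3")
        lo, hi = self.lesion_diameter_range
        if not (0 < lo <= hi < self.image_size / 2):
            problems.append("lesion_diameter_range must be positive and below image_size/2")
        nlo, nhi = self.lesions_per_image
        if not (0 <= nlo <= nhi):
            problems.append("lesions_per_image must be a non-decreasing pair of counts")
        if nhi == 0 and not self.allow_empty:
            problems.append("lesions_per_image (0, 0) requires allow_empty=True")
        if self.noise_model not in NOISE_MODELS:
            problems.append(f"noise_model must be one of {NOISE_MODELS}")
        if self.noise_magnitude < 0:
            problems.append("noise_magnitude must be >= 0")
        if self.background_texture < 0:
            problems.append("background_texture must be >= 0")
        if problems:
            raise ValueError("invalid SyntheticSpec: " + "; ".join(problems))

    @classmethod
    def preset(cls, stratum: str, **overrides) -> "SyntheticSpec":
        """Spec with the lesion-size range of one clinical stratum."""
        if stratum not in SIZE_PRESETS:
            raise ValueError(f"unknown stratum {stratum!r}; choose from {sorted(SIZE_PRESETS)}")
        return cls(lesion_diameter_range=SIZE_PRESETS[stratum], **overrides)


@dataclass(frozen=True)
class SegmentationSample:
    image: np.ndarray          # (C, H, W) float in [0, 1]
    mask: np.ndarray           # (H, W) uint8 in {0, 1}
    metadata: dict

    def __post_init__(self):
        if not np.all(np.isfinite(self.image)):
            raise ValueError("image contains non-finite values")
        if not np.all((self.mask == 0) | (self.mask == 1)):
            raise ValueError("mask must be binary")
        frac = float(self.mask.mean())
        if not self.metadata.get("allow_empty", False) and not 0.0 < frac < 0.5:
            raise ValueError(f"mask foreground fraction {frac:.3f} outside (0, 0.5)")


def _lesion_footprint(size: int, center, diameter: float, rng: np.random.Generator):
    """Boolean footprint of one deformed ellipse (sinusoidal boundary)."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dy, dx = yy - center[0], xx - center[1]
    theta = rng.uniform(0, 2 * np.pi)
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * dx + st * dy
    v = -st * dx + ct * dy
    ecc = rng.uniform(0.7, 1.3)
    a = diameter / 2.0 * ecc
    b = diameter / 2.0 / ecc
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    ang = np.arctan2(v / b, u / a)
    boundary = 1.0
    for k in (2, 3, 5):
        boundary = boundary + rng.uniform(0.0, 0.12) * np.sin(k * ang + rng.uniform(0, 2 * np.pi))
    return rho <= boundary, rho / np.maximum(boundary, 1e-9)


def _background(size: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    base = 0.15 + 0.05 * rng.uniform()
    texture = gaussian_filter(rng.normal(size=(size, size)), sigma=4.0)
    peak = max(np.abs(texture).max(), 1e-9)
    return base + amplitude * texture / peak


def add_noise(image: np.ndarray, model: str, magnitude: float,
              seed: Optional[int] = None) -> np.ndarray:
    """Additive (or, for salt-pepper, replacement) perturbation of an image.

    ``checkerboard`` adds the +/-magnitude Nyquist pattern — pure
    highest-frequency content that a Haar low-pass discards exactly.
    """
    image = np.asarray(image, dtype=np.float64)
    if model not in NOISE_MODELS:
        raise ValueError(f"unknown noise model {model!r}; choose from {NOISE_MODELS}")
    if magnitude == 0 or model == "none":
        return image.copy()
    rng = np.random.default_rng(seed)
    h, w = image.shape[-2], image.shape[-1]
    if model == "gaussian":
        return image + rng.normal(0.0, magnitude, image.shape)
    if model == "checkerboard":
        yy, xx = np.mgrid[0:h, 0:w]
        pattern = magnitude * (-1.0) ** (yy + xx)
        return image + pattern
    # salt_pepper: magnitude is the corruption rate
    out = image.copy()
    corrupt = rng.random(image.shape) < magnitude
    salt = rng.random(image.shape) < 0.5
    out[corrupt & salt] = 1.0
    out[corrupt & ~salt] = 0.0
    return out


def _render_sample(spec: SyntheticSpec, rng: np.random.Generator, index: int) -> SegmentationSample:
    size = spec.image_size
    n_lesions = int(rng.integers(spec.lesions_per_image[0], spec.lesions_per_image[1] + 1))
    image = _background(size, spec.background_texture, rng)
    mask = np.zeros((size, size), dtype=np.uint8)
    diameters = []
    margin = spec.lesion_diameter_range[1] / 2.0 + 2.0
    for _ in range(n_lesions):
        diameter = rng.uniform(*spec.lesion_diameter_range)
        center = rng.uniform(margin, size - margin, size=2)
        footprint, rho = _lesion_footprint(size, center, diameter, rng)
        if not footprint.any():
            continue
        brightness = rng.uniform(0.65, 0.9)
        profile = np.exp(-1.5 * rho ** 2)
        image = np.where(footprint, np.maximum(image, brightness * (0.55 + 0.45 * profile)), image)
        mask[footprint] = 1
        diameters.append(float(diameter))
    noise_seed = int(rng.integers(0, 2 ** 31))
    image = add_noise(image, spec.noise_model, spec.noise_magnitude, seed=noise_seed)
    image = np.clip(image, 0.0, 1.0)
    if spec.channels == 3:
        tint = np.array([1.0, rng.uniform(0.8, 1.0), rng.uniform(0.6, 0.9)])
        image = tint[:, None, None] * image[None]
    else:
        image = image[None]
    return SegmentationSample(
        image=image.astype(np.float64),
        mask=mask,
        metadata={
            "index": index,
            "lesion_count": len(diameters),
            "diameters_px": diameters,
            "noise_seed": noise_seed,
            "allow_empty": spec.allow_empty,
        },
    )


def generate_dataset(spec: SyntheticSpec) -> list:
    """Deterministic list of samples; resamples the rare degenerate draws.

    Unless ``allow_empty`` is set, every sample is guaranteed at least one
    lesion and a foreground fraction inside (0, 0.5).
    """
    rng = np.random.default_rng(spec.seed)
    samples = []
    for i in range(spec.n_samples):
        for _ in range(64):
            try:
                sub = replace(spec,
                              lesions_per_image=(max(spec.lesions_per_image[0],
                                                     0 if spec.allow_empty else 1),
                                                 max(spec.lesions_per_image[1],
                                                     0 if spec.allow_empty else 1)))
                samples.append(_render_sample(sub, rng, i))
                break
            except ValueError:
                continue
        else:
            raise RuntimeError("could not draw a valid sample; check the spec ranges")
    return samples


# ---------------------------------------------------------------------------
# Disk layout: images/ (16-bit grayscale or 8-bit RGB PNG), masks/ (8-bit
# {0,255} PNG), manifest.json with the spec and per-sample metadata.

def _to_png_array(image: np.ndarray):
    if image.shape[0] == 1:
        return np.round(image[0] * 65535.0).astype(np.uint16)
    return np.round(image.transpose(1, 2, 0) * 255.0).astype(np.uint8)


def _from_png_array(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 2:
        return (arr.astype(np.float64) / 65535.0)[None]
    return arr.astype(np.float64).transpose(2, 0, 1) / 255.0


def write_dataset(samples: Sequence[SegmentationSample], directory,
                  spec: Optional[SyntheticSpec] = None) -> dict:
    """Write PNG pairs plus a JSON manifest; returns the manifest."""
    directory = Path(directory)
    (directory / "images").mkdir(parents=True, exist_ok=True)
    (directory / "masks").mkdir(parents=True, exist_ok=True)
    entries = []
    for i, s in enumerate(samples):
        img_name, mask_name = f"sample_{i:05d}.png", f"sample_{i:05d}.png"
        arr = _to_png_array(s.image)
        Image.fromarray(arr).save(directory / "images" / img_name)
        Image.fromarray((s.mask * 255).astype(np.uint8)).save(
            directory / "masks" / mask_name)
        entries.append({"image": f"images/{img_name}", "mask": f"masks/{mask_name}",
                        "metadata": s.metadata})
    manifest = {
        "n_samples": len(entries),
        # normalise tuples to lists so the in-memory dict equals its JSON form
        "spec": json.loads(json.dumps(asdict(spec))) if spec is not None else None,
        "samples": entries,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_dataset(directory) -> list:
    """Read a dataset written by :func:`write_dataset` (lossless for masks)."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json under {directory}")
    manifest = json.loads(manifest_path.read_text())
    samples = []
    for entry in manifest["samples"]:
        try:
            img = np.asarray(Image.open(directory / entry["image"]))
            mask = np.asarray(Image.open(directory / entry["mask"]))
        except OSError as exc:
            raise OSError(f"failed reading sample under {directory}: {exc}") from exc
        samples.append(SegmentationSample(
            image=_from_png_array(img),
            mask=(mask >= 128).astype(np.uint8),
            metadata=dict(entry.get("metadata", {})),
        ))
    return samples
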