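"""Evaluation metrics for binary segmentation.

Dice, IoU, precision (PR) and sensitivity (SE) from hard masks, with the
confusion counts they derive from.  Conventions for degenerate images:
if ground truth and prediction are both empty all four metrics are 1 (the
prediction is perfect); if exactly one is empty they are all 0.

Per-image ("macro") averaging is the default — each image contributes
equally regardless of lesion size; ``average="micro"`` pools the confusion
counts over the whole set instead.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

__all__ = ["MetricsReport", "segmentation_metrics", "confusion_counts"]


@dataclass(frozen=True)
class MetricsReport:
    dice: float
    iou: float
    precision: float
    sensitivity: float
    tp: int
    fp: int
    fn: int
    tn: int
    n_images: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MetricsReport":
        return cls(**json.loads(text))


def confusion_counts(pred: np.ndarray, gt: np.ndarray):
    """(tp, fp, fn, tn) for one or more binarized masks."""
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if pred.shape != gt.shape:
        raise ValueError(f"prediction shape {pred.shape} != mask shape {gt.shape}")
    tp = int(np.sum(pred & gt))
    fp = int(np.sum(pred & ~gt))
    fn = int(np.sum(~pred & gt))
    tn = int(np.sum(~pred & ~gt))
    return tp, fp, fn, tn


def _from_counts(tp: int, fp: int, fn: int):
    if tp + fp + fn == 0:                     # both masks empty
        return 1.0, 1.0, 1.0, 1.0
    dice = 2.0 * tp / (2.0 * tp + fp + fn)
    iou = tp / (tp + fp + fn)
    pr = tp / (tp + fp) if tp + fp else 0.0
    se = tp / (tp + fn) if tp + fn else 0.0
    return dice, iou, pr, se


def segmentation_metrics(pred, gt, threshold: float = 0.5,
                         average: str = "macro") -> MetricsReport:
    """Dice/IoU/PR/SE of probability maps against binary ground truth.

    ``pred`` and ``gt`` are arrays of shape (H, W), (N, H, W) or
    (N, 1, H, W); probabilities are binarized at ``threshold``.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if average not in ("macro", "micro"):
        raise ValueError("average must be 'macro' or 'micro'")
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    if pred.ndim == 4 and pred.shape[1] == 1:
        pred = pred[:, 0]
    if gt.ndim == 4 and gt.shape[1] == 1:
        gt = gt[:, 0]
    if pred.ndim == 2:
        pred, gt = pred[None], gt[None]
    if pred.shape != gt.shape:
        raise ValueError(f"prediction shape {pred.shape} != mask shape {gt.shape}")

    hard = pred >= threshold
    gt_b = gt >= 0.5
    per_image = [confusion_counts(h, g) for h, g in zip(hard, gt_b)]
    tp, fp, fn, tn = (int(sum(c[i] for c in per_image)) for i in range(4))
    if average == "macro":
        scores = np.array([_from_counts(*c[:3]) for c in per_image])
        dice, iou, pr, se = scores.mean(axis=0)
    else:
        dice, iou, pr, se = _from_counts(tp, fp, fn)
    return MetricsReport(
        dice=float(dice), iou=float(iou), precision=float(pr),
        sensitivity=float(se), tp=tp, fp=fp, fn=fn, tn=tn,
        n_images=len(per_image),
    )
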