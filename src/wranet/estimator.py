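"""Scikit-learn style estimator wrapping the network and training loop.

``WRANetSegmenter`` is a binary image segmenter with the usual estimator
contract: constructor stores hyperparameters verbatim, :meth:`fit` learns
from ``(X, y)`` arrays, fitted state lives in trailing-underscore
attributes, and the object composes with sklearn model selection (KFold
cross-validation is exposed via :func:`crossvalidate`).

Inputs are image stacks: ``X`` of shape (n, H, W) or (n, C, H, W) with
values in [0, 1] and H, W divisible by ``2**depth`` (16 for the default
depth-4 network); ``y`` are binary masks of shape (n, H, W).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.model_selection import KFold

from .losses import LossConfig, bce_loss, dice_loss, hybrid_loss
from .metrics import MetricsReport, segmentation_metrics
from .network import NetworkConfig, WRANet, load_checkpoint, save_checkpoint

__all__ = ["WRANetSegmenter", "crossvalidate"]


class WRANetSegmenter(BaseEstimator):
    """Wavelet residual attention U-Net as a fit/predict estimator.

    Parameters mirror the published training setup: Adam with
    betas (0.9, 0.999), eps 1e-8, weight decay 5e-4, learning rate 1e-4,
    batch size 4, 200 epochs, hybrid 0.4*BCE + 0.6*Dice loss.  For the
    scaled-down CPU experiments in this repository, smaller ``base_channels``,
    fewer epochs and a larger learning rate are the intended overrides.
    """

    def __init__(self, in_channels: int = 1, base_channels: int = 64,
                 depth: int = 4, wavelet: str = "sym6",
                 downsample: str = "wavelet", use_attention: bool = True,
                 loss: str = "hybrid", alpha_weight: float = 0.4,
                 beta_weight: float = 0.6, lambda_smooth: float = 1.0,
                 learning_rate: float = 1e-4, batch_size: int = 4,
                 epochs: int = 200, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, weight_decay: float = 5e-4,
                 validation_fraction: float = 0.0, threshold: float = 0.5,
                 random_state=None, verbose: int = 0):
        self.in_channels = in_channels
        self.base_channels = base_channels
        self.depth = depth
        self.wavelet = wavelet
        self.downsample = downsample
        self.use_attention = use_attention
        self.loss = loss
        self.alpha_weight = alpha_weight
        self.beta_weight = beta_weight
        self.lambda_smooth = lambda_smooth
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.weight_decay = weight_decay
        self.validation_fraction = validation_fraction
        self.threshold = threshold
        self.random_state = random_state
        self.verbose = verbose

    # -- helpers ------------------------------------------------------------
    def _network_config(self) -> NetworkConfig:
        return NetworkConfig(
            in_channels=self.in_channels, base_channels=self.base_channels,
            depth=self.depth, wavelet=self.wavelet, downsample=self.downsample,
            use_attention=self.use_attention,
        )

    def _loss_config(self) -> LossConfig:
        return LossConfig(alpha_weight=self.alpha_weight,
                          beta_weight=self.beta_weight,
                          lambda_smooth=self.lambda_smooth)

    def _objective(self, p, y):
        if self.loss == "bce":
            return bce_loss(p, y)
        if self.loss == "dice":
            return dice_loss(p, y, self.lambda_smooth)
        if self.loss == "hybrid":
            return hybrid_loss(p, y, self._loss_config())
        raise ValueError("loss must be 'bce', 'dice' or 'hybrid'")

    @staticmethod
    def _coerce_X(X, in_channels: int) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 3:
            X = X[:, None]
        if X.ndim != 4 or X.shape[1] != in_channels:
            raise ValueError(
                f"X must have shape (n, H, W) or (n, {in_channels}, H, W), got {X.shape}")
        return X

    @staticmethod
    def _coerce_y(y, X: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=np.float64)
        if y.ndim == 4 and y.shape[1] == 1:
            y = y[:, 0]
        if y.shape != (X.shape[0], X.shape[2], X.shape[3]):
            raise ValueError(f"y must have shape (n, H, W) matching X, got {y.shape}")
        if not np.all((y == 0) | (y == 1)):
            raise ValueError("y must be a binary mask")
        return y

    # -- estimator API ------------------------------------------------------
    def fit(self, X, y):
        from .nn import Adam  # local import keeps module load light

        X = self._coerce_X(X, self.in_channels)
        y = self._coerce_y(y, X)
        if len(X) == 0:
            raise ValueError("cannot fit on an empty dataset")
        rng = np.random.default_rng(self.random_state)
        model = WRANet(self._network_config(), seed=int(rng.integers(0, 2 ** 31)))

        n_val = int(round(self.validation_fraction * len(X)))
        order = rng.permutation(len(X))
        val_idx, train_idx = order[:n_val], order[n_val:]
        if len(train_idx) == 0:
            raise ValueError("validation_fraction leaves no training samples")

        optimizer = Adam(model.parameters(), lr=self.learning_rate,
                         betas=(self.beta1, self.beta2), eps=self.eps,
                         weight_decay=self.weight_decay)
        history = {"train_loss": [], "val_dice": []}
        best = (-np.inf, None)
        for epoch in range(self.epochs):
            model.train()
            perm = rng.permutation(train_idx)
            losses = []
            for start in range(0, len(perm), self.batch_size):
                idx = perm[start:start + self.batch_size]
                prob = model(X[idx])[:, 0]
                loss = self._objective(prob, y[idx])
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}; lower the learning rate")
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
                losses.append(loss.item())
            history["train_loss"].append(float(np.mean(losses)))
            if n_val:
                prob = model.predict_proba(X[val_idx])
                report = segmentation_metrics(prob, y[val_idx], self.threshold)
                history["val_dice"].append(report.dice)
                if report.dice > best[0]:
                    best = (report.dice, {k: v.copy() for k, v in model.named_state().items()})
            if self.verbose:
                msg = f"epoch {epoch + 1}/{self.epochs} loss {history['train_loss'][-1]:.4f}"
                if n_val:
                    msg += f" val_dice {history['val_dice'][-1]:.4f}"
                print(msg)
        if best[1] is not None:
            model.load_state(best[1])
        self.model_ = model
        self.history_ = history
        self.config_ = model.config
        self.n_iter_ = self.epochs
        return self

    def predict_proba(self, X) -> np.ndarray:
        self._require_fitted()
        X = self._coerce_X(X, self.in_channels)
        return self.model_.predict_proba(X)

    def predict(self, X) -> np.ndarray:
        """Binary masks (n, H, W) thresholded at ``self.threshold``."""
        proba = self.predict_proba(X)
        return (proba[:, 0] >= self.threshold).astype(np.uint8)

    def score(self, X, y) -> float:
        """Mean per-image Dice coefficient on (X, y)."""
        return self.evaluate(X, y).dice

    def evaluate(self, X, y, average: str = "macro") -> MetricsReport:
        X = self._coerce_X(X, self.in_channels)
        y = self._coerce_y(y, X)
        return segmentation_metrics(self.predict_proba(X), y,
                                    self.threshold, average=average)

    def _require_fitted(self):
        if not hasattr(self, "model_"):
            raise AttributeError("estimator is not fitted; call fit() first")

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        self._require_fitted()
        save_checkpoint(self.model_, path)
        sidecar = Path(path).with_suffix(Path(path).suffix + ".json")
        meta = json.loads(sidecar.read_text())
        meta["estimator"] = self.get_params()
        meta["history"] = self.history_
        sidecar.write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "WRANetSegmenter":
        sidecar = Path(path).with_suffix(Path(path).suffix + ".json")
        meta = json.loads(sidecar.read_text())
        est = cls(**meta.get("estimator", {}))
        est.model_ = load_checkpoint(path)
        est.history_ = meta.get("history", {"train_loss": [], "val_dice": []})
        est.config_ = est.model_.config
        return est


def crossvalidate(estimator: WRANetSegmenter, X, y, cv_folds: int = 5,
                  random_state=0) -> dict:
    """Seeded k-fold cross-validation; per-fold reports plus mean +/- sd.

    Folds are disjoint and cover every sample exactly once.  Returns a dict
    with ``folds`` (list of MetricsReport), ``assignments`` (fold index per
    sample) and ``summary`` (mean/sd for each metric).
    """
    X = np.asarray(X)
    if cv_folds < 2 or cv_folds > len(X):
        raise ValueError(f"cv_folds must be in [2, n_samples]; got {cv_folds} "
                         f"for {len(X)} samples")
    splitter = KFold(n_splits=cv_folds, shuffle=True, random_state=random_state)
    reports, assignments = [], np.empty(len(X), dtype=int)
    for fold, (train_idx, test_idx) in enumerate(splitter.split(X)):
        assignments[test_idx] = fold
        est = estimator.__class__(**estimator.get_params())
        est.fit(X[train_idx], np.asarray(y)[train_idx])
        reports.append(est.evaluate(X[test_idx], np.asarray(y)[test_idx]))
    summary = {}
    for name in ("dice", "iou", "precision", "sensitivity"):
        vals = np.array([getattr(r, name) for r in reports])
        summary[name] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=0))}
    return {"folds": reports, "assignments": assignments.tolist(), "summary": summary}
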