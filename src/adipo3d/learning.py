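"""Optional trainable thresholding backend.

A lightweight, dependency-free stand-alone learner: a logistic pixel
classifier over multi-scale Gaussian intensity features, trained by
full-batch gradient descent on annotated 2D slices.  It mirrors the
two-round annotate/train protocol used by commercial deep-learning
segmenters — an initial round on first annotations, then a longer
refinement round on corrected/extended annotations — and fulfils the same
contract as classical :func:`adipo3d.segmentation.binarize`: given an
intensity volume it returns a hole-filled foreground mask.

It is a simple linear classifier, not a deep network; it exists so the
trainable code path (scheduling, loss logging, prediction contract) is
exercised end to end.  The classical backend remains the default and is
the one used everywhere results matter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .volumes import AdipoError, ParameterError

logger = logging.getLogger(__name__)

__all__ = ["TrainingRound", "TrainableSegmenter", "TrainingError", "train_backend"]

DEFAULT_SCHEDULE = (200, 1500)  # iterations of the two training rounds
FEATURE_SIGMAS = (0.0, 1.0, 2.0, 4.0)


class TrainingError(AdipoError):
    """Training cannot proceed (empty schedule, missing annotations...)."""


@dataclass
class TrainingRound:
    """One round: annotated slices plus an iteration budget."""

    images: list[np.ndarray]
    labels: list[np.ndarray]
    iterations: int

    def validate(self) -> None:
        if self.iterations < 0:
            raise ParameterError("iterations must be >= 0")
        if len(self.images) != len(self.labels) or not self.images:
            raise TrainingError("each round needs matching non-empty image/label lists")
        for im, lb in zip(self.images, self.labels):
            if im.shape != lb.shape:
                raise TrainingError(f"image/label shape mismatch: {im.shape} vs {lb.shape}")


def _slice_features(img: np.ndarray) -> np.ndarray:
    """(n_pixels, n_features) multi-scale Gaussian features of one slice."""
    img = np.asarray(img, dtype=float)
    feats = [img if s == 0 else ndi.gaussian_filter(img, s) for s in FEATURE_SIGMAS]
    feats.append(ndi.gaussian_gradient_magnitude(img, 1.0))
    return np.stack([f.ravel() for f in feats], axis=1)


@dataclass
class TrainableSegmenter:
    """Logistic pixel classifier over multi-scale intensity features."""

    learning_rate: float = 1.0
    weights_: np.ndarray | None = field(default=None, repr=False)
    bias_: float = 0.0
    feat_mean_: np.ndarray | None = field(default=None, repr=False)
    feat_std_: np.ndarray | None = field(default=None, repr=False)
    loss_log_: list = field(default_factory=list, repr=False)

    def fit(self, rounds: list[TrainingRound]) -> "TrainableSegmenter":
        """Run the multi-round training schedule, logging loss per iteration.

        Raises :class:`TrainingError` if the total iteration budget is zero.
        """
        if not rounds:
            raise TrainingError("no training rounds given")
        for r in rounds:
            r.validate()
        if sum(r.iterations for r in rounds) <= 0:
            raise TrainingError("training schedule has zero total iterations")

        self.loss_log_ = []
        for round_idx, rnd in enumerate(rounds):
            X = np.concatenate([_slice_features(im) for im in rnd.images], axis=0)
            y = np.concatenate([np.asarray(lb, dtype=bool).ravel() for lb in rnd.labels])
            if round_idx == 0 or self.feat_mean_ is None:
                self.feat_mean_ = X.mean(axis=0)
                self.feat_std_ = X.std(axis=0) + 1e-12
            Xs = (X - self.feat_mean_) / self.feat_std_
            if self.weights_ is None:
                self.weights_ = np.zeros(Xs.shape[1])
                self.bias_ = 0.0
            self._gd(Xs, y.astype(float), rnd.iterations, round_idx)
        return self

    def _gd(self, X: np.ndarray, y: np.ndarray, iterations: int, round_idx: int) -> None:
        w, b = self.weights_, self.bias_
        n = len(y)
        for it in range(iterations):
            z = X @ w + b
            p = 1.0 / (1.0 + np.exp(-z))
            eps = 1e-12
            loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
            self.loss_log_.append({"round": round_idx, "iteration": it, "loss": float(loss)})
            grad = (p - y) / n
            w = w - self.learning_rate * (X.T @ grad)
            b = b - self.learning_rate * grad.sum()
        self.weights_, self.bias_ = w, b

    def predict_proba_slice(self, img: np.ndarray) -> np.ndarray:
        if self.weights_ is None:
            raise TrainingError("segmenter is not trained")
        Xs = (_slice_features(img) - self.feat_mean_) / self.feat_std_
        z = Xs @ self.weights_ + self.bias_
        return (1.0 / (1.0 + np.exp(-z))).reshape(np.asarray(img).shape)

    def predict_mask(self, volume: np.ndarray) -> np.ndarray:
        """Foreground mask for a 2D slice or 3D (z, y, x) volume.

        Same contract as the classical ``binarize``: boolean grid aligned
        to the input with enclosed holes filled.
        """
        volume = np.asarray(volume)
        if volume.ndim == 2:
            mask = self.predict_proba_slice(volume) > 0.5
        elif volume.ndim == 3:
            mask = np.stack([self.predict_proba_slice(sl) > 0.5 for sl in volume])
        else:
            raise ParameterError(f"expected 2D or 3D input, got ndim={volume.ndim}")
        return ndi.binary_fill_holes(mask)

    @property
    def initial_loss(self) -> float:
        if not self.loss_log_:
            raise TrainingError("no training has been logged")
        return self.loss_log_[0]["loss"]

    @property
    def final_loss(self) -> float:
        if not self.loss_log_:
            raise TrainingError("no training has been logged")
        return self.loss_log_[-1]["loss"]


def train_backend(
    phantom,
    schedule: tuple[int, int] = DEFAULT_SCHEDULE,
    n_round1_slices: int = 3,
    n_round2_slices: int = 9,
    average_window: int = 5,
) -> TrainableSegmenter:
    """Train the backend on slices of a phantom with its ground-truth labels.

    Round 1 uses a few z-averaged slices (initial annotations), round 2 a
    larger corrected set, following the two-round protocol.  Slice windows
    are averaged with :func:`adipo3d.segmentation.zstack_average`.
    """
    from .segmentation import zstack_average

    lipid = phantom.image.channel("lipid")
    gt = phantom.labels.data > 0
    depth = lipid.shape[0]
    window = min(average_window, depth)
    averaged = zstack_average(lipid, window)
    gt_mid = gt[window // 2 : window // 2 + averaged.shape[0]]

    def pick(n):
        idx = np.linspace(0, averaged.shape[0] - 1, num=min(n, averaged.shape[0]), dtype=int)
        return [averaged[i] for i in idx], [gt_mid[i] for i in idx]

    im1, lb1 = pick(n_round1_slices)
    im2, lb2 = pick(n_round2_slices)
    rounds = [
        TrainingRound(im1, lb1, schedule[0]),
        TrainingRound(im2, lb2, schedule[1]),
    ]
    model = TrainableSegmenter().fit(rounds)
    logger.info(
        "trainable backend: loss %.4g -> %.4g over %d iterations",
        model.initial_loss, model.final_loss, len(model.loss_log_),
    )
    return model
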