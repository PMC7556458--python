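"""Preprocessing, augmentation, multi-readout loss and the training loop.

The recipe mirrors the full-scale study: images are cropped (a random crop
covering at least one third of the image area during training, a centre crop
for evaluation), randomly flipped left-right, lightly jittered in brightness,
saturation and contrast, resized, and rescaled from [0, 1] to [-1, 1].
Optimisation uses Adam (learning rate 0.005, epsilon 0.1) on the mean over
readouts of the cross-entropy, with L2 regularisation coefficient 1e-6 and a
constant learning-rate schedule.  Defaults for epochs (90) and batch size
(100) correspond to the full-scale recipe and are overridden at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nn, network
from .specs import ArchitectureSpec


@dataclass
class TrainConfig:
    epochs: int = 90
    batch_size: int = 100
    learning_rate: float = 0.005
    adam_epsilon: float = 0.1
    l2_coefficient: float = 1e-6
    seed: int = 0
    augment: bool = True
    #: inputs already cropped/scaled to [-1, 1]; skip preprocessing entirely
    preprocessed: bool = False

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size) < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")


def _resize(image: np.ndarray, target: int) -> np.ndarray:
    """Bilinear resize to (target, target); plain numpy, channels last."""
    h, w = image.shape[:2]
    if (h, w) == (target, target):
        return image
    ys = np.linspace(0, h - 1, target)
    xs = np.linspace(0, w - 1, target)
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    wy = (ys - y0)[:, None, None]
    wx = (xs - x0)[None, :, None]
    a = image[np.ix_(y0, x0)]
    b = image[np.ix_(y0, x1)]
    c = image[np.ix_(y1, x0)]
    d = image[np.ix_(y1, x1)]
    return (a * (1 - wy) * (1 - wx) + b * (1 - wy) * wx
            + c * wy * (1 - wx) + d * wy * wx)


def preprocess(
    image: np.ndarray,
    phase: str,
    target_size: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Crop, augment (training only), resize and rescale one image.

    ``image`` is (H, W, C) with values in [0, 1]; output is
    (target_size, target_size, C) in [-1, 1].  Training crops cover at least
    one third of the image area with aspect ratio in [3/4, 4/3]; evaluation
    takes a centre crop.  Jitter: brightness +-0.1, saturation and contrast
    scaled by factors in [0.9, 1.1].
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape[:2]
    if h < 2 or w < 2:
        raise ValueError("image smaller than 2x2")
    if img.min() < -1e-9 or img.max() > 1 + 1e-9:
        raise ValueError("input pixel values must lie in [0, 1]")

    if phase == "eval":
        side = min(h, w)
        top, left = (h - side) // 2, (w - side) // 2
        crop = img[top:top + side, left:left + side]
    elif phase == "train":
        if rng is None:
            raise ValueError("training preprocessing needs an rng")
        area = h * w
        for _ in range(10):
            frac = rng.uniform(1.0 / 3.0, 1.0)
            aspect = rng.uniform(3.0 / 4.0, 4.0 / 3.0)
            ch = int(round(np.sqrt(frac * area / aspect)))
            cw = int(round(np.sqrt(frac * area * aspect)))
            if 1 <= ch <= h and 1 <= cw <= w:
                break
        else:
            ch = cw = min(h, w)
        top = rng.integers(0, h - ch + 1)
        left = rng.integers(0, w - cw + 1)
        crop = img[top:top + ch, left:left + cw]
        if rng.random() < 0.5:
            crop = crop[:, ::-1]
        crop = crop + rng.uniform(-0.1, 0.1)  # brightness
        grey = crop.mean(axis=-1, keepdims=True)
        crop = grey + rng.uniform(0.9, 1.1) * (crop - grey)  # saturation
        crop = crop.mean() + rng.uniform(0.9, 1.1) * (crop - crop.mean())  # contrast
        crop = np.clip(crop, 0.0, 1.0)
    else:
        raise ValueError(f"unknown phase {phase!r}")

    out = _resize(crop, target_size)
    return 2.0 * out - 1.0


def multi_readout_loss(probs: np.ndarray, labels: Sequence[int]) -> float:
    """Mean over readouts of the batch-mean cross-entropy.

    ``probs`` is (N, T, C) of per-step softmax readouts; with T=1 this is
    ordinary cross-entropy.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    if labels.max() >= probs.shape[2] or labels.min() < 0:
        raise ValueError("label outside class range")
    n, T = probs.shape[:2]
    picked = probs[np.arange(n)[:, None], np.arange(T)[None, :], labels[:, None]]
    return float(-np.log(np.clip(picked, 1e-12, None)).mean())


def accuracy_per_step(probs: np.ndarray, labels: np.ndarray, *, cumulative: bool = True):
    """Top-1 accuracy at every readout, instantaneous or cumulative."""
    if cumulative:
        T = probs.shape[1]
        probs = np.cumsum(probs, axis=1) / np.arange(1, T + 1)[None, :, None]
    preds = probs.argmax(axis=2)
    return (preds == np.asarray(labels)[:, None]).mean(axis=0)


def train(
    spec: ArchitectureSpec,
    data: tuple,
    config: TrainConfig,
) -> tuple[network.ModelParams, list[dict]]:
    """Train a network; fully reproducible given ``config.seed``.

    ``data`` is (X_train, y_train, X_val, y_val); validation arrays may be
    None.  Images are either raw in [0, 1] (preprocessing applied here) or
    already in [-1, 1] when ``config.preprocessed`` is set.  Returns the
    trained parameters and a per-epoch log of loss and accuracy.  Raises
    ``FloatingPointError`` naming the epoch if the loss diverges to NaN.
    """
    X_train, y_train, X_val, y_val = data
    rng = np.random.default_rng(config.seed)
    model = network.init_params(spec, rng)
    opt = nn.Adam(lr=config.learning_rate, eps=config.adam_epsilon)
    target = spec.input_size[0]

    def prep_eval(X):
        if config.preprocessed:
            return np.asarray(X, dtype=float)
        return np.stack([preprocess(im, "eval", target) for im in X])

    X_val_p = prep_eval(X_val) if X_val is not None else None
    n = len(X_train)
    log: list[dict] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss, seen = 0.0, 0
        correct = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            if config.preprocessed:
                xb = np.asarray(X_train[idx], dtype=float)
            elif config.augment:
                xb = np.stack([preprocess(X_train[i], "train", target, rng) for i in idx])
            else:
                xb = np.stack([preprocess(X_train[i], "eval", target) for i in idx])
            yb = np.asarray(y_train)[idx]
            loss, grads, probs = network.loss_and_grads(
                spec, model, xb, yb, l2=config.l2_coefficient
            )
            if not np.isfinite(loss):
                raise FloatingPointError(f"loss diverged (NaN/inf) at epoch {epoch + 1}")
            opt.step(model.params, grads)
            epoch_loss += loss * len(idx)
            seen += len(idx)
            cum_final = probs.mean(axis=1)
            correct += int((cum_final.argmax(axis=1) == yb).sum())
        entry = {
            "epoch": epoch + 1,
            "train_loss": epoch_loss / seen,
            "train_accuracy": correct / seen,
        }
        if X_val_p is not None:
            val_probs = network.forward(spec, model, X_val_p, training=False)
            entry["val_loss"] = multi_readout_loss(val_probs, y_val)
            acc = accuracy_per_step(val_probs, y_val, cumulative=True)
            entry["val_accuracy"] = float(acc[-1])
            entry["val_accuracy_per_step"] = [float(a) for a in acc]
        log.append(entry)
    return model, log
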