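"""Synthetic study data: an image task with graded difficulty and
subject x image reaction-time matrices with a planted entropy threshold.

The image task stands in for a large-scale recognition dataset: each class
has a procedurally drawn prototype (a distinct shape and colour), and every
image is the prototype corrupted by additive Gaussian pixel noise whose
standard deviation - the image's *difficulty* - is drawn uniformly from
[0, sigma_max].  Harder images carry more noise, so entropy-threshold
reaction times vary across images.  Classes are split into a binary
super-category partition (the analogue of animate/inanimate).

Synthetic subjects emulate a binary categorisation experiment: a reference
model decides at the site where its readout entropy first falls below a
planted threshold theta*, and each subject's reaction time for an image is an
affine transform of that site index (per-subject gain and offset) plus
Gaussian trial noise, averaged over repeated presentations.  Defaults mirror
a 20-subject, 96-image, 6-repeat design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rt import LN2, RTMatrix, network_rt


# ------------------------------------------------------------- image task

@dataclass(frozen=True)
class SyntheticTaskConfig:
    n_classes: int = 10
    image_size: int = 32
    n_train_per_class: int = 40
    n_val_per_class: int = 10
    sigma_max: float = 0.8
    supercategory_map: tuple | None = None  # class -> {0, 1}
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.image_size < 8:
            raise ValueError("image_size too small to draw prototypes (< 8)")
        smap = self.supercategory_map
        if smap is None:
            smap = tuple(0 if c < self.n_classes // 2 else 1 for c in range(self.n_classes))
            object.__setattr__(self, "supercategory_map", smap)
        if len(smap) != self.n_classes or len(set(smap)) < 2:
            raise ValueError("supercategory partition must cover all classes and be non-trivial")


@dataclass
class SyntheticDataset:
    images: np.ndarray  # (N, H, W, 3) in [0, 1]
    labels: np.ndarray
    superlabels: np.ndarray
    difficulty: np.ndarray
    split: np.ndarray  # "train" / "val" per image
    prototypes: np.ndarray  # (n_classes, H, W, 3)

    def subset(self, which: str):
        m = self.split == which
        return self.images[m], self.labels[m], self.superlabels[m], self.difficulty[m]


_PALETTE = np.array([
    (0.9, 0.2, 0.2), (0.2, 0.7, 0.3), (0.25, 0.4, 0.9), (0.9, 0.8, 0.2),
    (0.8, 0.3, 0.8), (0.2, 0.8, 0.8), (0.95, 0.55, 0.15), (0.55, 0.35, 0.2),
    (0.6, 0.9, 0.3), (0.5, 0.5, 0.95), (0.9, 0.4, 0.6), (0.4, 0.9, 0.7),
])


def _shape_mask(shape_index: int, size: int) -> np.ndarray:
    """One of 12 procedural shapes on a size x size canvas."""
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2.0
    r = size / 3.0
    d = np.hypot(yy - c, xx - c)
    k = shape_index % 12
    if k == 0:
        return d <= r
    if k == 1:
        return (np.abs(yy - c) <= r * 0.8) & (np.abs(xx - c) <= r * 0.8)
    if k == 2:
        return (d <= r) & (d >= r * 0.55)
    if k == 3:
        return (np.abs(yy - c) <= size / 10) | (np.abs(xx - c) <= size / 10)
    if k == 4:
        return (yy >= c - r) & (np.abs(xx - c) <= (yy - (c - r)) / 2)
    if k == 5:
        return np.abs(yy - c) <= size / 8
    if k == 6:
        return np.abs(xx - c) <= size / 8
    if k == 7:
        return np.abs((yy - c) - (xx - c)) <= size / 8
    if k == 8:
        return ((yy // max(size // 8, 1) + xx // max(size // 8, 1)) % 2 == 0) & (d <= r * 1.2)
    if k == 9:
        return (np.abs(yy - c) + np.abs(xx - c)) <= r
    if k == 10:
        return np.abs((yy - c) + (xx - c)) <= size / 8
    return (d <= r) & ~((np.abs(yy - c) <= size / 10) & (np.abs(xx - c) <= size / 10))


def class_prototype(class_index: int, size: int) -> np.ndarray:
    """Deterministic prototype image for one class: shape + colour on grey."""
    mask = _shape_mask(class_index, size)
    colour = _PALETTE[class_index % len(_PALETTE)]
    img = np.full((size, size, 3), 0.5)
    img[mask] = colour
    return img


def generate_images(config: SyntheticTaskConfig) -> SyntheticDataset:
    """Draw the synthetic recognition dataset; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    size = config.image_size
    protos = np.stack([class_prototype(c, size) for c in range(config.n_classes)])
    images, labels, supers, diffs, split = [], [], [], [], []
    for which, n_per in (("train", config.n_train_per_class), ("val", config.n_val_per_class)):
        for c in range(config.n_classes):
            sigma = rng.uniform(0.0, config.sigma_max, size=n_per)
            for s in sigma:
                noisy = np.clip(protos[c] + rng.normal(0.0, s, protos[c].shape), 0.0, 1.0)
                images.append(noisy)
                labels.append(c)
                supers.append(config.supercategory_map[c])
                diffs.append(s)
                split.append(which)
    order = rng.permutation(len(images))
    return SyntheticDataset(
        images=np.stack(images)[order],
        labels=np.asarray(labels)[order],
        superlabels=np.asarray(supers)[order],
        difficulty=np.asarray(diffs)[order],
        split=np.asarray(split)[order],
        prototypes=protos,
    )


def nearest_prototype_accuracy(ds: SyntheticDataset, which: str = "val") -> float:
    """Accuracy of the fixed nearest-prototype reference classifier."""
    X, y, _, _ = ds.subset(which)
    flat = X.reshape(len(X), -1)
    pf = ds.prototypes.reshape(len(ds.prototypes), -1)
    d2 = ((flat[:, None, :] - pf[None, :, :]) ** 2).sum(axis=2)
    return float((d2.argmin(axis=1) == y).mean())


# -------------------------------------------------------------- subjects

@dataclass(frozen=True)
class SyntheticSubjectConfig:
    n_subjects: int = 20
    n_images: int = 96
    planted_threshold: float = 0.35  # theta* in (0, ln 2), nats
    gain_mean: float = 100.0  # ms per site index
    gain_sd: float = 15.0
    offset_mean: float = 450.0  # ms
    offset_sd: float = 50.0
    trial_noise_sd: float = 80.0  # ms, per presentation
    repeats_per_image: int = 6
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.planted_threshold < LN2:
            raise ValueError("planted_threshold must lie in (0, ln 2)")
        if self.n_subjects < 2 or self.n_images < 3:
            raise ValueError("need at least 2 subjects and 3 images")


def generate_entropy_trajectories(
    n_images: int = 96,
    n_sites: int = 8,
    seed: int = 0,
    n_seeds_averaged: int = 10,
) -> np.ndarray:
    """Per-image binary-readout entropy trajectories from a reference model.

    Emulates the averaged sigmoid outputs of a trained binary readout: each
    image has a latent difficulty governing how quickly evidence accumulates
    across sites; outputs drift from 0.5 toward a confident value, with small
    site-level jitter averaged over ``n_seeds_averaged`` model seeds.
    Returns (n_images, n_sites) entropies in nats, non-increasing in
    tendency but not strictly monotone (as in real readouts).
    """
    from .rt import binary_entropy

    rng = np.random.default_rng(seed)
    rate = rng.uniform(0.15, 1.2, size=n_images)  # evidence per site
    ys = np.zeros((n_images, n_sites))
    sites = np.arange(1, n_sites + 1)
    for _ in range(n_seeds_averaged):
        drift = rate[:, None] * sites[None, :] + rng.normal(0, 0.15, (n_images, n_sites))
        ys += 1.0 / (1.0 + np.exp(-drift))
    ys /= n_seeds_averaged
    return binary_entropy(ys)


def generate_subject_rts(
    entropies: np.ndarray,
    config: SyntheticSubjectConfig,
    *,
    return_repeats: bool = False,
):
    """Subject x image reaction times from a planted entropy threshold.

    Each subject s responds to image i in ``gain_s * site(theta*, i) +
    offset_s`` milliseconds plus Gaussian trial noise, averaged over
    ``repeats_per_image`` presentations.
    """
    ent = np.asarray(entropies, dtype=float)
    if ent.shape[0] != config.n_images:
        raise ValueError("entropy trajectories must cover n_images images")
    rng = np.random.default_rng(config.seed)
    sites = network_rt(ent, config.planted_threshold).astype(float)  # (n_images,)
    gains = rng.normal(config.gain_mean, config.gain_sd, config.n_subjects)
    gains = np.clip(gains, config.gain_mean * 0.2, None)  # keep RTs increasing in site
    offsets = rng.normal(config.offset_mean, config.offset_sd, config.n_subjects)
    base = gains[:, None] * sites[None, :] + offsets[:, None]
    repeats = base[:, :, None] + rng.normal(
        0.0, config.trial_noise_sd, (config.n_subjects, config.n_images, config.repeats_per_image)
    )
    values = repeats.mean(axis=2)
    values = np.clip(values, 1.0, None)  # reaction times are positive
    matrix = RTMatrix(values=values)
    if return_repeats:
        return matrix, repeats
    return matrix
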