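"""Training loop for the density regressor.

The loss is a pixelwise mean squared error between the network output
and the density target scaled up by a factor m (default 1000); the
scaling improves regression convergence and is divided out at inference.
Both image and target are reflection-padded before the forward pass, but
mirrored pixels are excluded from the loss so border artifacts do not
propagate into the fit. Augmentation applies one of the eight dihedral
transforms to image and target jointly (the target integral is exactly
preserved) plus per-pixel multiplicative intensity noise to the image
only. Training sets are optionally resampled so the manual-count
histogram is approximately uniform, reducing the regression-to-the-mean
bias on images with unusually few or many axons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .density import AnnotationSet, blur, integrate, rasterize, resize_with_points
from .model import mirror_pad, normalize
from .nn import Adam, UNet

__all__ = [
    "TrainingConfig",
    "TrainingSample",
    "loss",
    "augment",
    "resample_uniform",
    "build_training_samples",
    "train",
]


@dataclass
class TrainingConfig:
    epochs: int = 25
    batch_size: int = 1
    learning_rate: float = 1e-4
    m: float = 1000.0  # density scaling factor
    pad_px: int = 16
    resample_bins: int = 10
    resample: bool = True
    augment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise ValueError("density scaling factor m must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size != 1:
            raise ValueError("only batch size 1 is supported")


@dataclass(eq=False)  # identity equality: ndarray fields
class TrainingSample:
    """One image with its density target, at multiple-of-16 resolution."""

    image: np.ndarray  # raw grayscale (H, W)
    target: np.ndarray  # density map (H, W), integral = mean manual count
    count: float  # mean manual count, used for resampling bins
    sample_id: str = ""


def loss(
    prediction: np.ndarray, target: np.ndarray, mask: np.ndarray, m: float
) -> float:
    """Mean over masked (non-mirrored) pixels of (pred - m*target)^2."""
    if prediction.shape != target.shape or prediction.shape != mask.shape:
        raise ValueError("prediction, target and mask shapes must match")
    diff = (prediction - m * target)[mask]
    return float(np.mean(diff**2))


_DIHEDRAL = 8  # 4 rotations x optional transpose-flip


def _apply_dihedral(arr: np.ndarray, idx: int) -> np.ndarray:
    out = np.rot90(arr, idx % 4)
    if idx >= 4:
        out = out[::-1]
    return np.ascontiguousarray(out)


def augment(
    image: np.ndarray,
    target: np.ndarray,
    rng: np.random.Generator,
    transform: int | None = None,
    noise: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Jointly transform an (image, target) pair for augmentation.

    ``transform`` selects one of the 8 dihedral operations (0 is the
    identity); if None it is drawn uniformly. Multiplicative per-pixel
    noise, uniform in [0.85, 1.15], is applied to the image only.
    """
    if image.shape != target.shape:
        raise ValueError("image and target must share a shape")
    if image.shape[0] != image.shape[1]:
        raise ValueError("dihedral augmentation requires square images")
    idx = int(rng.integers(_DIHEDRAL)) if transform is None else int(transform)
    img = _apply_dihedral(image, idx)
    tgt = _apply_dihedral(target, idx)
    if noise:
        img = img * rng.uniform(0.85, 1.15, img.shape)
    return img, tgt


def resample_uniform(
    samples: Sequence[TrainingSample], n_bins: int = 10
) -> list[TrainingSample]:
    """Flatten the count histogram by whole-image replication.

    Images in each nonempty count bin are replicated round(max/size)
    times so every bin is within one whole replication of the fullest;
    all originals are retained and empty bins are skipped.
    """
    samples = list(samples)
    if not samples:
        return samples
    counts = np.array([s.count for s in samples], dtype=float)
    lo, hi = counts.min(), counts.max()
    if hi == lo:
        return samples
    edges = np.linspace(lo, hi, n_bins + 1)
    bins = np.clip(np.digitize(counts, edges[1:-1]), 0, n_bins - 1)
    sizes = np.bincount(bins, minlength=n_bins)
    largest = sizes.max()
    out: list[TrainingSample] = []
    for s, b in zip(samples, bins):
        factor = int(np.floor(largest / sizes[b] + 0.5))  # round half up
        out.extend([s] * max(1, factor))
    return out


def build_training_samples(
    records: Sequence, target_multiple: int = 16
) -> list[TrainingSample]:
    """Resize images to multiple-of-16 sides and build density targets.

    Density maps are constructed from the rescaled points at the resized
    resolution (never by interpolating a density map, which would not
    conserve counts).
    """
    out = []
    for i, rec in enumerate(records):
        img, anns = resize_with_points(
            rec.image.pixels, rec.annotations, target_multiple
        )
        matrix = rasterize(anns, img.shape)
        target = blur(matrix).values
        out.append(
            TrainingSample(
                image=img, target=target, count=matrix.total, sample_id=f"rec_{i:05d}"
            )
        )
    return out


def _step_forward(model: UNet, sample_img: np.ndarray, sample_tgt: np.ndarray,
                  pad_px: int, m: float):
    img_p, mask = mirror_pad(sample_img, pad_px)
    tgt_p, _ = mirror_pad(sample_tgt, pad_px)
    pred = model.forward(img_p)
    nmask = mask.sum()
    diff = np.where(mask, pred - m * tgt_p, 0.0)
    step_loss = float((diff[mask] ** 2).mean())
    return pred, diff, nmask, step_loss


def validation_loss(model: UNet, samples: Sequence[TrainingSample],
                    config: TrainingConfig) -> float:
    """Masked MSE on un-augmented samples, same padding as training."""
    total = 0.0
    for s in samples:
        _, _, _, l = _step_forward(model, normalize(s.image), s.target,
                                   config.pad_px, config.m)
        total += l
    return total / max(1, len(samples))


def train(
    model: UNet,
    samples: Sequence[TrainingSample],
    config: TrainingConfig,
    val_samples: Sequence[TrainingSample] = (),
    early_stop: Callable[[int, pd.DataFrame], bool] | None = None,
) -> pd.DataFrame:
    """Train in place; returns the per-epoch loss history.

    One epoch is a full shuffled pass over the (optionally resampled)
    training multiset, one image per optimizer step. A non-finite loss
    aborts with a diagnostic. ``early_stop(epoch, history)`` may end
    training after any epoch.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("training set is empty")
    expanded = (
        resample_uniform(samples, config.resample_bins) if config.resample else samples
    )
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params, lr=config.learning_rate)
    history: list[dict] = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(expanded))
        epoch_loss = 0.0
        for j in order:
            s = expanded[j]
            img = normalize(s.image)
            tgt = s.target
            if config.augment:
                img, tgt = augment(img, tgt, rng)
            pred, diff, nmask, step_loss = _step_forward(
                model, img, tgt, config.pad_px, config.m
            )
            if not np.isfinite(step_loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, sample {s.sample_id!r}; "
                    "try a lower learning rate"
                )
            epoch_loss += step_loss
            model.zero_grad()
            model.backward((2.0 / nmask) * diff)
            opt.step()
        row = {"epoch": epoch, "train_loss": epoch_loss / len(expanded)}
        if len(val_samples):
            row["val_loss"] = validation_loss(model, val_samples, config)
        history.append(row)
        if early_stop is not None and early_stop(epoch, pd.DataFrame(history)):
            break
    return pd.DataFrame(history)
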