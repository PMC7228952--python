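"""Architecture specification and the image-side contracts of the regressor.

The network consumes images normalized so that intensities within two
standard deviations of the image mean land in [-1, 1] (outliers clipped),
and is evaluated on reflection-padded inputs so border axons see valid
context; the padding is mirrored without repeating the edge pixel, and a
mask marks the original (non-mirrored) region for the training loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .nn import UNet

__all__ = ["UNetSpec", "normalize", "mirror_pad", "build", "save_model", "load_model"]


@dataclass
class UNetSpec:
    """Half-width U-Net hyperparameters.

    ``base_filters=32`` halves the original architecture's width at every
    level while keeping the base-two filter progression; ``depth=4``
    max-pooling levels mean input sides must be divisible by 16. The
    decoder uses 2x2 stride-2 transposed convolutions (pinned here so the
    architecture is reproducible from the spec alone).
    """

    depth: int = 4
    base_filters: int = 32
    in_channels: int = 1
    upsample: str = "transposed_conv"
    seed: int = 0

    @property
    def size_multiple(self) -> int:
        return 2**self.depth


def normalize(image: np.ndarray) -> np.ndarray:
    """Map an image to [-1, 1]: (x - mean) / (2*SD), clipped.

    A constant image (zero variance) maps to all zeros.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.size == 0:
        raise ValueError("image must be nonempty")
    sd = img.std()
    if sd == 0:
        return np.zeros_like(img)
    return np.clip((img - img.mean()) / (2.0 * sd), -1.0, 1.0)


def mirror_pad(image: np.ndarray, pad_px: int = 16) -> tuple[np.ndarray, np.ndarray]:
    """Reflect ``pad_px`` pixels on every side (edge pixel not repeated).

    Returns the padded image and a boolean mask that is True on the
    original region; the training loss is evaluated only where the mask
    is True. A 192x192 image padded by 16 becomes 224x224.
    """
    if pad_px < 0:
        raise ValueError("pad_px must be nonnegative")
    h, w = image.shape
    if pad_px >= min(h, w):
        raise ValueError("pad_px must be smaller than the smallest image side")
    if pad_px == 0:
        return image.copy(), np.ones_like(image, dtype=bool)
    padded = np.pad(image, pad_px, mode="reflect")
    mask = np.zeros(padded.shape, dtype=bool)
    mask[pad_px:-pad_px, pad_px:-pad_px] = True
    return padded, mask


def build(spec: UNetSpec, dtype=np.float32) -> UNet:
    """Instantiate a trainable network from its specification."""
    if spec.upsample != "transposed_conv":
        raise ValueError("only the transposed-convolution decoder is implemented")
    return UNet(
        base_filters=spec.base_filters,
        depth=spec.depth,
        in_channels=spec.in_channels,
        seed=spec.seed,
        dtype=dtype,
    )


def save_model(path: str | Path, model: UNet, spec: UNetSpec, m: float) -> None:
    """Write weights (.npz) plus a JSON sidecar with the spec and density scale m."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    sidecar = {"spec": asdict(spec), "m": m}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> tuple[UNet, UNetSpec, float]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    spec = UNetSpec(**sidecar["spec"])
    model = build(spec)
    with np.load(path.with_suffix(".npz")) as data:
        model.load_state_dict(dict(data))
    return model, spec, float(sidecar["m"])
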