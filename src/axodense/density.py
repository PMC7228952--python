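"""Ground-truth count-density construction from point annotations.

Manual counters mark one point per axon. The marks from K counters are
averaged into a per-pixel indicator matrix whose total equals the mean
manual count, then distributed over each axon's extent with an isotropic
Gaussian so that the integral of the resulting density map over any
region estimates the number of axons in that region. Density mass blurred
beyond the image border is discarded on purpose: an object lying partly
outside the frame should contribute only fractionally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

__all__ = [
    "AnnotationSet",
    "AnnotationMatrix",
    "DensityMap",
    "rasterize",
    "gaussian_kernel",
    "blur",
    "integrate",
    "nearest_multiple",
    "resize_with_points",
]

# Blur parameters used to spread one annotation over a typical axon's extent.
DEFAULT_SIGMA = 8.0
DEFAULT_KERNEL_SIZE = 33


@dataclass
class AnnotationSet:
    """One counter's axon-center marks for one image.

    Points are 0-based ``(row, col)`` integer pixel coordinates; CSV
    interchange uses ``x`` = column, ``y`` = row. At most one mark per
    pixel per counter is meaningful (duplicates are collapsed on
    rasterization).
    """

    counter_id: str
    points: np.ndarray  # (n, 2) int array of (row, col)
    image_shape: tuple[int, int]

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.int64).reshape(-1, 2)
        h, w = self.image_shape
        if pts.size and (
            pts[:, 0].min() < 0
            or pts[:, 1].min() < 0
            or pts[:, 0].max() >= h
            or pts[:, 1].max() >= w
        ):
            raise ValueError("annotation points must lie within image bounds")
        self.points = pts

    @property
    def count(self) -> int:
        return len(np.unique(self.points, axis=0)) if len(self.points) else 0


@dataclass
class AnnotationMatrix:
    """Per-pixel counter-averaged indicator D; entries are multiples of 1/K."""

    values: np.ndarray
    n_counters: int

    @property
    def total(self) -> float:
        """Mean manual count across counters."""
        return float(self.values.sum())


@dataclass
class DensityMap:
    """Nonnegative count-density field; its integral is a count."""

    values: np.ndarray
    scale: str = field(default="count_per_pixel")

    @property
    def count(self) -> float:
        return float(self.values.sum())


def rasterize(
    annotations: Sequence[AnnotationSet], shape: tuple[int, int]
) -> AnnotationMatrix:
    """Average the K counters' point indicators into the matrix D.

    ``D[i, j]`` is the fraction of counters that marked pixel ``(i, j)``,
    so the sum of D equals the mean of the counters' per-image counts.
    """
    if not annotations:
        raise ValueError("at least one counter is required (K >= 1)")
    values = np.zeros(shape, dtype=np.float64)
    for ann in annotations:
        if tuple(ann.image_shape) != tuple(shape):
            raise ValueError(
                f"annotation shape {ann.image_shape} does not match {shape}"
            )
        pts = np.unique(ann.points, axis=0) if len(ann.points) else ann.points
        if len(pts):
            values[pts[:, 0], pts[:, 1]] += 1.0
    values /= len(annotations)
    return AnnotationMatrix(values=values, n_counters=len(annotations))


def gaussian_kernel(sigma: float = DEFAULT_SIGMA, size: int = DEFAULT_KERNEL_SIZE) -> np.ndarray:
    """Truncated 2-D isotropic Gaussian, renormalized to unit sum.

    Renormalization makes an interior annotation integrate to exactly one
    count; a raw sigma=8 Gaussian truncated at +/-16 px would retain only
    ~91% of its mass and every count would be biased low.
    """
    if size % 2 == 0:
        raise ValueError("kernel size must be odd")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    half = size // 2
    x = np.arange(-half, half + 1, dtype=np.float64)
    g1 = np.exp(-(x**2) / (2.0 * sigma**2))
    k = np.outer(g1, g1)
    return k / k.sum()


def blur(
    matrix: AnnotationMatrix,
    sigma: float = DEFAULT_SIGMA,
    kernel_size: int = DEFAULT_KERNEL_SIZE,
) -> DensityMap:
    """Distribute annotation mass with the truncated Gaussian kernel.

    Convolution uses implicit zero padding and keeps the original extent,
    so mass carried beyond the border is dropped: partial objects count
    fractionally.
    """
    k = gaussian_kernel(sigma, kernel_size)
    out = ndimage.convolve(matrix.values, k, mode="constant", cval=0.0)
    return DensityMap(values=out)


def integrate(density: DensityMap | np.ndarray) -> float:
    """Total count: the sum of all density entries."""
    values = density.values if isinstance(density, DensityMap) else np.asarray(density)
    return float(values.sum())


def nearest_multiple(n: int, multiple: int = 16) -> int:
    """Closest multiple of ``multiple`` to ``n``; exact ties round up."""
    q = n / multiple
    return int(np.floor(q + 0.5)) * multiple


def resize_with_points(
    image: np.ndarray,
    annotations: Sequence[AnnotationSet] = (),
    target_multiple: int = 16,
) -> tuple[np.ndarray, list[AnnotationSet]]:
    """Bilinearly resize each side to its nearest multiple of 16, carrying points.

    Point coordinates are rescaled with the pixel-center convention and
    rounded. Density maps must be rebuilt from the rescaled points (never
    interpolated): bilinear interpolation does not conserve the integral.
    """
    h, w = image.shape
    if h < target_multiple or w < target_multiple:
        raise ValueError("image must be at least one multiple in each dimension")
    th, tw = nearest_multiple(h, target_multiple), nearest_multiple(w, target_multiple)
    if (th, tw) == (h, w):
        resized = image.astype(np.float64, copy=True)
    else:
        resized = _sk_resize(
            image.astype(np.float64), (th, tw), order=1, anti_aliasing=False,
            preserve_range=True,
        )
    sr, sc = th / h, tw / w
    out_annotations = []
    for ann in annotations:
        if len(ann.points):
            rows = np.round((ann.points[:, 0] + 0.5) * sr - 0.5).astype(np.int64)
            cols = np.round((ann.points[:, 1] + 0.5) * sc - 0.5).astype(np.int64)
            pts = np.stack(
                [np.clip(rows, 0, th - 1), np.clip(cols, 0, tw - 1)], axis=1
            )
        else:
            pts = ann.points
        out_annotations.append(
            AnnotationSet(counter_id=ann.counter_id, points=pts, image_shape=(th, tw))
        )
    return resized, out_annotations
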