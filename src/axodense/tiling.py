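"""Density prediction, count integration and whole-mosaic tiling.

Predictions run on reflection-padded inputs and are cropped back and
divided by the density scaling factor m, so the integral of the returned
map is directly a count. Mosaics larger than one tile are processed in
context-padded tiles: each tile carries true neighbouring pixels where
available (mirror padding is used only at the mosaic boundary), the
prediction is cropped back to the tile's core, and the cores partition
the mosaic exactly, so every pixel's density is predicted exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .density import DensityMap, integrate, nearest_multiple, resize_with_points
from .model import mirror_pad, normalize
from .nn import UNet

__all__ = [
    "TilingScheme",
    "TilePlacement",
    "predict_density",
    "count",
    "tile_image",
    "stitch",
    "count_full_nerve",
]


@dataclass
class TilingScheme:
    """Tile geometry for whole-nerve processing.

    ``tile_px`` is the core tile size and ``context_px`` the width of
    true neighbour context added on every side where available; both
    must be multiples of 16 so every padded window stays divisible by 16
    after edge mirroring. Defaults mirror the training conditions.
    """

    tile_px: int = 192
    context_px: int = 16

    def __post_init__(self) -> None:
        if self.tile_px % 16 or self.tile_px <= 0:
            raise ValueError("tile_px must be a positive multiple of 16")
        if self.context_px % 16 or self.context_px < 0:
            raise ValueError("context_px must be a nonnegative multiple of 16")


@dataclass
class TilePlacement:
    """Where a padded tile's pixels came from and which part is its core."""

    window: tuple[int, int, int, int]  # (r0, r1, c0, c1) of the padded window
    core: tuple[int, int, int, int]  # (r0, r1, c0, c1) of the core in the mosaic


def predict_density(model: UNet, image: np.ndarray, m: float, pad_px: int = 16) -> DensityMap:
    """Predict the count-density map of one image.

    Normalizes, reflection-pads by ``pad_px``, runs the network, crops
    back to the original extent and divides by the density scaling
    factor m. Input sides must be divisible by 16.
    """
    h, w = image.shape
    if h % 16 or w % 16:
        raise ValueError(f"image sides must be divisible by 16, got {(h, w)}")
    padded, _ = mirror_pad(normalize(image), pad_px)
    pred = model.forward(padded)
    if pad_px:
        pred = pred[pad_px:-pad_px, pad_px:-pad_px]
    return DensityMap(values=np.asarray(pred, dtype=np.float64) / m)


def count(model: UNet, image: np.ndarray, m: float, pad_px: int = 16) -> float:
    """Axon count: the integral of the predicted density map."""
    return integrate(predict_density(model, image, m, pad_px))


def _starts(extent: int, tile: int) -> list[int]:
    """Core-tile start offsets; the final tile is end-aligned."""
    if extent <= tile:
        return [0]
    n = int(np.ceil(extent / tile))
    s = [i * tile for i in range(n - 1)]
    s.append(extent - tile)
    return s


def tile_image(image: np.ndarray, scheme: TilingScheme) -> list[TilePlacement]:
    """Plan context-padded tiles whose cores partition the image.

    End-aligned final tiles overlap their predecessors, but their cores
    are clipped to the not-yet-covered remainder, preserving the
    partition property. Context comes from true neighbouring pixels,
    clipped at the mosaic boundary (the boundary sides are mirror-padded
    at prediction time instead).
    """
    h, w = image.shape
    t, ctx = scheme.tile_px, scheme.context_px
    placements = []
    row_starts, col_starts = _starts(h, t), _starts(w, t)
    prev_r_end = 0
    for r0 in row_starts:
        r1 = min(r0 + t, h)
        core_r0, core_r1 = max(r0, prev_r_end), r1
        prev_r_end = r1
        prev_c_end = 0
        for c0 in col_starts:
            c1 = min(c0 + t, w)
            core_c0, core_c1 = max(c0, prev_c_end), c1
            prev_c_end = c1
            win = (
                max(0, r0 - ctx), min(h, r1 + ctx),
                max(0, c0 - ctx), min(w, c1 + ctx),
            )
            placements.append(
                TilePlacement(window=win, core=(core_r0, core_r1, core_c0, core_c1))
            )
    return placements


def stitch(tiles: list[np.ndarray], placements: list[TilePlacement],
           shape: tuple[int, int]) -> np.ndarray:
    """Reassemble per-tile arrays (cropped to their cores) into one mosaic."""
    out = np.zeros(shape, dtype=np.float64)
    for arr, pl in zip(tiles, placements):
        wr0, _, wc0, _ = pl.window
        r0, r1, c0, c1 = pl.core
        out[r0:r1, c0:c1] = arr[r0 - wr0 : r1 - wr0, c0 - wc0 : c1 - wc0]
    return out


def _predict_any_size(model: UNet, img: np.ndarray, m: float, pad_px: int) -> np.ndarray:
    """Predict a window of any size by reflect-padding up to a multiple of 16."""
    hh, ww = img.shape
    ph, pw = (-hh) % 16, (-ww) % 16
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw)), mode="reflect")
    return predict_density(model, img, m, pad_px).values[:hh, :ww]


def count_full_nerve(
    model: UNet,
    mosaic: np.ndarray,
    scheme: TilingScheme | None = None,
    m: float = 1000.0,
    pad_px: int = 16,
) -> tuple[float, DensityMap]:
    """Count a whole-nerve mosaic by context-padded tiling.

    Returns the total count and the stitched density map. Mosaics
    smaller than one tile are resized to the nearest multiple-of-16
    dimensions and processed in a single pass.
    """
    scheme = scheme or TilingScheme()
    h, w = mosaic.shape
    if h < scheme.tile_px or w < scheme.tile_px:
        resized, _ = resize_with_points(mosaic, ())
        dm = predict_density(model, resized, m, pad_px)
        return dm.count, dm
    placements = tile_image(mosaic, scheme)
    tiles = []
    for i, pl in enumerate(placements):
        r0, r1, c0, c1 = pl.window
        try:
            tiles.append(_predict_any_size(model, mosaic[r0:r1, c0:c1], m, pad_px))
        except Exception as exc:  # annotate failures with the tile index
            raise RuntimeError(f"tile {i} (window {pl.window}) failed: {exc}") from exc
    stitched = stitch(tiles, placements, (h, w))
    return float(stitched.sum()), DensityMap(values=stitched)
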