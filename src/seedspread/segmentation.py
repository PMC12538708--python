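"""RGB scene -> binary seed mask -> grid proportions.

Mirrors the image-processing chain used for uniformity scoring: an
optional unsharp-mask sharpen, HSV-interval thresholding to a binary
seed/background mask, then partition of the mask into equal tiles
(default 6 x 8 = 48 tiles of 480 x 360 px on a 3840 x 2160 frame) whose
per-tile seed-pixel fractions are the Moran's I inputs.

HSV convention: H, S and V are all scaled to [0, 1]; hue intervals may
wrap around 0 (e.g. (0.95, 0.05) selects reds).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage import color as skcolor

__all__ = [
    "BinaryMask",
    "GridProportions",
    "unsharp_sharpen",
    "hsv_segment",
    "grid_proportions",
    "DEFAULT_HSV_RANGES",
]

#: HSV intervals tuned to the synthetic palette (warm-yellow/brown seeds
#: on a near-white belt): seeds are saturated and non-bright-white.
#: User-supplied imagery must pass explicit ranges; these defaults are
#: only meaningful for scenes rendered by :mod:`seedspread.scene_sim`.
DEFAULT_HSV_RANGES = {
    "h_range": (0.0, 0.35),
    "s_range": (0.15, 1.0),
    "v_range": (0.05, 1.0),
}


@dataclass(frozen=True)
class BinaryMask:
    """A per-pixel seed(1)/background(0) raster, row-major, origin top-left."""

    pixels: np.ndarray = field(repr=False)

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not np.isin(px, (0, 1)).all():
            raise ValueError("mask values must be 0/1")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    def foreground_count(self) -> int:
        return int(self.pixels.sum())

    def to_png(self, path: str | Path) -> None:
        Image.fromarray(self.pixels * np.uint8(255), mode="L").save(path)

    @classmethod
    def from_png(cls, path: str | Path) -> "BinaryMask":
        arr = np.asarray(Image.open(path).convert("L"))
        return cls(pixels=(arr > 127).astype(np.uint8))


@dataclass(frozen=True)
class GridProportions:
    """Per-tile seed-pixel fractions on an ``n_rows x n_cols`` grid.

    ``counts`` holds the exact integer foreground count per tile so the
    bookkeeping identity  sum(counts) == mask foreground total  is exact;
    ``values`` (= counts / tile area) are the x_i fed to Moran's I.
    """

    n_rows: int
    n_cols: int
    tile_w_px: int
    tile_h_px: int
    counts: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def tile_area_px(self) -> int:
        return self.tile_w_px * self.tile_h_px

    @property
    def values(self) -> np.ndarray:
        return self.counts / self.tile_area_px

    def flat_values(self) -> np.ndarray:
        """Row-major flat view consumed by the weights builder."""
        return self.values.ravel()

    def to_csv(self, path: str | Path) -> None:
        rows, cols = np.divmod(np.arange(self.n), self.n_cols)
        pd.DataFrame(
            {"row": rows, "col": cols, "proportion": self.flat_values()}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, tile_w_px: int = 480, tile_h_px: int = 360):
        """Rebuild from a (row, col, proportion) CSV written by :meth:`to_csv`."""
        df = pd.read_csv(path)
        n_rows = int(df["row"].max()) + 1
        n_cols = int(df["col"].max()) + 1
        vals = np.zeros((n_rows, n_cols))
        vals[df["row"], df["col"]] = df["proportion"]
        counts = np.rint(vals * tile_w_px * tile_h_px).astype(np.int64)
        return cls(n_rows, n_cols, tile_w_px, tile_h_px, counts)


def _require_rgb(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB raster")
    return arr


def unsharp_sharpen(image: np.ndarray, radius: float = 2.0, amount: float = 1.0) -> np.ndarray:
    """Unsharp-mask sharpen an RGB image.

    Per channel: ``clip(input + amount * (input - gaussian_blur(input,
    radius)))``, with the result clipped to the input's value range and
    returned in the input dtype.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if amount < 0:
        raise ValueError("amount must be nonnegative")
    arr = _require_rgb(image)
    x = arr.astype(float)
    blurred = np.stack(
        [ndimage.gaussian_filter(x[..., c], sigma=radius) for c in range(3)], axis=-1
    )
    out = x + amount * (x - blurred)
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return np.clip(np.rint(out), info.min, info.max).astype(arr.dtype)
    return np.clip(out, 0.0, 1.0)


def _in_interval(channel: np.ndarray, lo: float, hi: float, wrap: bool) -> np.ndarray:
    if lo <= hi:
        return (channel >= lo) & (channel <= hi)
    if not wrap:
        raise ValueError(f"empty interval ({lo}, {hi})")
    return (channel >= lo) | (channel <= hi)  # hue wraparound through 0


def hsv_segment(
    image: np.ndarray,
    h_range: tuple[float, float],
    s_range: tuple[float, float],
    v_range: tuple[float, float],
) -> BinaryMask:
    """Threshold an RGB image to a binary seed mask in HSV space.

    A pixel is foreground iff H, S and V all fall inside their intervals.
    All channels use the [0, 1] convention; the hue interval may wrap
    around 0 (lo > hi means "through red").
    """
    arr = _require_rgb(image)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr / 255.0
    hsv = skcolor.rgb2hsv(arr)
    m = _in_interval(hsv[..., 0], *h_range, wrap=True)
    m &= _in_interval(hsv[..., 1], *s_range, wrap=False)
    m &= _in_interval(hsv[..., 2], *v_range, wrap=False)
    return BinaryMask(pixels=m.astype(np.uint8))


def grid_proportions(
    mask: BinaryMask, tile_w_px: int = 480, tile_h_px: int = 360
) -> GridProportions:
    """Bin a mask into equal tiles and return per-tile foreground fractions.

    Tile (r, c) covers the half-open pixel block
    ``[r*tile_h, (r+1)*tile_h) x [c*tile_w, (c+1)*tile_w)``. Mask
    dimensions must divide exactly — partial tiles would distort the
    proportions, so non-divisible input is an error.
    """
    if tile_w_px <= 0 or tile_h_px <= 0:
        raise ValueError("tile dimensions must be positive")
    h, w = mask.pixels.shape
    if h % tile_h_px or w % tile_w_px:
        raise ValueError(
            f"mask {w}x{h} is not divisible into {tile_w_px}x{tile_h_px} tiles"
        )
    n_rows, n_cols = h // tile_h_px, w // tile_w_px
    counts = (
        mask.pixels.reshape(n_rows, tile_h_px, n_cols, tile_w_px)
        .sum(axis=(1, 3))
        .astype(np.int64)
    )
    return GridProportions(n_rows, n_cols, tile_w_px, tile_h_px, counts)
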