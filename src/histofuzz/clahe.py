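"""Contrast limited adaptive histogram equalization (CLAHE).

The image is partitioned into a grid of contextual regions (tiles).  Each
tile gets its own histogram-equalization lookup table, built from a
*clipped* histogram: bins exceeding the clip limit are trimmed and the
excess mass is redistributed uniformly, iterated to a fixed point so no bin
re-violates the limit.  Clipping bounds the slope of the cumulative
distribution and thus prevents the contrast (and noise) over-amplification
of plain adaptive equalization.  Each output pixel is the bilinear blend of
the lookup tables of the four nearest tile centers, which removes the
block boundaries a per-tile mapping would create; pixels in the border band
fall back to the nearest tile.

RGB images are enhanced on the luminance channel only (RGB -> YUV, equalize
Y, convert back); equalizing the channels independently would shift stain
hue, which is ruinous for histology.  The clip limit is specified relative
to the uniform bin height, so the configuration is independent of tile
size: ``clip_counts = clip_limit * tile_pixels / n_bins``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from skimage.color import rgb2yuv, yuv2rgb

__all__ = [
    "CLAHEConfig",
    "TileMapping",
    "clip_and_redistribute",
    "build_tile_mapping",
    "apply_clahe",
]

#: iterative redistribution stops when the remaining excess is below this
_RESIDUAL_TOL = 1e-3


@dataclasses.dataclass(frozen=True)
class CLAHEConfig:
    """Tile grid, clip limit (multiple of the uniform bin height), bin count."""

    grid_rows: int = 8
    grid_cols: int = 8
    clip_limit: float = 2.0
    n_bins: int = 256

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.clip_limit < 1.0:
            raise ValueError(
                "clip_limit must be >= 1 (clipping below the uniform bin "
                "height would erase all contrast)"
            )
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


@dataclasses.dataclass(frozen=True)
class TileMapping:
    """Monotone intensity lookup table for one tile, plus the tile center."""

    lut: np.ndarray  # (n_bins,) int levels in [0, n_bins-1]
    center: tuple[float, float]  # (row, col) in pixel coordinates

    def __post_init__(self) -> None:
        if np.any(np.diff(self.lut) < 0):
            raise ValueError("tile lookup table must be non-decreasing")


def clip_and_redistribute(histogram: np.ndarray, clip_limit_counts: float) -> np.ndarray:
    """Clip histogram bins at ``clip_limit_counts`` and redistribute the excess.

    Classical iterative scheme: trim every bin to the limit, spread the
    collected excess uniformly over all bins, and repeat (redistribution can
    push previously clipped bins back over the limit) until the residual
    excess is below 1e-3 counts.  Total mass is conserved.  An all-zero
    histogram is returned unchanged.

    The iteration only has a fixed point when the limit is at least the
    uniform bin height (total / n_bins) — below that the histogram cannot
    fit under the limit at all — so lower limits are clamped up to it,
    which yields the flat histogram.
    """
    hist = np.asarray(histogram, dtype=float).copy()
    if np.any(hist < 0):
        raise ValueError("histogram counts must be non-negative")
    if clip_limit_counts <= 0:
        raise ValueError("clip_limit_counts must be positive")
    if hist.sum() == 0:
        return hist
    clip_limit_counts = max(clip_limit_counts, hist.sum() / hist.size)
    while True:
        excess = np.sum(np.maximum(hist - clip_limit_counts, 0.0))
        if excess < _RESIDUAL_TOL:
            break
        np.minimum(hist, clip_limit_counts, out=hist)
        hist += excess / hist.size
    return hist


def _equalization_lut(hist: np.ndarray, n_bins: int) -> np.ndarray:
    """Scaled-CDF lookup table; identity for degenerate (single-level) tiles."""
    cdf = np.cumsum(hist)
    total = cdf[-1]
    nonzero = np.flatnonzero(hist)
    if total <= 0 or nonzero.size <= 1:
        # constant tile: CDF min-max scaling would be 0/0; keep it constant
        return np.arange(n_bins)
    cdf_min = cdf[nonzero[0]]
    if total == cdf_min:
        return np.arange(n_bins)
    scaled = (cdf - cdf_min) / (total - cdf_min) * (n_bins - 1)
    return np.clip(np.rint(scaled), 0, n_bins - 1).astype(np.int64)


def build_tile_mapping(
    tile_pixels: np.ndarray,
    config: CLAHEConfig,
    center: tuple[float, float] = (0.0, 0.0),
) -> TileMapping:
    """Equalization LUT for one tile from its clipped histogram.

    ``tile_pixels`` are integer levels in ``[0, n_bins)``.  The LUT is the
    min-max scaled CDF of the clipped histogram (non-decreasing by
    construction); a single-valued tile maps identically.
    """
    levels = np.asarray(tile_pixels).ravel()
    if levels.size == 0:
        raise ValueError("tile must be non-empty")
    hist = np.bincount(levels, minlength=config.n_bins).astype(float)
    if np.count_nonzero(hist) <= 1:
        # single-intensity tile: keep it constant (identity mapping)
        return TileMapping(lut=np.arange(config.n_bins), center=center)
    if np.isfinite(config.clip_limit):
        clip_counts = config.clip_limit * levels.size / config.n_bins
        hist = clip_and_redistribute(hist, clip_counts)
    return TileMapping(lut=_equalization_lut(hist, config.n_bins), center=center)


def _clahe_levels(levels: np.ndarray, config: CLAHEConfig) -> np.ndarray:
    """CLAHE on a 2-D array of integer levels in [0, n_bins)."""
    h, w = levels.shape
    rows, cols = config.grid_rows, config.grid_cols
    if h < rows or w < cols:
        raise ValueError(
            f"image ({h}x{w}) smaller than the tile grid ({rows}x{cols})"
        )
    row_edges = np.linspace(0, h, rows + 1).astype(int)
    col_edges = np.linspace(0, w, cols + 1).astype(int)
    luts = np.empty((rows, cols, config.n_bins), dtype=np.int64)
    for i in range(rows):
        for j in range(cols):
            tile = levels[row_edges[i] : row_edges[i + 1], col_edges[j] : col_edges[j + 1]]
            center = (
                0.5 * (row_edges[i] + row_edges[i + 1]),
                0.5 * (col_edges[j] + col_edges[j + 1]),
            )
            luts[i, j] = build_tile_mapping(tile, config, center).lut

    # fractional tile coordinates of each pixel relative to tile centers;
    # clamping the indices realizes the nearest-tile fallback at borders
    tile_h = h / rows
    tile_w = w / cols
    fy = (np.arange(h) + 0.5) / tile_h - 0.5
    fx = (np.arange(w) + 0.5) / tile_w - 0.5
    i0 = np.clip(np.floor(fy).astype(int), 0, rows - 1)
    j0 = np.clip(np.floor(fx).astype(int), 0, cols - 1)
    i1 = np.minimum(i0 + 1, rows - 1)
    j1 = np.minimum(j0 + 1, cols - 1)
    wy = np.clip(fy - np.floor(fy), 0.0, 1.0)
    wx = np.clip(fx - np.floor(fx), 0.0, 1.0)
    wy[fy < 0] = 0.0
    wx[fx < 0] = 0.0

    i0g, j0g = i0[:, None], j0[None, :]
    i1g, j1g = i1[:, None], j1[None, :]
    wyg, wxg = wy[:, None], wx[None, :]
    v = levels
    out = (
        (1 - wyg) * (1 - wxg) * luts[i0g, j0g, v]
        + (1 - wyg) * wxg * luts[i0g, j1g, v]
        + wyg * (1 - wxg) * luts[i1g, j0g, v]
        + wyg * wxg * luts[i1g, j1g, v]
    )
    return out


def apply_clahe(image: np.ndarray, config: CLAHEConfig | None = None) -> np.ndarray:
    """CLAHE on a 2-D grayscale or ``(H, W, 3)`` RGB image.

    Grayscale arrays are equalized directly; RGB arrays are converted to
    YUV and only luminance is equalized.  Output dtype and nominal range
    match the input (uint8 in [0, 255], floats in [0, 1]).  Constant images
    are fixed points.
    """
    if config is None:
        config = CLAHEConfig()
    img = np.asarray(image)
    if img.ndim == 2:
        return _apply_gray(img, config)
    if img.ndim == 3 and img.shape[2] == 3:
        return _apply_rgb(img, config)
    raise ValueError(f"expected 2-D grayscale or (H, W, 3) RGB image, got shape {img.shape}")


def _to_unit(img: np.ndarray) -> tuple[np.ndarray, str]:
    if img.dtype == np.uint8:
        return img.astype(float) / 255.0, "uint8"
    if img.dtype == np.uint16:
        return img.astype(float) / 65535.0, "uint16"
    return np.asarray(img, dtype=float), "float"

def _from_unit(img: np.ndarray, kind: str) -> np.ndarray:
    img = np.clip(img, 0.0, 1.0)
    if kind == "uint8":
        return np.rint(img * 255.0).astype(np.uint8)
    if kind == "uint16":
        return np.rint(img * 65535.0).astype(np.uint16)
    return img


def _apply_gray(img: np.ndarray, config: CLAHEConfig) -> np.ndarray:
    unit, kind = _to_unit(img)
    scale = config.n_bins - 1
    levels = np.clip(np.rint(unit * scale), 0, scale).astype(np.int64)
    mapped = _clahe_levels(levels, config)
    # apply the LUT as a delta on the unquantized values so that an
    # identity mapping (e.g. a constant image) reproduces the input exactly
    out = unit + (mapped - levels) / scale
    return _from_unit(out, kind)


def _apply_rgb(img: np.ndarray, config: CLAHEConfig) -> np.ndarray:
    unit, kind = _to_unit(img)
    yuv = rgb2yuv(unit)
    y = np.clip(yuv[..., 0], 0.0, 1.0)
    scale = config.n_bins - 1
    levels = np.clip(np.rint(y * scale), 0, scale).astype(np.int64)
    mapped = _clahe_levels(levels, config)
    yuv[..., 0] = np.clip(y + (mapped - levels) / scale, 0.0, 1.0)
    return _from_unit(yuv2rgb(yuv), kind)
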