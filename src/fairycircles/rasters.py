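"""Grayscale raster scenes: rendering synthetic landscapes and image I/O.

A :class:`RasterImage` is a row-major intensity grid in [0, 1] with a
meters-per-pixel scale and a world origin, mimicking the satellite tiles
the detection stage consumes. Barren circles render brighter than the
grass matrix by default (bare sand vs vegetated surface); the matrix gets
a smoothed speckle texture standing in for grass tussocks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .geometry import CirclePattern

__all__ = ["RasterImage", "render_landscape", "to_grayscale", "read_raster"]

#: Rec. 601 luma weights used for RGB -> grayscale conversion.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass
class RasterImage:
    """2-D intensity grid (values in [0,1]) with geospatial plumbing.

    Row 0 is the top of the image; x grows with columns, y with world
    northing, so world y = origin_y + (n_rows - row - 0.5) * pixel_scale.
    """

    data: np.ndarray
    pixel_scale: float
    origin_x: float = 0.0
    origin_y: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.size == 0:
            raise ValueError("raster grid must be 2-D and non-empty")
        if not self.pixel_scale > 0:
            raise ValueError("pixel_scale must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def pixel_to_world(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """World (x, y) of pixel centers given fractional row/col indices."""
        x = self.origin_x + (np.asarray(cols) + 0.5) * self.pixel_scale
        y = self.origin_y + (self.shape[0] - np.asarray(rows) - 0.5) * self.pixel_scale
        return x, y

    def write_png(self, path: str | Path) -> None:
        """8-bit PNG plus a JSON sidecar carrying scale and origin."""
        path = Path(path)
        arr = np.clip(self.data, 0.0, 1.0)
        iio.imwrite(path, (arr * 255).round().astype(np.uint8))
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {
                    "pixel_scale_m": self.pixel_scale,
                    "origin_x_m": self.origin_x,
                    "origin_y_m": self.origin_y,
                }
            )
        )


def read_raster(path: str | Path, pixel_scale: float | None = None) -> RasterImage:
    """Read a PNG/TIFF raster; scale comes from the JSON sidecar written by
    :meth:`RasterImage.write_png` unless given explicitly."""
    path = Path(path)
    arr = np.asarray(iio.imread(path), dtype=float)
    if arr.ndim == 3:
        arr = _luminance(arr)
    if arr.max() > 1.0:
        arr = arr / 255.0
    origin_x = origin_y = 0.0
    sidecar = path.with_suffix(path.suffix + ".json")
    if pixel_scale is None:
        if not sidecar.exists():
            raise ValueError(
                f"pixel scale not given and sidecar {sidecar.name} missing"
            )
        meta = json.loads(sidecar.read_text())
        pixel_scale = float(meta["pixel_scale_m"])
        origin_x = float(meta.get("origin_x_m", 0.0))
        origin_y = float(meta.get("origin_y_m", 0.0))
    return RasterImage(arr, pixel_scale, origin_x, origin_y)


def _luminance(rgb: np.ndarray) -> np.ndarray:
    if rgb.shape[-1] == 4:  # drop alpha
        rgb = rgb[..., :3]
    if rgb.shape[-1] != 3:
        raise ValueError(f"expected 3 channels, got {rgb.shape[-1]}")
    return rgb @ LUMA_WEIGHTS


def to_grayscale(rgb: np.ndarray, pixel_scale: float = 1.0) -> RasterImage:
    """Convert an RGB(A) array to a normalized grayscale RasterImage using
    Rec. 601 luma weights, rescaled into [0, 1]."""
    arr = np.asarray(rgb, dtype=float)
    if arr.ndim != 3:
        raise ValueError("expected an rows x cols x channels array")
    gray = _luminance(arr)
    if gray.max() > 1.0:
        gray = gray / 255.0
    return RasterImage(np.clip(gray, 0.0, 1.0), pixel_scale)


def render_landscape(
    pattern: CirclePattern,
    pixel_scale: float = 0.5,
    circle_level: float = 0.85,
    matrix_level: float = 0.35,
    speckle_sd: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    speckle_smoothing_px: float = 1.0,
) -> RasterImage:
    """Rasterize a circle pattern as a grayscale scene.

    The matrix is filled at ``matrix_level`` plus a smoothed Gaussian
    speckle field (grass-tussock texture, sd ``speckle_sd``); barren discs
    overwrite it at ``circle_level``; i.i.d. Gaussian sensor noise
    (``noise_sd``) is added everywhere and the result clipped to [0, 1].
    Deterministic for a fixed seed.
    """
    if pixel_scale <= 0:
        raise ValueError("pixel_scale must be positive")
    if not circle_level > matrix_level:
        raise ValueError("barren circles must be brighter than the matrix")
    w = pattern.window
    n_cols = int(round(w.width / pixel_scale))
    n_rows = int(round(w.height / pixel_scale))
    if n_rows < 3 or n_cols < 3:
        raise ValueError("window smaller than 3 px in one dimension")

    rng = np.random.default_rng(seed)
    img = np.full((n_rows, n_cols), matrix_level)
    if speckle_sd > 0:
        field = rng.normal(0.0, 1.0, img.shape)
        field = ndimage.gaussian_filter(field, speckle_smoothing_px)
        sd = field.std()
        if sd > 0:
            img += field * (speckle_sd / sd)

    # pixel-center world coordinates
    xs = w.xmin + (np.arange(n_cols) + 0.5) * pixel_scale
    ys = w.ymax - (np.arange(n_rows) + 0.5) * pixel_scale
    for (cx, cy), r in zip(pattern.centers, pattern.radii):
        if r <= 0:
            continue
        c0 = max(0, int((cx - r - w.xmin) / pixel_scale) - 1)
        c1 = min(n_cols, int((cx + r - w.xmin) / pixel_scale) + 2)
        r0 = max(0, int((w.ymax - cy - r) / pixel_scale) - 1)
        r1 = min(n_rows, int((w.ymax - cy + r) / pixel_scale) + 2)
        if c0 >= c1 or r0 >= r1:
            continue
        dx = xs[c0:c1] - cx
        dy = ys[r0:r1] - cy
        mask = dy[:, None] ** 2 + dx[None, :] ** 2 <= r * r
        block = img[r0:r1, c0:c1]
        block[mask] = circle_level
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, img.shape)
    return RasterImage(np.clip(img, 0.0, 1.0), pixel_scale, w.xmin, w.ymin)
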