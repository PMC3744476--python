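"""Planar windows and circle patterns.

A :class:`CirclePattern` (centers + radii in a rectangular observation
window, all in meters) is the currency that connects the synthetic
generators, the raster renderer, the image detector and the dispersion
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SpatialWindow", "CirclePattern", "hexagonal_window"]


@dataclass(frozen=True)
class SpatialWindow:
    """Rectangular observation window in meters.

    ``distance_mode`` controls how nearest-neighbor distances are measured
    inside the window: ``"euclidean"`` (plain distances, appropriate for
    field data) or ``"toroidal"`` (periodic wrap-around, which removes edge
    bias in simulation studies).
    """

    xmin: float
    xmax: float
    ymin: float
    ymax: float
    distance_mode: str = "euclidean"

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError("window must have positive extent")
        if self.distance_mode not in ("euclidean", "toroidal"):
            raise ValueError(f"unknown distance_mode {self.distance_mode!r}")

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        """Window area in m^2."""
        return self.width * self.height

    @property
    def hectares(self) -> float:
        return self.area / 1e4

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        return (
            (pts[:, 0] >= self.xmin)
            & (pts[:, 0] <= self.xmax)
            & (pts[:, 1] >= self.ymin)
            & (pts[:, 1] <= self.ymax)
        )

    def inset(self, margin: float) -> "SpatialWindow":
        """Window shrunk by ``margin`` on every side (same distance mode)."""
        return SpatialWindow(
            self.xmin + margin,
            self.xmax - margin,
            self.ymin + margin,
            self.ymax - margin,
            self.distance_mode,
        )


def hexagonal_window(spacing: float, nx: int, ny: int) -> SpatialWindow:
    """Toroidal window holding exactly ``nx*ny`` points of a seamless
    triangular lattice with the given spacing.

    ``ny`` must be even so that the row offset pattern wraps without a seam;
    then every point has all six neighbors at exactly ``spacing`` under
    toroidal distances.
    """
    if ny % 2:
        raise ValueError("ny must be even for a seamless toroidal lattice")
    dy = spacing * np.sqrt(3.0) / 2.0
    return SpatialWindow(0.0, nx * spacing, 0.0, ny * dy, distance_mode="toroidal")


@dataclass
class CirclePattern:
    """Circle centers and radii (meters) inside an observation window."""

    centers: np.ndarray
    radii: np.ndarray
    window: SpatialWindow = field(default_factory=lambda: SpatialWindow(0, 100, 0, 100))

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 2)
        self.radii = np.asarray(self.radii, dtype=float).reshape(-1)
        if len(self.centers) != len(self.radii):
            raise ValueError("centers and radii length mismatch")
        if np.any(self.radii < 0):
            raise ValueError("radii must be non-negative")
        if len(self.centers) and not self.window.contains(self.centers).all():
            raise ValueError("all centers must lie inside the window")

    @property
    def n(self) -> int:
        return len(self.radii)

    @property
    def areas(self) -> np.ndarray:
        """Individual circle areas, m^2."""
        return np.pi * self.radii**2

    @property
    def diameters(self) -> np.ndarray:
        return 2.0 * self.radii

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_m": self.centers[:, 0],
                "y_m": self.centers[:, 1],
                "radius_m": self.radii,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, window: SpatialWindow | None = None) -> "CirclePattern":
        df = pd.read_csv(path)
        centers = df[["x_m", "y_m"]].to_numpy(dtype=float)
        radii = df["radius_m"].to_numpy(dtype=float)
        if window is None:
            pad = float(radii.max()) if len(radii) else 1.0
            window = SpatialWindow(
                centers[:, 0].min() - pad,
                centers[:, 0].max() + pad,
                centers[:, 1].min() - pad,
                centers[:, 1].max() + pad,
            )
        return cls(centers, radii, window)

    def with_window(self, window: SpatialWindow) -> "CirclePattern":
        return CirclePattern(self.centers.copy(), self.radii.copy(), window)
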