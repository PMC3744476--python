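"""Point-pattern dispersion and landscape-occupancy statistics.

Implements the Clark-Evans nearest-neighbor index R = r_obs / r_exp with
r_exp = 1 / (2 sqrt(rho)) under complete spatial randomness, its normal
significance test (SE = 0.26136 / sqrt(n * rho)), and the per-site summary
set used for regional comparisons: density, landscape occupancy (% land
surface inside circles), area/diameter percentiles, periphery-to-periphery
spacing and cumulative circle circumference per hectare.

R < 1 diagnoses clumping, R = 1 randomness, and R = 2.15 the hexagonal
maximum-dispersion limit.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .geometry import CirclePattern, SpatialWindow

__all__ = [
    "DispersionResult",
    "OccupancySummary",
    "nn_distances",
    "clark_evans",
    "landscape_occupancy",
    "periphery_distances",
    "cumulative_circumference",
    "summarize_patterns",
]

#: Clark & Evans standard error constant for the mean NN distance under CSR.
CE_SE_CONSTANT = 0.26136

#: Clark-Evans R of a perfect triangular (hexagonal) lattice, 2 d.p.
HEXAGONAL_MAX_R = 2.15


@dataclass(frozen=True)
class DispersionResult:
    """Clark-Evans dispersion test bundle for one pattern."""

    n: int
    area_m2: float
    density_per_m2: float
    density_per_ha: float
    r_obs: float
    r_exp: float
    R: float
    se_r: float
    Z: float
    p_two_sided: float
    significant_at_05: bool

    def as_dict(self) -> dict:
        return asdict(self)


def _resolve_mode(window: SpatialWindow, mode: str | None) -> str:
    return window.distance_mode if mode is None else mode


def nn_distances(
    centers: np.ndarray, window: SpatialWindow, mode: str | None = None
) -> np.ndarray:
    """Distance from every point to its nearest other point.

    ``mode="toroidal"`` wraps the window (periodic boundary), removing edge
    bias; ``"euclidean"`` uses plain distances. Defaults to the window's
    distance mode.
    """
    pts = np.asarray(centers, dtype=float).reshape(-1, 2)
    if len(pts) < 2:
        raise ValueError("nearest-neighbor distances need at least 2 points")
    mode = _resolve_mode(window, mode)
    if mode == "toroidal":
        shifted = pts - [window.xmin, window.ymin]
        box = np.array([window.width, window.height])
        # cKDTree requires coordinates strictly inside [0, boxsize)
        shifted = np.mod(shifted, box)
        tree = cKDTree(shifted, boxsize=box)
        d, _ = tree.query(shifted, k=2)
    elif mode == "euclidean":
        tree = cKDTree(pts)
        d, _ = tree.query(pts, k=2)
    else:
        raise ValueError(f"unknown distance mode {mode!r}")
    return d[:, 1]


def clark_evans(
    centers: np.ndarray, window: SpatialWindow, mode: str | None = None
) -> DispersionResult:
    """Clark-Evans nearest-neighbor dispersion test.

    rho = n / area, r_exp = 1/(2 sqrt(rho)), R = mean NN distance / r_exp,
    Z = (r_obs - r_exp) / (0.26136 / sqrt(n rho)), two-sided normal p.
    """
    pts = np.asarray(centers, dtype=float).reshape(-1, 2)
    n = len(pts)
    if n < 2:
        raise ValueError("Clark-Evans test needs at least 2 points")
    area = window.area
    if area <= 0:
        raise ValueError("degenerate window")
    rho = n / area
    d = nn_distances(pts, window, mode)
    r_obs = float(d.mean())
    r_exp = 1.0 / (2.0 * np.sqrt(rho))
    se_r = CE_SE_CONSTANT / np.sqrt(n * rho)
    z = (r_obs - r_exp) / se_r
    p = 2.0 * stats.norm.sf(abs(z))
    return DispersionResult(
        n=n,
        area_m2=area,
        density_per_m2=rho,
        density_per_ha=rho * 1e4,
        r_obs=r_obs,
        r_exp=r_exp,
        R=r_obs / r_exp,
        se_r=se_r,
        Z=float(z),
        p_two_sided=float(p),
        significant_at_05=bool(p < 0.05),
    )


def landscape_occupancy(pattern: CirclePattern) -> float:
    """Percent of the window surface covered by circle interiors
    (sum pi r^2 / window area * 100). Overlap, if any, is double-counted."""
    if pattern.n == 0:
        return 0.0
    return float(100.0 * pattern.areas.sum() / pattern.window.area)


def periphery_distances(pattern: CirclePattern, mode: str | None = None) -> np.ndarray:
    """Nearest-neighbor distance between circle edges: center NN distance
    minus both radii, floored at zero for touching/overlapping circles."""
    if pattern.n < 2:
        raise ValueError("periphery distances need at least 2 circles")
    pts = pattern.centers
    window = pattern.window
    mode = _resolve_mode(window, mode)
    if mode == "toroidal":
        shifted = np.mod(pts - [window.xmin, window.ymin], [window.width, window.height])
        tree = cKDTree(shifted, boxsize=[window.width, window.height])
        d, idx = tree.query(shifted, k=2)
    else:
        tree = cKDTree(pts)
        d, idx = tree.query(pts, k=2)
    gaps = d[:, 1] - pattern.radii - pattern.radii[idx[:, 1]]
    return np.maximum(gaps, 0.0)


def cumulative_circumference(pattern: CirclePattern) -> float:
    """Total circle circumference per hectare (m / ha): sum 2 pi r over the
    window area in hectares."""
    if pattern.n == 0:
        return 0.0
    return float(2.0 * np.pi * pattern.radii.sum() / pattern.window.hectares)


@dataclass(frozen=True)
class OccupancySummary:
    """Per-site (or across-site) landscape summary statistics."""

    n_sites: int
    density_per_ha: float
    density_se: float | None
    occupancy_pct: float
    occupancy_se: float | None
    area_mean_m2: float
    area_median_m2: float
    area_p5_m2: float
    area_p95_m2: float
    diameter_mean_m: float
    diameter_median_m: float
    diameter_p5_m: float
    diameter_p95_m: float
    periphery_mean_m: float
    periphery_se: float | None
    circumference_m_per_ha: float
    R: float | None
    R_se: float | None

    def as_dict(self) -> dict:
        return asdict(self)


def _se(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1) / np.sqrt(len(values)))


def summarize_patterns(
    patterns: CirclePattern | Sequence[CirclePattern],
    mode: str | None = None,
) -> OccupancySummary:
    """Summary-statistic table for one pattern or an ensemble of site
    patterns: density, occupancy, area/diameter distribution, periphery
    spacing, cumulative circumference and Clark-Evans R (mean +/- SE across
    sites when several patterns are given; SE fields are None for one)."""
    if isinstance(patterns, CirclePattern):
        patterns = [patterns]
    patterns = list(patterns)
    if not patterns:
        raise ValueError("need at least one pattern")
    multi = len(patterns) > 1

    densities = np.array([p.n / p.window.hectares for p in patterns])
    occupancies = np.array([landscape_occupancy(p) for p in patterns])
    areas = np.concatenate([p.areas for p in patterns])
    diameters = np.concatenate([p.diameters for p in patterns])
    periph = [
        periphery_distances(p, mode).mean() for p in patterns if p.n >= 2
    ]
    circum = np.array([cumulative_circumference(p) for p in patterns])
    r_values = np.array(
        [clark_evans(p.centers, p.window, mode).R for p in patterns if p.n >= 2]
    )

    return OccupancySummary(
        n_sites=len(patterns),
        density_per_ha=float(densities.mean()),
        density_se=_se(densities) if multi else None,
        occupancy_pct=float(occupancies.mean()),
        occupancy_se=_se(occupancies) if multi else None,
        area_mean_m2=float(areas.mean()),
        area_median_m2=float(np.median(areas)),
        area_p5_m2=float(np.percentile(areas, 5)),
        area_p95_m2=float(np.percentile(areas, 95)),
        diameter_mean_m=float(diameters.mean()),
        diameter_median_m=float(np.median(diameters)),
        diameter_p5_m=float(np.percentile(diameters, 5)),
        diameter_p95_m=float(np.percentile(diameters, 95)),
        periphery_mean_m=float(np.mean(periph)) if periph else float("nan"),
        periphery_se=_se(np.array(periph)) if (multi and len(periph) > 1) else None,
        circumference_m_per_ha=float(circum.mean()),
        R=float(r_values.mean()) if len(r_values) else None,
        R_se=_se(r_values) if (multi and len(r_values) > 1) else None,
    )
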