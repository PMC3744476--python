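"""Point-process generators for circle-center patterns.

Four processes span the dispersion continuum diagnosed by the Clark-Evans
R statistic: Matern cluster (clumped, R < 1), complete spatial randomness
(R = 1), sequential hard-core inhibition (over-dispersed, 1 < R < 2.15) and
the jittered triangular lattice (maximum dispersion, R = 2.15 at zero
jitter). ``assign_radii`` then dresses centers with lognormal diameters
calibrated to field summary percentiles.

All generators are pure functions of their parameters and an explicit seed.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .geometry import CirclePattern, SpatialWindow

__all__ = [
    "gen_csr",
    "gen_hexagonal",
    "gen_matern_cluster",
    "gen_hardcore",
    "assign_radii",
]

#: Field-calibrated diameter summary (m): median and 5/95 percentiles.
DIAMETER_MEDIAN = 4.8
DIAMETER_P5 = 3.2
DIAMETER_P95 = 7.9


def gen_csr(n: int, window: SpatialWindow, seed: int) -> CirclePattern:
    """``n`` i.i.d. uniform points in the window (binomial process, the CSR
    null of the dispersion test). Radii are set to zero placeholders."""
    if n < 2:
        raise ValueError("CSR pattern needs n >= 2 points")
    rng = np.random.default_rng(seed)
    x = rng.uniform(window.xmin, window.xmax, n)
    y = rng.uniform(window.ymin, window.ymax, n)
    return CirclePattern(np.column_stack([x, y]), np.zeros(n), window)


def gen_hexagonal(
    spacing: float, jitter_sd: float, window: SpatialWindow, seed: int
) -> CirclePattern:
    """Triangular-lattice points with isotropic Gaussian positional jitter.

    The lattice is laid out to cover the window; jittered points falling
    outside are dropped. With ``jitter_sd=0`` in a window built by
    :func:`~fairycircles.geometry.hexagonal_window` every nearest-neighbor
    distance equals ``spacing`` under toroidal distances.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be non-negative")
    if spacing > min(window.width, window.height):
        raise ValueError("spacing exceeds the window: empty pattern")
    dy = spacing * np.sqrt(3.0) / 2.0
    rows = int(np.floor(window.height / dy))
    cols = int(np.floor(window.width / spacing))
    if rows < 1 or cols < 1:
        raise ValueError("window too small for the requested spacing")
    pts = []
    for i in range(rows):
        offset = (i % 2) * spacing / 2.0
        xs = window.xmin + offset + (np.arange(cols) + 0.25) * spacing
        ys = np.full(cols, window.ymin + (i + 0.5) * dy)
        pts.append(np.column_stack([xs, ys]))
    pts = np.concatenate(pts)
    pts = pts[(pts[:, 0] <= window.xmax) & (pts[:, 1] <= window.ymax)]
    rng = np.random.default_rng(seed)
    if jitter_sd > 0:
        pts = pts + rng.normal(0.0, jitter_sd, pts.shape)
        pts = pts[
            (pts[:, 0] >= window.xmin)
            & (pts[:, 0] <= window.xmax)
            & (pts[:, 1] >= window.ymin)
            & (pts[:, 1] <= window.ymax)
        ]
    if len(pts) < 2:
        raise ValueError("jitter removed nearly all lattice points")
    return CirclePattern(pts, np.zeros(len(pts)), window)


def gen_matern_cluster(
    parent_intensity: float,
    mean_offspring: float,
    cluster_radius: float,
    window: SpatialWindow,
    seed: int,
) -> CirclePattern:
    """Matern cluster process: Poisson parents, Poisson(mean_offspring)
    children uniform in a disc of ``cluster_radius`` around each parent.

    Children are wrapped toroidally into the window so the realized
    intensity matches parent_intensity * mean_offspring.
    """
    if min(parent_intensity, mean_offspring, cluster_radius) <= 0:
        raise ValueError("all Matern parameters must be positive")
    expected = parent_intensity * window.area * mean_offspring
    if expected < 2:
        import warnings

        warnings.warn(
            "expected fewer than 2 points: degenerate cluster pattern",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    n_parents = rng.poisson(parent_intensity * window.area)
    pts = []
    for _ in range(n_parents):
        px = rng.uniform(window.xmin, window.xmax)
        py = rng.uniform(window.ymin, window.ymax)
        k = rng.poisson(mean_offspring)
        if k == 0:
            continue
        # uniform in disc via sqrt-radius sampling
        r = cluster_radius * np.sqrt(rng.uniform(size=k))
        th = rng.uniform(0, 2 * np.pi, k)
        cx = px + r * np.cos(th)
        cy = py + r * np.sin(th)
        pts.append(np.column_stack([cx, cy]))
    if not pts:
        # degenerate realization (warned above when expected < 2)
        return CirclePattern(np.empty((0, 2)), np.empty(0), window)
    pts = np.concatenate(pts)
    pts[:, 0] = window.xmin + np.mod(pts[:, 0] - window.xmin, window.width)
    pts[:, 1] = window.ymin + np.mod(pts[:, 1] - window.ymin, window.height)
    return CirclePattern(pts, np.zeros(len(pts)), window)


def gen_hardcore(
    intensity: float,
    min_distance: float,
    window: SpatialWindow,
    seed: int,
    max_attempts_factor: int = 200,
) -> CirclePattern:
    """Simple sequential inhibition: uniform proposals accepted only when at
    least ``min_distance`` from every accepted point.

    Produces over-dispersed patterns (1 < R <= 2.15 as packing tightens).
    With ``min_distance=0`` this is exactly CSR.
    """
    if intensity <= 0:
        raise ValueError("intensity must be positive")
    if min_distance < 0:
        raise ValueError("min_distance must be non-negative")
    n_target = max(2, int(round(intensity * window.area)))
    packing = intensity * np.pi * min_distance**2 / 4.0
    if packing >= 1:
        raise ValueError(f"infeasible packing fraction {packing:.2f} >= 1")
    rng = np.random.default_rng(seed)
    if min_distance == 0:
        x = rng.uniform(window.xmin, window.xmax, n_target)
        y = rng.uniform(window.ymin, window.ymax, n_target)
        return CirclePattern(np.column_stack([x, y]), np.zeros(n_target), window)
    accepted: list[np.ndarray] = []
    attempts = 0
    max_attempts = max_attempts_factor * n_target
    d2 = min_distance**2
    pts_arr = np.empty((0, 2))
    while len(accepted) < n_target and attempts < max_attempts:
        attempts += 1
        p = np.array(
            [
                rng.uniform(window.xmin, window.xmax),
                rng.uniform(window.ymin, window.ymax),
            ]
        )
        if len(accepted):
            deltas = pts_arr - p
            if np.min(np.einsum("ij,ij->i", deltas, deltas)) < d2:
                continue
        accepted.append(p)
        pts_arr = np.vstack([pts_arr, p])
    if len(accepted) < n_target:
        raise RuntimeError(
            f"hard-core packing failed: placed {len(accepted)}/{n_target} "
            f"points in {max_attempts} attempts"
        )
    return CirclePattern(pts_arr, np.zeros(n_target), window)


def lognormal_from_percentiles(
    median: float, p5: float, p95: float
) -> tuple[float, float]:
    """(mu, sigma) of the lognormal whose median matches exactly and whose
    5th/95th percentiles compromise between the two stated tail values.

    A two-parameter lognormal cannot honor three quantiles exactly; sigma is
    the average of the two one-sided solutions.
    """
    if not (p5 < median < p95):
        raise ValueError("need p5 < median < p95")
    z95 = stats.norm.ppf(0.95)
    mu = np.log(median)
    sigma = 0.5 * ((np.log(p95) - mu) / z95 + (mu - np.log(p5)) / z95)
    return mu, sigma


def assign_radii(
    pattern: CirclePattern,
    diameter_median: float = DIAMETER_MEDIAN,
    diameter_p5: float = DIAMETER_P5,
    diameter_p95: float = DIAMETER_P95,
    seed: int = 0,
    forbid_overlap: bool = False,
    max_rounds: int = 100,
) -> CirclePattern:
    """Draw lognormal diameters calibrated to (p5, median, p95) and attach
    them to the centers of ``pattern``.

    With ``forbid_overlap`` the radii of intersecting pairs are resampled
    (bounded rounds) until no two discs overlap.
    """
    mu, sigma = lognormal_from_percentiles(diameter_median, diameter_p5, diameter_p95)
    rng = np.random.default_rng(seed)
    n = pattern.n
    radii = np.exp(rng.normal(mu, sigma, n)) / 2.0
    if forbid_overlap and n > 1:
        tree = cKDTree(pattern.centers)
        for _ in range(max_rounds):
            rmax = radii.max()
            pairs = tree.query_pairs(2 * rmax, output_type="ndarray")
            if len(pairs) == 0:
                break
            d = np.linalg.norm(
                pattern.centers[pairs[:, 0]] - pattern.centers[pairs[:, 1]], axis=1
            )
            bad = d < radii[pairs[:, 0]] + radii[pairs[:, 1]]
            if not bad.any():
                break
            redraw = np.unique(pairs[bad].ravel())
            radii[redraw] = np.exp(rng.normal(mu, sigma, len(redraw))) / 2.0
        else:
            raise RuntimeError("could not satisfy non-overlap after bounded retries")
    return CirclePattern(pattern.centers.copy(), radii, pattern.window)
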