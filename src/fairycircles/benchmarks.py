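"""Seeded benchmark scenes with known ground truth.

These are the study conditions the end-to-end checks run under: a rendered
landscape whose circle pattern is known exactly, and an occupancy-style
(x, y) cloud whose true 90th-percentile surface is a tent (piecewise
linear rise and fall), mimicking the unimodal upper limit of landscape
occupancy along a rainfall gradient.
"""

from __future__ import annotations

import numpy as np

from .geometry import CirclePattern, SpatialWindow
from .patterns import assign_radii, gen_hardcore
from .rasters import RasterImage, render_landscape

__all__ = ["detection_scene", "tent_envelope_data", "TENT_DEFAULTS"]


def detection_scene(
    seed: int = 0,
    n_circles: int = 100,
    pixel_scale: float = 0.5,
    speckle_sd: float = 0.06,
    noise_sd: float = 0.04,
) -> tuple[CirclePattern, RasterImage]:
    """Default seeded detection benchmark: ~100 hard-core circles with
    field-calibrated diameters in a 200 x 200 m window (25 ha^-1), rendered
    at 0.5 m/px with speckle texture and sensor noise.

    Centers are drawn in an inset window (margin 6 m) so no disc touches
    the border, and discs may not overlap — every ground-truth circle is
    recoverable in principle.
    """
    outer = SpatialWindow(0.0, 200.0, 0.0, 200.0)
    margin = 6.0
    inner = outer.inset(margin)
    intensity = n_circles / inner.area
    centers = gen_hardcore(intensity, min_distance=9.0, window=inner, seed=seed)
    pattern = assign_radii(
        centers, seed=seed + 1, forbid_overlap=True
    ).with_window(outer)
    image = render_landscape(
        pattern,
        pixel_scale=pixel_scale,
        speckle_sd=speckle_sd,
        noise_sd=noise_sd,
        seed=seed + 2,
    )
    return pattern, image


#: True tent for the envelope benchmark: occupancy-% like response over a
#: rainfall-like axis, peaking mid-gradient.
TENT_DEFAULTS = {
    "x_range": (30.0, 320.0),
    "breakpoint": 130.0,
    "left": (0.5, 0.075),  # intercept, slope of the q90 surface left of peak
    "right_slope": -0.045,
}


def tent_envelope_data(
    n: int = 2000,
    seed: int = 0,
    tau: float = 0.9,
    breakpoint: float | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """(x, y, truth) sample whose conditional tau-quantile is exactly a
    known tent function.

    y | x is uniform on (0, tent(x) / tau), so the tau-quantile of y given
    x equals tent(x) by construction. ``truth`` records the tent parameters
    actually used.
    """
    params = dict(TENT_DEFAULTS)
    if breakpoint is not None:
        params["breakpoint"] = float(breakpoint)
    lo, hi = params["x_range"]
    b = params["breakpoint"]
    li, ls = params["left"]
    rs = params["right_slope"]
    peak = li + ls * b
    rng = np.random.default_rng(seed)
    x = rng.uniform(lo, hi, n)
    tent = np.where(x <= b, li + ls * x, peak + rs * (x - b))
    y = rng.uniform(0.0, tent / tau, n)
    truth = {
        "breakpoint": b,
        "left_intercept": li,
        "left_slope": ls,
        "right_slope": rs,
        "peak": peak,
        "tau": tau,
    }
    return x, y, truth
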