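"""Synthetic soil samples: paired circle/matrix draws and radial transects.

``gen_paired_soil`` emulates the paired survey design (one sample at each
circle center, one at the midpoint to the nearest neighboring circle)
using Gaussian draws whose means/SEs default to the field soil table —
e.g. gravimetric moisture 2.2 +/- 0.2 % inside circles vs 0.95 +/- 0.18 %
in the matrix (n = 11 sites).

``gen_soil_transect`` emulates the radial profiles: soil moisture (SM)
declines monotonically from the circle center into the matrix while soil
organic carbon (SOC) rises, so SM and SOC are negatively correlated inside
the barren interior by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SoilSample",
    "PAIRED_DEFAULTS",
    "TRANSECT_DEPTHS",
    "gen_paired_soil",
    "gen_soil_transect",
    "samples_to_dataframe",
]

#: Default circle/matrix (mean, SE) pairs per variable, n = 11 sites.
PAIRED_DEFAULTS: dict[str, dict[str, tuple[float, float]]] = {
    "moisture_pct": {"circle": (2.2, 0.2), "matrix": (0.95, 0.18)},
    "field_capacity_pct": {"circle": (21.7, 0.7), "matrix": (18.8, 0.8)},
    "soc_pct": {"circle": (0.037, 0.003), "matrix": (0.052, 0.002)},
    "n_pct": {"circle": (0.006, 0.0005), "matrix": (0.008, 0.0005)},
    "p_olsen_mg_kg": {"circle": (1.82, 0.18), "matrix": (1.45, 0.16)},
    "k_mg_kg": {"circle": (69.0, 4.0), "matrix": (84.0, 2.0)},
}

#: Sampled depth intervals (m) for transect profiles (4 depths to 0.5 m).
TRANSECT_DEPTHS: tuple[tuple[float, float], ...] = (
    (0.0, 0.1),
    (0.1, 0.2),
    (0.2, 0.3),
    (0.3, 0.5),
)


@dataclass(frozen=True)
class SoilSample:
    """One soil measurement at a given zone/distance/depth."""

    site_id: int
    zone: str  # circle_center | periphery | matrix
    distance_from_center: float  # m
    depth_top: float  # m
    depth_bottom: float  # m
    moisture_pct: float
    soc_pct: float
    n_pct: float | None = None

    def __post_init__(self) -> None:
        if self.zone not in ("circle_center", "periphery", "matrix"):
            raise ValueError(f"unknown zone {self.zone!r}")
        if not self.depth_bottom > self.depth_top:
            raise ValueError("depth_bottom must exceed depth_top")
        if self.moisture_pct < 0 or self.soc_pct < 0:
            raise ValueError("percentages must be non-negative")


def samples_to_dataframe(samples: list[SoilSample]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in samples])


def gen_paired_soil(
    n_sites: int = 11,
    variables: Mapping[str, Mapping[str, tuple[float, float]]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired circle/matrix Gaussian draws.

    ``variables`` maps variable name -> {"circle": (mean, se),
    "matrix": (mean, se)}; per-site SD is reconstructed from the SE of the
    site mean as SD = SE * sqrt(n_sites). Negative draws for percentage-like
    quantities are clipped at zero. Returns one row per (site, zone).
    """
    if n_sites < 2:
        raise ValueError("n_sites must be >= 2")
    variables = PAIRED_DEFAULTS if variables is None else variables
    for var, zones in variables.items():
        for zone, (_, se) in zones.items():
            if se < 0:
                raise ValueError(f"negative SE for {var}/{zone}")
    rng = np.random.default_rng(seed)
    rows = []
    for site in range(n_sites):
        for zone_key, zone_name in (("circle", "circle_center"), ("matrix", "matrix")):
            row: dict = {"site_id": site, "zone": zone_name}
            for var in sorted(variables):
                mean, se = variables[var][zone_key]
                sd = se * np.sqrt(n_sites)
                row[var] = max(0.0, rng.normal(mean, sd))
            rows.append(row)
    return pd.DataFrame(rows)


def gen_soil_transect(
    n_sites: int = 5,
    center_sm: float = 2.2,
    matrix_sm: float = 0.95,
    center_soc: float = 0.037,
    matrix_soc: float = 0.052,
    circle_radius: float = 2.4,
    max_distance: float = 8.0,
    step: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[SoilSample]:
    """Radial soil transects at 1 m intervals and 4 depths per station.

    The noise-free per-layer profiles are
    SM(d) = matrix + (center - matrix) * exp(-(d / r)^2) (strictly
    decreasing) and SOC(d) the mirror-image increase, with r the circle
    radius, so depth-summed SM and SOC co-vary inversely inside the barren
    interior. Gaussian measurement noise (sd ``noise_sd``, in SM percent
    units; SOC noise scaled by the SOC/SM contrast ratio) is added per
    layer and clipped at zero.
    """
    if not center_sm > matrix_sm:
        raise ValueError("center soil moisture must exceed matrix soil moisture")
    if not matrix_soc > center_soc:
        raise ValueError("matrix SOC must exceed center SOC")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    distances = np.arange(0.0, max_distance + 1e-9, step)
    soc_scale = (matrix_soc - center_soc) / (center_sm - matrix_sm)
    samples: list[SoilSample] = []
    for site in range(n_sites):
        for d in distances:
            shape = np.exp(-((d / circle_radius) ** 2))
            sm_base = matrix_sm + (center_sm - matrix_sm) * shape
            soc_base = matrix_soc - (matrix_soc - center_soc) * shape
            if d <= circle_radius:
                zone = "circle_center" if d == 0 else "periphery"
            else:
                zone = "matrix"
            for top, bottom in TRANSECT_DEPTHS:
                # deeper layers hold slightly more moisture (less evaporation)
                depth_factor = 1.0 + 0.3 * top
                sm = sm_base * depth_factor
                soc = soc_base / depth_factor
                if noise_sd > 0:
                    sm += rng.normal(0.0, noise_sd)
                    soc += rng.normal(0.0, noise_sd * soc_scale)
                samples.append(
                    SoilSample(
                        site_id=site,
                        zone=zone,
                        distance_from_center=float(d),
                        depth_top=top,
                        depth_bottom=bottom,
                        moisture_pct=max(0.0, float(sm)),
                        soc_pct=max(0.0, float(soc)),
                    )
                )
    return samples
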