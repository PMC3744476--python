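"""Synthetic environmental site tables for the niche model.

Sites carry three covariates — mean annual precipitation (MAP, mm),
temperature seasonality (BIO4, SD of monthly temperature x 100) and the
first principal component of the enhanced vegetation index (EVI1, a
vegetation-biomass surrogate) — drawn uniformly over the observed
background ranges. Presence is 1 exactly inside the nested niche box and
0 outside, then every label is flipped independently with probability
``label_noise`` (symmetric misclassification).

Default ranges follow the field calibration: niche MAP 52-135 mm,
EVI1 715-1281, BIO4 193-315 inside backgrounds 29-324 / 593-2067 / 193-417.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "NICHE_RANGES",
    "BACKGROUND_RANGES",
    "gen_env_presence",
    "expected_prevalence",
    "add_noise_covariates",
]

NICHE_RANGES: dict[str, tuple[float, float]] = {
    "map_mm": (52.0, 135.0),
    "evi1": (715.0, 1281.0),
    "bio4": (193.0, 315.0),
}

BACKGROUND_RANGES: dict[str, tuple[float, float]] = {
    "map_mm": (29.0, 324.0),
    "evi1": (593.0, 2067.0),
    "bio4": (193.0, 417.0),
}

#: nominal lon/lat box for site plumbing (degrees); no geographic realism
_LONLAT_BOX = ((14.0, 20.0), (-28.0, -17.0))


def expected_prevalence(
    niche: dict[str, tuple[float, float]] | None = None,
    background: dict[str, tuple[float, float]] | None = None,
) -> float:
    """Closed-form presence prevalence at zero label noise: the product of
    per-covariate niche/background range fractions (uniform sampling)."""
    niche = NICHE_RANGES if niche is None else niche
    background = BACKGROUND_RANGES if background is None else background
    frac = 1.0
    for var, (lo, hi) in niche.items():
        blo, bhi = background[var]
        frac *= (hi - lo) / (bhi - blo)
    return frac


def gen_env_presence(
    n_sites: int,
    niche: dict[str, tuple[float, float]] | None = None,
    background: dict[str, tuple[float, float]] | None = None,
    label_noise: float = 0.0,
    seed: int = 0,
    n_noise_covariates: int = 0,
) -> pd.DataFrame:
    """Sample a presence/absence site table.

    ``n_noise_covariates`` optionally appends uninformative uniform(0, 1)
    columns noise1..k, useful for benchmarking variable selection.
    """
    niche = NICHE_RANGES if niche is None else dict(niche)
    background = BACKGROUND_RANGES if background is None else dict(background)
    if set(niche) != set(background):
        raise ValueError("niche and background must cover the same covariates")
    for var, (lo, hi) in niche.items():
        blo, bhi = background[var]
        if not lo < hi:
            raise ValueError(f"empty niche range for {var}")
        if lo < blo or hi > bhi:
            raise ValueError(f"niche range for {var} not nested in background")
    if not 0 <= label_noise < 0.5:
        raise ValueError("label_noise must be in [0, 0.5)")
    if n_sites < 1:
        raise ValueError("n_sites must be positive")

    rng = np.random.default_rng(seed)
    (lon_lo, lon_hi), (lat_lo, lat_hi) = _LONLAT_BOX
    data: dict[str, np.ndarray] = {
        "lon": rng.uniform(lon_lo, lon_hi, n_sites),
        "lat": rng.uniform(lat_lo, lat_hi, n_sites),
    }
    inside = np.ones(n_sites, dtype=bool)
    for var in sorted(background):
        blo, bhi = background[var]
        vals = rng.uniform(blo, bhi, n_sites)
        data[var] = vals
        lo, hi = niche[var]
        inside &= (vals >= lo) & (vals <= hi)
    presence = inside.astype(int)
    if label_noise > 0:
        flip = rng.uniform(size=n_sites) < label_noise
        presence = np.where(flip, 1 - presence, presence)
    data["presence"] = presence
    df = pd.DataFrame(data)
    if n_noise_covariates:
        df = add_noise_covariates(df, n_noise_covariates, seed=seed + 1)
    return df


def add_noise_covariates(df: pd.DataFrame, k: int, seed: int = 0) -> pd.DataFrame:
    """Append k pure-noise uniform(0, 1) covariates noise1..noisek."""
    rng = np.random.default_rng(seed)
    out = df.copy()
    for i in range(1, k + 1):
        out[f"noise{i}"] = rng.uniform(size=len(df))
    return out
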