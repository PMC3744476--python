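"""Soil and growth statistics: depth-weighted totals, group comparisons
from summary statistics, fold ratios, OLS fits and the interior
moisture-carbon correlation.

Group comparisons default to Welch's t test computed directly from
(mean, SE, n) summaries — the conservative choice when pairing and
variance pooling are unreported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .soil import SoilSample, samples_to_dataframe

__all__ = [
    "SummaryStat",
    "TTestResult",
    "BULK_DENSITY_KG_M3",
    "depth_weighted_sum",
    "t_test_summary",
    "fold_ratio",
    "ols_fit",
    "interior_correlation",
]

#: Measured soil bulk density used for depth weight-summing (kg / m^3).
BULK_DENSITY_KG_M3 = 1738.0


@dataclass(frozen=True)
class SummaryStat:
    """Group summary: mean, standard error of the mean, group size."""

    mean: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("se must be non-negative")
        if self.n < 2:
            raise ValueError("n must be >= 2")

    @property
    def sd(self) -> float:
        """Per-observation SD reconstructed as SE * sqrt(n)."""
        return self.se * np.sqrt(self.n)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p_two_sided: float
    flavor: str


def depth_weighted_sum(
    profile: list[SoilSample] | pd.DataFrame,
    variable: str = "moisture_pct",
    bulk_density: float = BULK_DENSITY_KG_M3,
) -> float:
    """Areal total (kg / m^2) of a mass-percentage variable over a depth
    profile at one location: sum of (pct / 100) * bulk_density * thickness.

    Layers must not overlap (a layer split into sub-layers leaves the total
    unchanged; overlapping layers would double-count mass and raise).
    """
    if isinstance(profile, list):
        df = samples_to_dataframe(profile)
    else:
        df = profile.copy()
    if df.empty:
        return 0.0
    df = df.sort_values("depth_top")
    tops = df["depth_top"].to_numpy(dtype=float)
    bottoms = df["depth_bottom"].to_numpy(dtype=float)
    if np.any(bottoms <= tops):
        raise ValueError("each layer needs depth_bottom > depth_top")
    if np.any(tops[1:] < bottoms[:-1] - 1e-12):
        raise ValueError("overlapping depth layers")
    conc = df[variable].to_numpy(dtype=float)
    return float(np.sum(conc / 100.0 * bulk_density * (bottoms - tops)))


def t_test_summary(
    a: SummaryStat, b: SummaryStat, flavor: str = "welch"
) -> TTestResult:
    """Two-sample t test from group summaries.

    Welch (default): t = (m1 - m2) / sqrt(se1^2 + se2^2) with
    Welch-Satterthwaite degrees of freedom. "pooled" pools variances with
    df = n1 + n2 - 2. "paired" cannot be computed from summaries alone and
    raises.
    """
    if flavor == "paired":
        raise ValueError("paired test needs raw pairs, not summaries")
    if flavor == "welch":
        var_sum = a.se**2 + b.se**2
        if var_sum == 0:
            t = 0.0 if a.mean == b.mean else np.inf * np.sign(a.mean - b.mean)
            df = float(a.n + b.n - 2)
        else:
            t = (a.mean - b.mean) / np.sqrt(var_sum)
            df = var_sum**2 / (
                a.se**4 / (a.n - 1) + b.se**4 / (b.n - 1)
            )
    elif flavor == "pooled":
        s2a, s2b = a.sd**2, b.sd**2
        sp2 = ((a.n - 1) * s2a + (b.n - 1) * s2b) / (a.n + b.n - 2)
        denom = np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
        t = 0.0 if denom == 0 and a.mean == b.mean else (a.mean - b.mean) / denom
        df = float(a.n + b.n - 2)
    else:
        raise ValueError(f"unknown flavor {flavor!r}")
    p = float(2.0 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    if t == 0.0:
        p = 1.0
    return TTestResult(t=float(t), df=float(df), p_two_sided=p, flavor=flavor)


def fold_ratio(larger: float, smaller: float, decimals: int = 1) -> float:
    """larger / smaller, rounded to ``decimals`` (e.g. a 2.3-fold moisture
    difference)."""
    if smaller <= 0:
        raise ValueError("denominator mean must be positive")
    return float(round(larger / smaller, decimals))


def ols_fit(
    predictors: pd.DataFrame | np.ndarray,
    response: np.ndarray,
    names: list[str] | None = None,
) -> dict:
    """Ordinary least squares with intercept: coefficients, r^2 and the
    overall-F p value."""
    if isinstance(predictors, pd.DataFrame):
        X = predictors.to_numpy(dtype=float)
        names = list(predictors.columns)
    else:
        X = np.asarray(predictors, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if names is None:
            names = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(response, dtype=float).ravel()
    n, k = X.shape
    if n <= k + 1:
        raise ValueError("need n > predictors + 1 observations")
    design = sm.add_constant(X)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    res = sm.OLS(y, design).fit()
    coefs = dict(zip(["intercept"] + names, res.params))
    return {
        "coefficients": coefs,
        "r_squared": float(res.rsquared),
        "p_overall": float(res.f_pvalue),
        "coef_se": dict(zip(["intercept"] + names, res.bse)),
        "n": n,
    }


def interior_correlation(
    transect: list[SoilSample] | pd.DataFrame,
    interior_radius: float = 2.4,
) -> dict:
    """Pearson correlation between depth-summed soil moisture and SOC over
    the barren circle interior (stations with distance <= interior_radius).

    Totals are computed per (site, distance) profile. Returns r, r^2,
    two-sided p and the slope sign; raises with fewer than 4 interior
    profiles or a constant variable.
    """
    if isinstance(transect, list):
        df = samples_to_dataframe(transect)
    else:
        df = transect.copy()
    interior = df[df["distance_from_center"] <= interior_radius]
    sm_tot, soc_tot = [], []
    for (_, _), prof in interior.groupby(["site_id", "distance_from_center"]):
        sm_tot.append(depth_weighted_sum(prof, "moisture_pct"))
        soc_tot.append(depth_weighted_sum(prof, "soc_pct"))
    if len(sm_tot) < 4:
        raise ValueError("need at least 4 interior profiles")
    sm_arr = np.asarray(sm_tot)
    soc_arr = np.asarray(soc_tot)
    if np.ptp(sm_arr) == 0 or np.ptp(soc_arr) == 0:
        raise ValueError("correlation undefined for a constant variable")
    r, p = stats.pearsonr(sm_arr, soc_arr)
    return {
        "r": float(r),
        "r_squared": float(r**2),
        "p_two_sided": float(p),
        "slope_sign": int(np.sign(r)),
        "n": len(sm_arr),
    }
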