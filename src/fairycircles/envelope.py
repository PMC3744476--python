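"""Upper-limit envelopes via piecewise quantile regression.

Landscape occupancy peaks at intermediate rainfall, so its upper limit as
a function of an environmental driver is summarized by a continuous
two-segment linear fit of the tau-th conditional quantile (tau = 0.9 by
default). The breakpoint is grid-searched; each candidate fit minimizes
the pinball loss rho_tau(u) = u * (tau - 1[u < 0]) over the basis
[1, x, max(x - b, 0)], which keeps the curve continuous at the breakpoint.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import statsmodels.api as sm

__all__ = ["QuantileFit", "fit_quantile_piecewise", "fraction_above", "pinball_loss"]


def pinball_loss(y: np.ndarray, y_hat: np.ndarray, tau: float) -> float:
    """Total pinball (quantile) loss of predictions at level tau."""
    u = np.asarray(y, float) - np.asarray(y_hat, float)
    return float(np.sum(u * (tau - (u < 0))))


@dataclass(frozen=True)
class QuantileFit:
    """Continuous two-segment linear quantile fit.

    Left segment applies for x <= breakpoint, right segment beyond; the two
    lines meet at the breakpoint by construction.
    """

    tau: float
    breakpoint: float
    left_intercept: float
    left_slope: float
    right_intercept: float
    right_slope: float
    loss: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        left = self.left_intercept + self.left_slope * x
        right = self.right_intercept + self.right_slope * x
        return np.where(x <= self.breakpoint, left, right)

    def as_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2))


def _quantreg(design: np.ndarray, y: np.ndarray, tau: float) -> np.ndarray | None:
    """IRLS pinball-loss fit; None when the solver fails (e.g. collinear)."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.QuantReg(y, design)
            res = model.fit(q=tau, p_tol=1e-8, max_iter=5000)
        beta = np.asarray(res.params, dtype=float)
        if not np.all(np.isfinite(beta)):
            return None
        return beta
    except Exception:
        return None


def fit_quantile_piecewise(
    x: np.ndarray,
    y: np.ndarray,
    tau: float = 0.9,
    breakpoint_grid: np.ndarray | None = None,
) -> QuantileFit:
    """Fit the tau-quantile envelope as a continuous two-segment line.

    The breakpoint grid defaults to 21 interior quantiles of x (10th-90th
    percentile). A plain one-segment linear fit competes as a degenerate
    candidate so the returned loss never exceeds the best single line's.
    Ties break toward the smaller breakpoint. With all x identical the fit
    degenerates to the constant empirical tau-quantile of y.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 10:
        raise ValueError("need at least 10 points for an envelope fit")
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")

    if np.ptp(x) == 0 or np.ptp(y) == 0:
        level = float(np.quantile(y, tau))
        return QuantileFit(
            tau=tau,
            breakpoint=float(x[0]),
            left_intercept=level,
            left_slope=0.0,
            right_intercept=level,
            right_slope=0.0,
            loss=pinball_loss(y, np.full_like(y, level), tau),
        )

    if breakpoint_grid is None:
        breakpoint_grid = np.unique(
            np.quantile(x, np.linspace(0.1, 0.9, 21))
        )
    else:
        breakpoint_grid = np.unique(np.asarray(breakpoint_grid, dtype=float))

    best: QuantileFit | None = None

    # degenerate single-line candidate (nests the piecewise family)
    ones = np.ones_like(x)
    beta = _quantreg(np.column_stack([ones, x]), y, tau)
    if beta is not None:
        yhat = beta[0] + beta[1] * x
        best = QuantileFit(
            tau=tau,
            breakpoint=float(x.max()),
            left_intercept=float(beta[0]),
            left_slope=float(beta[1]),
            right_intercept=float(beta[0]),
            right_slope=float(beta[1]),
            loss=pinball_loss(y, yhat, tau),
        )

    tol = 1e-9
    for b in breakpoint_grid:
        hinge = np.maximum(x - b, 0.0)
        # both segments need support for an identified fit
        if (x <= b).sum() < 2 or (x > b).sum() < 2:
            continue
        beta = _quantreg(np.column_stack([ones, x, hinge]), y, tau)
        if beta is None:
            continue
        yhat = beta[0] + beta[1] * x + beta[2] * hinge
        loss = pinball_loss(y, yhat, tau)
        cand = QuantileFit(
            tau=tau,
            breakpoint=float(b),
            left_intercept=float(beta[0]),
            left_slope=float(beta[1]),
            right_intercept=float(beta[0] - beta[2] * b),
            right_slope=float(beta[1] + beta[2]),
            loss=loss,
        )
        if (
            best is None
            or loss < best.loss - tol
            or (abs(loss - best.loss) <= tol and cand.breakpoint < best.breakpoint)
        ):
            best = cand
    if best is None:
        raise RuntimeError("quantile envelope fit failed on every candidate")
    return best


def fraction_above(fit: QuantileFit, x: np.ndarray, y: np.ndarray) -> float:
    """Proportion of points lying strictly above the fitted envelope; for a
    calibrated tau-quantile fit this is approximately 1 - tau."""
    y = np.asarray(y, dtype=float).ravel()
    return float(np.mean(y > fit.predict(x)))
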