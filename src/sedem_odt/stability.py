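"""Shelf-life estimation from stability time series.

The assay (% of label claim) of each formulation is regressed on storage
time by ordinary least squares, and the shelf life is the earliest time at
which the one-sided lower confidence bound on the *mean* regression line
crosses the specification limit — the regulatory stability convention.
With fewer degrees of freedom the bound widens sharply (Student t), so the
estimate is deliberately conservative relative to the naive crossing of
the fitted mean line.

The bound at time t is ``yhat(t) - t_{conf,df} * s * sqrt(1/n + (t-xbar)^2
/ Sxx)``; its first crossing of the limit is located by a coarse bracketing
scan followed by bisection to 0.001 month. When the fit is exact (zero
residual variance) the bound collapses onto the mean line and the crossing
has the closed form ``(intercept - limit) / |slope|``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "StabilitySeries",
    "ShelfLifeEstimate",
    "StabilityModel",
    "estimate_shelf_life",
]


@dataclass
class StabilitySeries:
    """Assay-vs-time data for one formulation (accelerated or long term)."""

    label: str
    months: np.ndarray
    assay: np.ndarray  # percent of label claim
    dissolution: np.ndarray | None = None
    disintegration: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.months = np.asarray(self.months, dtype=float)
        self.assay = np.asarray(self.assay, dtype=float)
        if self.months.shape != self.assay.shape or self.months.ndim != 1:
            raise ValueError("months and assay must be 1-D and the same length")
        if np.any(self.months < 0) or np.any(np.diff(self.months) <= 0):
            raise ValueError("months must be non-negative and strictly increasing")
        if np.any(self.assay <= 0) or np.any(self.assay > 110):
            raise ValueError("assay must lie in (0, 110] percent")


@dataclass(frozen=True)
class ShelfLifeEstimate:
    """Regression line, settings and the bound-crossing time."""

    label: str
    slope: float  # %/month
    intercept: float  # %
    residual_sd: float
    spec_limit: float
    confidence: float
    horizon: float
    shelf_life_months: float  # +inf if the bound never crosses before horizon
    mean_crossing_months: float  # naive crossing of the fitted mean line

    @property
    def is_finite(self) -> bool:
        return math.isfinite(self.shelf_life_months)

    def summary(self) -> str:
        sl = (
            f"{self.shelf_life_months:.3f} months"
            if self.is_finite
            else f"no crossing within {self.horizon:g} months"
        )
        return (
            f"{self.label}: assay = {self.intercept:.3f} {self.slope:+.4f} * month "
            f"(s = {self.residual_sd:.4f}); shelf life at {self.spec_limit:g}% spec, "
            f"one-sided {self.confidence:.0%} bound: {sl}"
        )


class StabilityModel:
    """OLS stability regression with a one-sided lower bound on the mean."""

    def __init__(self, series: StabilitySeries, response: str = "assay"):
        y = getattr(series, response, None)
        if y is None:
            raise ValueError(f"series {series.label!r} has no {response!r} data")
        y = np.asarray(y, dtype=float)
        if y.size < 3:
            raise ValueError("need at least 3 time points")
        if np.all(y == y[0]):
            raise ValueError("degenerate series: response constant over time")
        self.series = series
        self.x = series.months
        self.y = y

    def fit(
        self,
        spec_limit: float = 90.0,
        confidence: float = 0.95,
        horizon: float = 600.0,
        tol: float = 1e-3,
    ) -> ShelfLifeEstimate:
        x, y = self.x, self.y
        n = x.size
        xbar = x.mean()
        sxx = float(np.sum((x - xbar) ** 2))
        slope = float(np.sum((x - xbar) * (y - y.mean())) / sxx)
        intercept = float(y.mean() - slope * xbar)
        resid = y - (intercept + slope * x)
        df = n - 2
        s = math.sqrt(float(np.sum(resid**2)) / df) if df > 0 else 0.0
        tcrit = float(stats.t.ppf(confidence, df)) if df > 0 and s > 0 else 0.0

        def lower_bound(t: np.ndarray) -> np.ndarray:
            t = np.asarray(t, dtype=float)
            mean = intercept + slope * t
            if s == 0.0 or tcrit == 0.0:
                return mean
            se = s * np.sqrt(1.0 / n + (t - xbar) ** 2 / sxx)
            return mean - tcrit * se

        mean_crossing = (
            (intercept - spec_limit) / -slope if slope < 0 else math.inf
        )
        if math.isfinite(mean_crossing) and mean_crossing < 0:
            mean_crossing = 0.0

        if s == 0.0:
            # exact fit: the bound collapses onto the mean line
            shelf = mean_crossing if mean_crossing <= horizon else math.inf
        else:
            shelf = self._first_crossing(lower_bound, spec_limit, horizon, tol)
        if not math.isfinite(shelf):
            warnings.warn(
                f"{self.series.label}: confidence bound never reaches "
                f"{spec_limit}% within {horizon} months",
                stacklevel=2,
            )
        return ShelfLifeEstimate(
            label=self.series.label,
            slope=slope,
            intercept=intercept,
            residual_sd=s,
            spec_limit=spec_limit,
            confidence=confidence,
            horizon=horizon,
            shelf_life_months=shelf,
            mean_crossing_months=mean_crossing,
        )

    @staticmethod
    def _first_crossing(bound, spec: float, horizon: float, tol: float) -> float:
        """Smallest t in [0, horizon] with bound(t) <= spec, to ``tol``."""
        if bound(np.array([0.0]))[0] <= spec:
            return 0.0
        # bracket the first crossing on a grid fine enough for a smooth bound
        grid = np.linspace(0.0, horizon, 4097)
        vals = bound(grid) - spec
        below = np.nonzero(vals <= 0)[0]
        if below.size == 0:
            return math.inf
        hi_i = below[0]
        lo, hi = grid[hi_i - 1], grid[hi_i]
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if bound(np.array([mid]))[0] <= spec:
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)


def estimate_shelf_life(
    series: StabilitySeries,
    spec_limit: float = 90.0,
    confidence: float = 0.95,
    horizon: float = 600.0,
    response: str = "assay",
) -> ShelfLifeEstimate:
    """Fit the stability regression and locate the bound-crossing time."""
    return StabilityModel(series, response=response).fit(
        spec_limit=spec_limit, confidence=confidence, horizon=horizon
    )
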