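"""Central composite design, tablet composition arithmetic and response
surfaces for the two-factor ODT formulation study.

The design varies ludipress (binder/filler) and croscarmellose sodium
(superdisintegrant) percentages around a center point, with axial runs at
distance alpha = sqrt(2) (rotatable for two factors). Each design point is
turned into a full tablet composition: fixed excipients (aerosil 0.14%,
talc 2.36%, aspartame 1%, magnesium stearate 1%) plus the two factors leave
the remainder to the API, and a fixed API dose (100 mg) sets the tablet
weight.

Responses (hardness, disintegration time, friability) are modelled on the
coded factors by ordinary least squares (linear or full quadratic), with the
classical regression ANOVA against the intercept-only null and the
design-of-experiments "adequate precision" signal-to-noise statistic
``(max fitted - min fitted) / sqrt(p * MS_res / n)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import truncate

__all__ = [
    "FactorSpec",
    "CCDesign",
    "FormulationComposition",
    "DEFAULT_FIXED_EXCIPIENTS",
    "CANONICAL_RUN_ORDER",
    "generate_ccd",
    "composition_from_point",
    "ResponseSurfaceModel",
    "ResponseSurfaceResults",
    "AnovaTable",
    "fit_response_surface",
    "adequate_precision",
]


@dataclass(frozen=True)
class FactorSpec:
    """One design factor on the percent scale: actual = center + coded * step."""

    name: str
    center: float
    step: float

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"factor {self.name!r}: step must be positive")

    @property
    def low(self) -> float:
        return self.center - self.step

    @property
    def high(self) -> float:
        return self.center + self.step

    def actual(self, coded: float) -> float:
        return self.center + coded * self.step

    def coded(self, actual: float) -> float:
        return (actual - self.center) / self.step


#: Run order of the published design: factorial (-1,-1), axial (+a,0),
#: factorial (-1,+1), center, axial (0,+a), axial (-a,0), axial (0,-a),
#: factorial (+1,-1), factorial (+1,+1).
CANONICAL_RUN_ORDER: tuple[tuple[float, float], ...] = (
    (-1, -1),
    (+1, 0),  # +alpha once scaled
    (-1, +1),
    (0, 0),
    (0, +1),  # +alpha
    (-1, 0),  # -alpha
    (0, -1),  # -alpha
    (+1, -1),
    (+1, +1),
)
_AXIAL_RUNS = {1, 4, 5, 6}  # indices in CANONICAL_RUN_ORDER scaled by alpha


@dataclass
class CCDesign:
    """A two-factor central composite design in coded and actual units."""

    factors: tuple[FactorSpec, FactorSpec]
    alpha: float
    n_center: int
    runs: pd.DataFrame  # columns: run, c1, c2, <f1>_pct, <f2>_pct

    @property
    def coded(self) -> np.ndarray:
        return self.runs[["c1", "c2"]].to_numpy()

    def display(self, ndigits: int = 3) -> pd.DataFrame:
        """Actual levels truncated (not rounded) to ``ndigits`` decimals,
        the published table convention."""
        out = self.runs.copy()
        for f in self.factors:
            col = f"{f.name}_pct"
            out[col] = out[col].map(lambda v: truncate(v, ndigits))
        return out


def generate_ccd(
    factors: Sequence[FactorSpec],
    alpha: float = math.sqrt(2),
    n_center: int = 1,
) -> CCDesign:
    """Generate the 4 factorial + 4 axial + ``n_center`` center runs.

    With ``alpha = sqrt(2)`` the design is rotatable for two factors; with
    ``alpha = 1`` the axial runs coincide with the face centers. Runs are
    labelled F1..Fn in the canonical published order, extra center
    replicates appended at the end.
    """
    if len(factors) != 2:
        raise ValueError("exactly two factors are supported")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if n_center < 1:
        raise ValueError("need at least one center run")
    f1, f2 = factors
    rows = []
    for i, (c1, c2) in enumerate(CANONICAL_RUN_ORDER):
        if i in _AXIAL_RUNS:
            c1, c2 = c1 * alpha, c2 * alpha
        rows.append((c1, c2))
    rows.extend([(0.0, 0.0)] * (n_center - 1))
    df = pd.DataFrame(rows, columns=["c1", "c2"])
    df.insert(0, "run", [f"F{i + 1}" for i in range(len(df))])
    df[f"{f1.name}_pct"] = f1.actual(df["c1"])
    df[f"{f2.name}_pct"] = f2.actual(df["c2"])
    return CCDesign(factors=(f1, f2), alpha=alpha, n_center=n_center, runs=df)


#: Fixed excipient percentages of the standardized formula.
DEFAULT_FIXED_EXCIPIENTS: dict[str, float] = {
    "aerosil": 0.14,
    "talc": 2.36,
    "aspartame": 1.0,
    "mg_stearate": 1.0,
}


@dataclass
class FormulationComposition:
    """Percent and milligram composition of one tablet formulation."""

    label: str
    percents: dict[str, float]  # all excipients, percent of tablet weight
    api_percent: float
    api_dose_mg: float
    tablet_weight_mg: float
    milligrams: dict[str, float]  # full precision

    def display(self, ndigits: int = 3) -> dict[str, float]:
        """Milligram entries and tablet weight truncated to ``ndigits``."""
        out = {k: truncate(v, ndigits) for k, v in self.milligrams.items()}
        out["api"] = self.api_dose_mg
        out["tablet_weight"] = truncate(self.tablet_weight_mg, ndigits)
        return out


def composition_from_point(
    ludipress_pct: float,
    croscarmellose_pct: float,
    fixed_excipients: Mapping[str, float] | None = None,
    api_dose_mg: float = 100.0,
    label: str = "",
) -> FormulationComposition:
    """Tablet composition implied by the two factor levels.

    The API takes the percentage left by all excipients, and the fixed API
    dose sets the tablet weight: ``weight = dose / (api% / 100)``.
    """
    fixed = dict(DEFAULT_FIXED_EXCIPIENTS if fixed_excipients is None else fixed_excipients)
    percents = {"ludipress": ludipress_pct, "croscarmellose": croscarmellose_pct, **fixed}
    total_excip = sum(percents.values())
    if total_excip >= 100:
        raise ValueError(
            f"excipients sum to {total_excip}% >= 100%; no room for the API"
        )
    if any(p < 0 for p in percents.values()):
        raise ValueError("negative excipient percentage")
    api_pct = 100.0 - total_excip
    weight = api_dose_mg / (api_pct / 100.0)
    mg = {name: p * weight / 100.0 for name, p in percents.items()}
    return FormulationComposition(
        label=label,
        percents=percents,
        api_percent=api_pct,
        api_dose_mg=api_dose_mg,
        tablet_weight_mg=weight,
        milligrams=mg,
    )


@dataclass(frozen=True)
class AnovaTable:
    """Regression ANOVA of the fitted surface against the intercept-only null."""

    df_model: int
    df_residual: int
    ss_model: float
    ss_residual: float
    ss_total: float
    ms_model: float
    ms_residual: float
    f_value: float
    p_value: float
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "df": [self.df_model, self.df_residual, self.df_model + self.df_residual],
                "SS": [self.ss_model, self.ss_residual, self.ss_total],
                "MS": [self.ms_model, self.ms_residual, np.nan],
                "F": [self.f_value, np.nan, np.nan],
                "p": [self.p_value, np.nan, np.nan],
            },
            index=["model", "residual", "total"],
        )


def _design_matrix(coded: np.ndarray, order: str) -> tuple[np.ndarray, list[str]]:
    c1, c2 = coded[:, 0], coded[:, 1]
    ones = np.ones_like(c1)
    if order == "linear":
        cols = [ones, c1, c2]
        names = ["const", "c1", "c2"]
    elif order == "quadratic":
        cols = [ones, c1, c2, c1 * c2, c1**2, c2**2]
        names = ["const", "c1", "c2", "c1:c2", "c1^2", "c2^2"]
    else:
        raise ValueError(f"order must be 'linear' or 'quadratic', got {order!r}")
    return np.column_stack(cols), names


class ResponseSurfaceModel:
    """OLS response-surface model on the coded factors of a CCD.

    Parameters
    ----------
    design : CCDesign or (n, 2) array of coded levels
    response : sequence of n response values
    order : "linear" or "quadratic"
    name : response name used in reports
    """

    def __init__(self, design, response, order: str = "linear", name: str = "y"):
        coded = design.coded if isinstance(design, CCDesign) else np.asarray(design, float)
        y = np.asarray(response, dtype=float)
        if coded.ndim != 2 or coded.shape[1] != 2:
            raise ValueError("design must provide two coded columns")
        if y.shape[0] != coded.shape[0]:
            raise ValueError("response length does not match number of runs")
        self.exog, self.exog_names = _design_matrix(coded, order)
        if y.shape[0] < self.exog.shape[1] + 1:
            raise ValueError(
                f"{order} model needs at least {self.exog.shape[1] + 1} runs"
            )
        rank = np.linalg.matrix_rank(self.exog)
        if rank < self.exog.shape[1]:
            # name the columns that add no rank when appended incrementally
            aliased, r_prev = [], 0
            for j in range(self.exog.shape[1]):
                r_now = np.linalg.matrix_rank(self.exog[:, : j + 1])
                if r_now == r_prev:
                    aliased.append(self.exog_names[j])
                r_prev = r_now
            raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
        self.endog = y
        self.order = order
        self.name = name

    def fit(self) -> "ResponseSurfaceResults":
        import statsmodels.api as sm

        res = sm.OLS(self.endog, self.exog).fit()
        return ResponseSurfaceResults(self, res)


class ResponseSurfaceResults:
    """Fit results: coefficients, ANOVA, adequate precision, prediction."""

    def __init__(self, model: ResponseSurfaceModel, sm_results):
        self.model = model
        self._sm = sm_results
        self.params = dict(zip(model.exog_names, sm_results.params))
        self.fittedvalues = np.asarray(sm_results.fittedvalues)
        self.resid = np.asarray(sm_results.resid)

    @property
    def r_squared(self) -> float:
        return float(self._sm.rsquared)

    def anova(self) -> AnovaTable:
        y = self.model.endog
        n, p = self.model.exog.shape
        ss_total = float(np.sum((y - y.mean()) ** 2))
        ss_res = float(np.sum(self.resid**2))
        ss_model = ss_total - ss_res
        df_model, df_res = p - 1, n - p
        ms_model = ss_model / df_model
        degenerate = ss_total <= 1e-12 or ms_model <= 0 or df_res <= 0
        if df_res > 0 and ss_res > 0 and not degenerate:
            ms_res = ss_res / df_res
            f = ms_model / ms_res
            pval = float(stats.f.sf(f, df_model, df_res))
        else:
            ms_res = ss_res / df_res if df_res > 0 else math.nan
            f = 0.0 if degenerate else math.inf
            pval = 1.0 if degenerate else 0.0
        return AnovaTable(
            df_model, df_res, ss_model, ss_res, ss_total, ms_model, ms_res,
            f, pval, degenerate=degenerate,
        )

    def adequate_precision(self) -> float:
        """Signal-to-noise: (fitted range) / sqrt(p * MS_res / n); > 4 adequate."""
        n, p = self.model.exog.shape
        an = self.anova()
        rng = float(self.fittedvalues.max() - self.fittedvalues.min())
        if an.df_residual <= 0 or an.ss_residual <= 0:
            return math.inf if rng > 0 else 0.0
        return rng / math.sqrt(p * an.ms_residual / n)

    def predict(self, coded) -> np.ndarray:
        X, _ = _design_matrix(np.atleast_2d(np.asarray(coded, float)), self.model.order)
        return X @ np.array([self.params[k] for k in self.model.exog_names])

    def prediction_variance(self, coded) -> np.ndarray:
        """Scaled prediction variance x' (X'X)^-1 x (unit error variance);
        constant on spheres about the center iff the design is rotatable."""
        X = self.model.exog
        xtx_inv = np.linalg.inv(X.T @ X)
        Xq, _ = _design_matrix(np.atleast_2d(np.asarray(coded, float)), self.model.order)
        return np.einsum("ij,jk,ik->i", Xq, xtx_inv, Xq)

    def summary(self) -> str:
        an = self.anova()
        lines = [
            f"Response surface fit: {self.model.name} ({self.model.order}, "
            f"n={len(self.model.endog)})",
            "coefficients (coded factors):",
        ]
        for k, v in self.params.items():
            lines.append(f"  {k:>6s}  {v: .6g}")
        lines += [
            f"R^2 = {self.r_squared:.4f}",
            f"ANOVA: F({an.df_model}, {an.df_residual}) = {an.f_value:.4g}, "
            f"p = {an.p_value:.4g}" + ("  [degenerate]" if an.degenerate else ""),
            f"adequate precision = {self.adequate_precision():.4g} "
            f"({'adequate' if self.adequate_precision() > 4 else 'inadequate'} signal)",
        ]
        return "\n".join(lines)


def fit_response_surface(
    design, response, order: str = "linear", name: str = "y"
) -> ResponseSurfaceResults:
    """Convenience wrapper: build and fit a :class:`ResponseSurfaceModel`."""
    return ResponseSurfaceModel(design, response, order=order, name=name).fit()


def adequate_precision(results: ResponseSurfaceResults) -> float:
    """Module-level alias of :meth:`ResponseSurfaceResults.adequate_precision`."""
    return results.adequate_precision()
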