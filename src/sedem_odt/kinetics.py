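"""Dissolution release-kinetics model fitting and selection.

Four classical models are fitted to cumulative-release profiles Qt(t)
(percent of label released, Q0 = 100% basis), all by least squares on the
release scale so their r-squared values are directly comparable:

* first order:      Qt = Q0 (1 - exp(-k1 t))
* Higuchi:          Qt = kH sqrt(t)
* Hixson-Crowell:   Q0^(1/3) - (Q0 - Qt)^(1/3) = kHC t
* Weibull:          Qt = Q0 (1 - exp(-(t - Ti)^beta / alpha)), Ti >= 0 lag

The first-order release convention (rather than the equivalent log-decay
regression of the remaining fraction) is the one dissolution add-ins use;
a log-linear decay fit is available via ``first_order_decay_fit`` for
comparison. Rate constants carry the time unit of the input grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DissolutionProfile",
    "KineticFitResult",
    "MODELS",
    "MODEL_N_PARAMS",
    "predict",
    "fit_model",
    "fit_all_models",
    "select_best_model",
    "first_order_decay_fit",
]

#: Sampling grid of the dissolution study, minutes.
DEFAULT_TIME_GRID: tuple[float, ...] = (2, 4, 6, 8, 10, 12, 15)

MODELS: tuple[str, ...] = ("first_order", "higuchi", "hixson_crowell", "weibull")
#: Free parameters per model (Weibull with the lag fixed at 0 fits two).
MODEL_N_PARAMS: dict[str, int] = {
    "first_order": 1,
    "higuchi": 1,
    "hixson_crowell": 1,
    "weibull": 2,
}


@dataclass
class DissolutionProfile:
    """Cumulative time-release data for one formulation."""

    times: np.ndarray  # minutes, strictly increasing, > 0
    release: np.ndarray  # percent of label released
    label: str = ""
    q0: float = 100.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.release = np.asarray(self.release, dtype=float)
        if self.times.shape != self.release.shape or self.times.ndim != 1:
            raise ValueError("times and release must be 1-D and the same length")
        if np.any(self.times <= 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be positive and strictly increasing")
        if np.any(self.release < 0) or np.any(self.release > 110):
            raise ValueError("release must lie in [0, 110] percent")

    def is_degenerate(self) -> bool:
        """All observations equal — no kinetics to fit."""
        return bool(np.all(self.release == self.release[0]))

    def trimmed(self) -> "DissolutionProfile":
        """Points below complete release plus the first at/above 100%.

        Log and cube-root release forms degenerate once dissolution is
        complete, so the plateau beyond the first complete point is dropped.
        """
        below = self.release < 100.0
        keep = below.copy()
        at_or_above = np.nonzero(~below)[0]
        if at_or_above.size:
            keep[at_or_above[0]] = True
            keep[at_or_above[1:]] = False
        return DissolutionProfile(
            self.times[keep], self.release[keep], label=self.label, q0=self.q0
        )


@dataclass(frozen=True)
class KineticFitResult:
    """A fitted release model with its goodness of fit."""

    model: str
    parameters: dict[str, float]
    r_squared: float
    fitted: np.ndarray
    profile_label: str = ""

    @property
    def n_params(self) -> int:
        return MODEL_N_PARAMS[self.model]

    def summary(self) -> str:
        pars = ", ".join(f"{k}={v:.6g}" for k, v in self.parameters.items())
        return (
            f"{self.model} fit{' of ' + self.profile_label if self.profile_label else ''}: "
            f"{pars}; r2={self.r_squared:.4f}"
        )


def predict(model: str, t, params: dict[str, float], q0: float = 100.0) -> np.ndarray:
    """Model curve Qt(t) on the release (percent) scale."""
    t = np.asarray(t, dtype=float)
    if model == "first_order":
        return q0 * (1.0 - np.exp(-params["k1"] * t))
    if model == "higuchi":
        return params["kH"] * np.sqrt(t)
    if model == "hixson_crowell":
        root = np.clip(q0 ** (1 / 3) - params["kHC"] * t, 0.0, None)
        return q0 - root**3
    if model == "weibull":
        ti = params.get("Ti", 0.0)
        tt = np.clip(t - ti, 0.0, None)
        return q0 * (1.0 - np.exp(-(tt ** params["beta"]) / params["alpha"]))
    raise ValueError(f"unknown model {model!r}")


def _r_squared(observed: np.ndarray, fitted: np.ndarray) -> float:
    ss_res = float(np.sum((observed - fitted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


def _fit_1param(profile, model: str, key: str, x0: float, upper: float) -> dict:
    def resid(p):
        return predict(model, profile.times, {key: p[0]}, profile.q0) - profile.release

    sol = least_squares(resid, x0=[x0], bounds=([0.0], [upper]))
    if not sol.success:
        raise RuntimeError(f"{model} fit failed to converge from {key}={x0}")
    return {key: float(sol.x[0])}


def fit_model(
    profile: DissolutionProfile,
    model: str,
    fit_lag: bool = False,
    trim_plateau: bool = True,
) -> KineticFitResult:
    """Least-squares fit of one release model on the release scale.

    Weibull uses bounded least squares from five deterministic starting
    points (the multistart guards against the shallow alpha/beta valley);
    ``fit_lag`` frees the lag time Ti (default pinned at 0: dissolution of
    an ODT starts immediately).
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    work = profile.trimmed() if trim_plateau else profile
    min_pts = 4 if model == "weibull" else 3
    if work.times.size < min_pts:
        raise ValueError(f"{model} needs at least {min_pts} points after trimming")
    if work.is_degenerate():
        raise ValueError("degenerate profile: all release values equal")
    t, y, q0 = work.times, work.release, work.q0

    if model == "higuchi":
        # linear through the origin in sqrt(t): closed form
        s = np.sqrt(t)
        params = {"kH": float(np.dot(s, y) / np.dot(s, s))}
    elif model == "first_order":
        frac = np.clip(1.0 - np.median(y) / q0, 1e-6, 1.0)
        x0 = max(-math.log(frac) / np.median(t), 1e-4)
        params = _fit_1param(work, "first_order", "k1", x0, np.inf)
    elif model == "hixson_crowell":
        upper = q0 ** (1 / 3) / t.max()  # beyond this the cube root goes negative
        params = _fit_1param(work, "hixson_crowell", "kHC", 0.5 * upper, upper)
    else:  # weibull
        params = _fit_weibull(work, fit_lag=fit_lag)

    return KineticFitResult(
        model=model,
        parameters=params,
        r_squared=_r_squared(y, predict(model, t, params, q0)),
        fitted=predict(model, profile.times, params, q0),
        profile_label=profile.label,
    )


_WEIBULL_STARTS = ((1.0, 3.0), (0.7, 3.5), (1.5, 5.0), (0.5, 1.0), (2.0, 10.0))


def _fit_weibull(profile: DissolutionProfile, fit_lag: bool) -> dict[str, float]:
    t, y, q0 = profile.times, profile.release, profile.q0

    def resid(p):
        if fit_lag:
            beta, alpha, ti = p
        else:
            (beta, alpha), ti = p, 0.0
        return predict("weibull", t, {"beta": beta, "alpha": alpha, "Ti": ti}, q0) - y

    best = None
    for beta0, alpha0 in _WEIBULL_STARTS:
        x0 = [beta0, alpha0, 0.0] if fit_lag else [beta0, alpha0]
        lo = [1e-3, 1e-3, 0.0][: len(x0)]
        hi = [10.0, 1e3, float(t[-1])] if fit_lag else [10.0, 1e3]
        sol = least_squares(resid, x0=x0, bounds=(lo, hi))
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise RuntimeError(
            f"weibull fit failed to converge; starts tried: {_WEIBULL_STARTS}"
        )
    out = {"beta": float(best.x[0]), "alpha": float(best.x[1])}
    if fit_lag:
        out["Ti"] = float(best.x[2])
    return out


def fit_all_models(
    profile: DissolutionProfile, models: Iterable[str] = MODELS, **kw
) -> list[KineticFitResult]:
    """Fit every requested model to the same profile."""
    return [fit_model(profile, m, **kw) for m in models]


def select_best_model(fits: Sequence[KineticFitResult]) -> str:
    """Best model by r-squared; exact ties go to the fewer-parameter model."""
    if not fits:
        raise ValueError("no fits to select from")
    best = max(fits, key=lambda f: (f.r_squared, -f.n_params))
    return best.model


def first_order_decay_fit(profile: DissolutionProfile) -> dict[str, float]:
    """Log-linear regression of the classical decay form
    ``ln(Q0 - Qt) = ln Q0 - k1 t`` (requires release strictly below Q0)."""
    work = profile.trimmed()
    remaining = work.q0 - work.release
    if np.any(remaining <= 0):
        raise ValueError("decay form needs release strictly below 100%")
    slope, intercept = np.polyfit(work.times, np.log(remaining), 1)
    return {"k1": float(-slope), "Q0_fit": float(np.exp(intercept))}
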