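"""Matplotlib figures: SeDeM radar diagrams, release-curve overlays and
stability regressions with their confidence band. All writers emit SVG."""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy import stats

from .kinetics import DissolutionProfile, KineticFitResult, predict
from .scoring import RadiusProfile
from .stability import ShelfLifeEstimate, StabilitySeries

__all__ = ["radar_diagram", "release_plot", "stability_plot"]

_PRETTY = {
    "Da": "Da", "Dc": "Dc", "Ie": "Ie", "IC": "IC%", "Icd": "Icd",
    "IH": "IH", "theta": "θ", "t_flow": 't"', "HR": "%HR", "H": "%H",
    "Pf": "%Pf", "Itheta": "Iθ", "effervescence": "Eff.",
    "DCD": "DCD", "DSD": "DSD",
}


def radar_diagram(profile: RadiusProfile, path: str | Path | None = None):
    """Classic SeDeM radar: radii on spokes, reference circle at r = 5."""
    params = profile.parameters
    n = len(params)
    r = profile.as_array()
    ang = np.pi / 2 - 2 * np.pi * np.arange(n + 1) / n
    rr = np.append(r, r[0])
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    theta = 2 * np.pi * np.arange(n + 1) / n
    ax.plot(theta, rr, "-o", lw=1.5, ms=3)
    ax.fill(theta, rr, alpha=0.25)
    ax.plot(np.linspace(0, 2 * np.pi, 200), np.full(200, 5.0), "--", color="gray",
            lw=1, label="acceptability (r = 5)")
    ax.set_xticks(theta[:-1])
    ax.set_xticklabels([_PRETTY.get(p, p) for p in params], fontsize=8)
    ax.set_ylim(0, max(10.0, float(r.max())))
    ax.set_title(profile.label)
    ax.legend(loc="lower right", bbox_to_anchor=(1.15, -0.1), fontsize=7)
    if path is not None:
        fig.savefig(path, format="svg", bbox_inches="tight")
        plt.close(fig)
        return None
    return fig


def release_plot(
    profile: DissolutionProfile,
    fits: Sequence[KineticFitResult],
    path: str | Path | None = None,
):
    """Observed release points with each fitted model curve overlaid."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(profile.times, profile.release, "ko", label="observed")
    tt = np.linspace(profile.times[0] * 0.2, profile.times[-1], 200)
    for fit in fits:
        ax.plot(tt, predict(fit.model, tt, fit.parameters, profile.q0),
                label=f"{fit.model} (r²={fit.r_squared:.3f})")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("cumulative release (%)")
    ax.set_title(profile.label or "dissolution profile")
    ax.legend(fontsize=8)
    if path is not None:
        fig.savefig(path, format="svg", bbox_inches="tight")
        plt.close(fig)
        return None
    return fig


def stability_plot(
    series: StabilitySeries,
    estimate: ShelfLifeEstimate,
    path: str | Path | None = None,
):
    """Assay points, fitted line, one-sided lower bound and the spec limit."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(series.months, series.assay, "ko", label="assay")
    t_end = (
        estimate.shelf_life_months * 1.1
        if estimate.is_finite
        else max(series.months.max() * 2, 12.0)
    )
    tt = np.linspace(0, t_end, 300)
    mean = estimate.intercept + estimate.slope * tt
    ax.plot(tt, mean, "-", label="fitted mean")
    n = series.months.size
    if estimate.residual_sd > 0 and n > 2:
        xbar = series.months.mean()
        sxx = float(np.sum((series.months - xbar) ** 2))
        tcrit = stats.t.ppf(estimate.confidence, n - 2)
        se = estimate.residual_sd * np.sqrt(1 / n + (tt - xbar) ** 2 / sxx)
        ax.plot(tt, mean - tcrit * se, "--",
                label=f"one-sided {estimate.confidence:.0%} lower bound")
    ax.axhline(estimate.spec_limit, color="red", lw=1,
               label=f"spec limit {estimate.spec_limit:g}%")
    if estimate.is_finite:
        ax.axvline(estimate.shelf_life_months, color="gray", ls=":",
                   label=f"shelf life {estimate.shelf_life_months:.1f} mo")
    ax.set_xlabel("months")
    ax.set_ylabel("assay (% label claim)")
    ax.set_title(series.label)
    ax.legend(fontsize=8)
    if path is not None:
        fig.savefig(path, format="svg", bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
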