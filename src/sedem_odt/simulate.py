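"""Seed-controlled synthetic data with the statistical structure each
pipeline stage assumes.

Every generator is a pure function of its configuration: the pseudo-random
stream is NumPy's PCG64 (``default_rng``), fixed here so fixtures are
reproducible across platforms. Defaults mirror the study conditions: the
7-point minute grid of the dissolution study, stability sampling at 0/3/6
months, and the 9-run rotatable central composite design.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import scoring
from .doe import CCDesign, FactorSpec, generate_ccd
from .kinetics import DEFAULT_TIME_GRID, DissolutionProfile, predict
from .scoring import DEFAULT_RULES, PowderParameterSet, RadiusProfile
from .stability import StabilitySeries

__all__ = [
    "GeneratorConfig",
    "gen_powder_set",
    "gen_dissolution",
    "gen_stability",
    "gen_response_surface",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Common plumbing for all generators: seed, size and noise level."""

    seed: int
    n: int = 1
    noise_sd: float = 0.0


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def gen_powder_set(
    seed: int,
    label: str = "synthetic",
    variant: str = "odt15",
    target_ipp: float | None = None,
    ranges: Mapping[str, tuple[float, float]] | None = None,
) -> PowderParameterSet:
    """Draw one powder parameter set within the SeDeM limit ranges.

    Without a target, each experimental value is uniform over its limit
    range. With ``target_ipp``, radii are drawn as N(target, 1) clipped to
    [0, 10] and mapped back through the inverse transforms, so the expected
    profile mean sits near the target. ``ranges`` pins or narrows individual
    parameters in value space (a zero-width range is a pin).
    """
    rng = _rng(seed)
    params = scoring.ODT15 if variant == "odt15" else scoring.CLASSIC12
    values: dict[str, float] = {}
    for name in params:
        rule = DEFAULT_RULES[name]
        if ranges is not None and name in ranges:
            lo, hi = ranges[name]
            values[name] = lo if lo == hi else float(rng.uniform(lo, hi))
        elif target_ipp is not None:
            r = float(np.clip(rng.normal(target_ipp, 1.0), 0.0, 10.0))
            values[name] = rule.from_radius(r)
        else:
            lo, hi = sorted((rule.lower_limit, rule.upper_limit))
            values[name] = float(rng.uniform(lo, hi))
    return PowderParameterSet(label=label, variant=variant, values=values)


def gen_dissolution(
    seed: int,
    model: str = "higuchi",
    params: Mapping[str, float] | None = None,
    times: Sequence[float] = DEFAULT_TIME_GRID,
    noise_sd: float = 0.0,
    label: str = "synthetic",
    q0: float = 100.0,
) -> DissolutionProfile:
    """Model curve on the sampling grid plus N(0, sd) noise, clipped to
    [0, 105]%. Warns when the generated profile is degenerate (e.g. a
    Weibull lag beyond the last sampling time gives all-zero release)."""
    if params is None:
        params = {"kH": 26.301}  # the fastest-releasing published profile
    t = np.asarray(times, dtype=float)
    curve = predict(model, t, dict(params), q0)
    rng = _rng(seed)
    if noise_sd > 0:
        curve = curve + rng.normal(0.0, noise_sd, size=t.shape)
    curve = np.clip(curve, 0.0, 105.0)
    profile = DissolutionProfile(t, curve, label=label, q0=q0)
    if profile.is_degenerate():
        warnings.warn(f"{label}: generated dissolution profile is degenerate",
                      stacklevel=2)
    return profile


def gen_stability(
    seed: int,
    slope: float = -0.2,
    intercept: float = 99.5,
    months: Sequence[float] = (0.0, 3.0, 6.0),
    noise_sd: float = 0.0,
    label: str = "synthetic",
) -> StabilitySeries:
    """Linear degradation signal plus N(0, sd) noise at the sampling months."""
    m = np.asarray(months, dtype=float)
    assay = intercept + slope * m
    rng = _rng(seed)
    if noise_sd > 0:
        assay = assay + rng.normal(0.0, noise_sd, size=m.shape)
    return StabilitySeries(label=label, months=m, assay=np.clip(assay, 1e-6, 110.0))


def gen_response_surface(
    seed: int,
    coefficients: Mapping[str, float] | None = None,
    design: CCDesign | None = None,
    noise_sd: float = 0.0,
) -> tuple[CCDesign, np.ndarray]:
    """Responses ``y = b0 + b1 c1 + b2 c2 (+ b12 c1 c2 + b11 c1^2 + b22 c2^2)
    + noise`` on the CCD runs. Missing coefficient keys default to 0."""
    if design is None:
        design = generate_ccd(
            (FactorSpec("ludipress", 52.0, 3.0), FactorSpec("croscarmellose", 3.0, 2.0))
        )
    b = {"b0": 0.0, "b1": 0.0, "b2": 0.0, "b12": 0.0, "b11": 0.0, "b22": 0.0}
    b.update(coefficients or {"b0": 3.1, "b1": 0.06, "b2": -0.02})
    c = design.coded
    y = (
        b["b0"]
        + b["b1"] * c[:, 0]
        + b["b2"] * c[:, 1]
        + b["b12"] * c[:, 0] * c[:, 1]
        + b["b11"] * c[:, 0] ** 2
        + b["b22"] * c[:, 1] ** 2
    )
    rng = _rng(seed)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return design, y
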