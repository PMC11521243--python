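"""SeDeM / SeDeM-ODT expert-system scoring of powders for direct compression.

The SeDeM method converts each measured rheological parameter of a powder
(bulk and tapped density, Carr index, Hausner ratio, angle of repose, ...)
to a dimensionless *radius* on a 0-10 scale, 10 being the value most
favourable for direct compression. Radii are grouped into *incidences*
(dimension, compressibility, flowability, lubricity/stability,
lubricity/dosage and — in the 15-parameter ODT variant — disgregability),
summarised by three indices:

* IP, the index parameter — fraction of radii at or above 5;
* IPP, the parameter profile index — the mean radius;
* IGC / IGCB — IPP multiplied by a polygon-to-circle reliability factor
  (0.952 for 12 parameters, 0.950 for 15); a value of 5 or more marks the
  powder as suitable for direct compression.

The module also provides the radar-polygon geometry behind the classic
SeDeM diagram and the corrective-excipient dose equation
``CP = 100 (RE - R) / (RE - RP)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._util import round_half_up

__all__ = [
    "Transform",
    "ParameterRule",
    "PowderParameterSet",
    "RadiusProfile",
    "IncidenceSet",
    "IndexSummary",
    "CorrectiveDoseInput",
    "CLASSIC12",
    "ODT15",
    "INCIDENCE_GROUPS",
    "DEFAULT_RULES",
    "RELIABILITY_FACTOR",
    "convert_parameters",
    "interparticle_porosity",
    "incidence_means",
    "index_summary",
    "corrective_dose",
    "radar_polygon",
    "regular_polygon_area",
]


class Transform(str, Enum):
    """How an experimental value maps onto the 0-10 radius scale."""

    SCALE_UP = "scale_up"  # r = 10 v / upper       (higher value is better)
    SCALE_DOWN = "scale_down"  # r = 10 - 10 v / upper  (lower value is better)
    HAUSNER = "hausner"  # r = 10 (3 - v) / 2      (limits 1..3, 1 is best)


@dataclass(frozen=True)
class ParameterRule:
    """Limit range and radius transform for one SeDeM parameter."""

    name: str
    unit: str
    lower_limit: float
    upper_limit: float
    transform: Transform
    incidence: str

    def to_radius(self, value: float) -> float:
        if self.transform is Transform.SCALE_UP:
            return 10.0 * value / self.upper_limit
        if self.transform is Transform.SCALE_DOWN:
            return 10.0 - 10.0 * value / self.upper_limit
        return 10.0 * (3.0 - value) / 2.0

    def from_radius(self, r: float) -> float:
        """Inverse of :meth:`to_radius` (exact round-trip)."""
        if self.transform is Transform.SCALE_UP:
            return r * self.upper_limit / 10.0
        if self.transform is Transform.SCALE_DOWN:
            return (10.0 - r) * self.upper_limit / 10.0
        return 3.0 - r / 5.0

    @property
    def best_value(self) -> float:
        """Experimental value mapping to radius 10."""
        return self.from_radius(10.0)

    @property
    def worst_value(self) -> float:
        """Experimental value mapping to radius 0."""
        return self.from_radius(0.0)


#: Canonical column order of the published tables; the first 12 form the
#: classic SeDeM set, all 15 the ODT set.
CLASSIC12: tuple[str, ...] = (
    "Da", "Dc", "Ie", "IC", "Icd", "IH", "theta", "t_flow",
    "HR", "H", "Pf", "Itheta",
)
ODT15: tuple[str, ...] = CLASSIC12 + ("effervescence", "DCD", "DSD")

INCIDENCE_GROUPS: dict[str, tuple[str, ...]] = {
    "dimension": ("Da", "Dc"),
    "compressibility": ("Ie", "IC", "Icd"),
    "flowability": ("IH", "theta", "t_flow"),
    "lubricity_stability": ("HR", "H"),
    "lubricity_dosage": ("Pf", "Itheta"),
    "disgregability": ("effervescence", "DCD", "DSD"),
}

_R = ParameterRule
DEFAULT_RULES: dict[str, ParameterRule] = {
    r.name: r
    for r in (
        _R("Da", "g/mL", 0.0, 1.0, Transform.SCALE_UP, "dimension"),
        _R("Dc", "g/mL", 0.0, 1.0, Transform.SCALE_UP, "dimension"),
        _R("Ie", "", 0.0, 1.2, Transform.SCALE_UP, "compressibility"),
        _R("IC", "%", 0.0, 50.0, Transform.SCALE_UP, "compressibility"),
        _R("Icd", "N", 0.0, 200.0, Transform.SCALE_UP, "compressibility"),
        _R("IH", "", 1.0, 3.0, Transform.HAUSNER, "flowability"),
        _R("theta", "deg", 0.0, 50.0, Transform.SCALE_DOWN, "flowability"),
        _R("t_flow", "s", 0.0, 20.0, Transform.SCALE_DOWN, "flowability"),
        _R("HR", "%", 0.0, 10.0, Transform.SCALE_DOWN, "lubricity_stability"),
        _R("H", "%", 0.0, 20.0, Transform.SCALE_DOWN, "lubricity_stability"),
        _R("Pf", "%", 0.0, 50.0, Transform.SCALE_DOWN, "lubricity_dosage"),
        _R("Itheta", "", 0.0, 0.02, Transform.SCALE_UP, "lubricity_dosage"),
        _R("effervescence", "min", 0.0, 5.0, Transform.SCALE_DOWN, "disgregability"),
        _R("DCD", "s", 0.0, 180.0, Transform.SCALE_DOWN, "disgregability"),
        _R("DSD", "s", 0.0, 180.0, Transform.SCALE_DOWN, "disgregability"),
    )
}

#: Polygon-to-circle reliability factor per variant.
RELIABILITY_FACTOR: dict[str, float] = {"classic12": 0.952, "odt15": 0.950}

_VARIANT_PARAMS: dict[str, tuple[str, ...]] = {"classic12": CLASSIC12, "odt15": ODT15}


def _variant_params(variant: str) -> tuple[str, ...]:
    try:
        return _VARIANT_PARAMS[variant]
    except KeyError:
        raise ValueError(
            f"unknown variant {variant!r}; expected 'classic12' or 'odt15'"
        ) from None


@dataclass
class PowderParameterSet:
    """Experimental SeDeM measurements for one material or blend."""

    label: str
    variant: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        params = _variant_params(self.variant)
        missing = [p for p in params if p not in self.values]
        if missing:
            raise ValueError(f"{self.label}: missing parameter(s) {missing}")
        for name, v in self.values.items():
            if not math.isfinite(v):
                raise ValueError(f"{self.label}: non-finite value for {name}")
            if v < 0:
                raise ValueError(f"{self.label}: negative value for {name}: {v}")

    @property
    def parameters(self) -> tuple[str, ...]:
        return _variant_params(self.variant)


@dataclass
class RadiusProfile:
    """Per-parameter 0-10 radii for one material, in canonical order."""

    label: str
    variant: str
    radii: dict[str, float]
    cap_applied: bool = False

    def __post_init__(self) -> None:
        params = _variant_params(self.variant)
        if set(self.radii) != set(params):
            raise ValueError(
                f"{self.label}: radius keys {sorted(self.radii)} do not match "
                f"variant {self.variant!r}"
            )
        for name, r in self.radii.items():
            if not math.isfinite(r) or r < 0:
                raise ValueError(f"{self.label}: invalid radius for {name}: {r}")
            if self.cap_applied and r > 10:
                raise ValueError(f"{self.label}: capped profile has radius > 10")

    @property
    def parameters(self) -> tuple[str, ...]:
        return _variant_params(self.variant)

    def as_array(self) -> np.ndarray:
        """Radii in canonical parameter order."""
        return np.array([self.radii[p] for p in self.parameters])


@dataclass(frozen=True)
class IncidenceSet:
    """Arithmetic mean radius per incidence group (full precision)."""

    label: str
    means: dict[str, float]

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        return {k: round_half_up(v, ndigits) for k, v in self.means.items()}


@dataclass(frozen=True)
class IndexSummary:
    """Global SeDeM indices for one profile.

    ``ip``, ``ipp`` and ``index`` are reported rounded to two decimals, the
    table convention; the unrounded mean is kept in ``ipp_full`` and the
    product IPP x f is formed from it before rounding.
    """

    label: str
    variant: str
    ip: float
    ipp: float
    ipp_full: float
    reliability_factor: float
    index: float  # IGC (classic12) or IGCB (odt15)
    verdict: str

    @property
    def index_name(self) -> str:
        return "IGC" if self.variant == "classic12" else "IGCB"


@dataclass(frozen=True)
class CorrectiveDoseInput:
    """Inputs of the corrective-excipient dose equation."""

    re_radius: float  # excipient incidence radius (RE)
    rp_radius: float  # API incidence radius (RP)
    target: float = 5.0  # radius the blend must reach (R)


def interparticle_porosity(da: float, dc: float) -> float:
    """Ie = (Dc - Da) / (Dc * Da) from bulk (Da) and tapped (Dc) density."""
    if da <= 0 or dc <= 0:
        raise ValueError("densities must be positive")
    return (dc - da) / (dc * da)


def convert_parameters(
    params: PowderParameterSet,
    rules: Mapping[str, ParameterRule] | None = None,
    cap: bool = False,
) -> RadiusProfile:
    """Convert experimental values to 0-10 radii.

    With ``cap`` off (the default, matching the published tables where a
    radius of 10.19 appears) radii may exceed 10; with ``cap`` on they are
    clipped to 10. Radii below 0 (value beyond the worst limit) are clipped
    to 0 with a warning in either mode.
    """
    rules = dict(DEFAULT_RULES) if rules is None else dict(rules)
    radii: dict[str, float] = {}
    for name in params.parameters:
        if name not in rules:
            raise ValueError(f"no conversion rule for parameter {name!r}")
        rule = rules[name]
        v = params.values[name]
        lo, hi = sorted((rule.lower_limit, rule.upper_limit))
        if not (lo <= v <= hi):
            warnings.warn(
                f"{params.label}: {name}={v} outside limit range [{lo}, {hi}]",
                stacklevel=2,
            )
        r = rule.to_radius(v)
        if r < 0:
            warnings.warn(
                f"{params.label}: {name} beyond worst limit; radius clipped to 0",
                stacklevel=2,
            )
            r = 0.0
        if cap and r > 10:
            r = 10.0
        radii[name] = r
    return RadiusProfile(params.label, params.variant, radii, cap_applied=cap)


def incidence_means(profile: RadiusProfile) -> IncidenceSet:
    """Mean radius of each incidence group present in the profile's variant."""
    present = set(profile.parameters)
    means = {
        group: float(np.mean([profile.radii[p] for p in members]))
        for group, members in INCIDENCE_GROUPS.items()
        if set(members) <= present
    }
    return IncidenceSet(profile.label, means)


def index_summary(
    profile: RadiusProfile, f: float | None = None, threshold: float = 5.0
) -> IndexSummary:
    """Compute IP, IPP and IGC/IGCB with the acceptability verdict.

    A radius exactly at the threshold counts as acceptable for IP. The
    verdict bands are "A" (index >= 5), "corrigible" (3 <= index < 5) and
    "inadequate" (< 3).
    """
    if f is None:
        f = RELIABILITY_FACTOR[profile.variant]
    if not 0 < f <= 1:
        raise ValueError(f"reliability factor must be in (0, 1], got {f}")
    r = profile.as_array()
    if r.size == 0:
        raise ValueError("empty radius profile")
    ipp_full = float(r.mean())
    ip = float((r >= threshold).sum()) / r.size
    index = ipp_full * f
    verdict = "A" if index >= 5 else ("corrigible" if index >= 3 else "inadequate")
    return IndexSummary(
        label=profile.label,
        variant=profile.variant,
        ip=round_half_up(ip, 2),
        ipp=round_half_up(ipp_full, 2),
        ipp_full=ipp_full,
        reliability_factor=f,
        index=round_half_up(index, 2),
        verdict=verdict,
    )


def corrective_dose(inp: CorrectiveDoseInput) -> float:
    """Corrective-excipient dose equation ``CP = 100 (RE - R) / (RE - RP)``.

    Under ideal linear blending of incidence radii, CP is the percentage of
    the blend at which the deficient incidence just reaches the target R:
    CP parts carry radius RP and the remaining 100 - CP parts radius RE, so
    CP is the maximum share of the deficient component (the API) and
    ``100 - CP`` the minimum share of the corrective excipient. Returns 0
    when the API already meets the target; raises when the excipient cannot
    correct (RE <= RP, or RE <= R).
    """
    re_, rp, r0 = inp.re_radius, inp.rp_radius, inp.target
    if re_ <= rp:
        raise ValueError(
            f"excipient radius RE={re_} must exceed API radius RP={rp} "
            "for a correction to exist"
        )
    if rp >= r0:
        return 0.0
    if re_ <= r0:
        raise ValueError(
            f"excipient radius RE={re_} does not reach the target {r0}; "
            "it cannot correct the blend"
        )
    cp = 100.0 * (re_ - r0) / (re_ - rp)
    if cp > 100.0:
        warnings.warn("corrective dose formula exceeded 100%; clamped", stacklevel=2)
        cp = 100.0
    return cp


def radar_polygon(
    profile: RadiusProfile | Sequence[float],
) -> tuple[np.ndarray, float]:
    """Vertices and area of the SeDeM radar polygon.

    Vertex *k* sits at angle ``pi/2 - 2 pi k / n`` (first parameter at the
    top, clockwise, the diagram convention) with radius ``r_k``. The area is
    the shoelace formula; for a constant radius R0 it reduces to the regular
    polygon area ``(n/2) sin(2 pi / n) R0**2``.

    Returns ``(vertices, area)`` with vertices of shape (n, 2).
    """
    r = profile.as_array() if isinstance(profile, RadiusProfile) else np.asarray(
        profile, dtype=float
    )
    n = r.size
    if n < 3:
        raise ValueError("a radar polygon needs at least 3 radii")
    ang = np.pi / 2 - 2 * np.pi * np.arange(n) / n
    verts = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
    x, y = verts[:, 0], verts[:, 1]
    area = 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
    return verts, area


def regular_polygon_area(n: int, radius: float) -> float:
    """Closed-form area of a regular n-gon with circumradius ``radius``."""
    return 0.5 * n * math.sin(2 * math.pi / n) * radius**2
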