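"""Compendial-style quality checks for orally disintegrating tablet batches.

The checks mirror routine tablet release testing: weight variation within a
pharmacopoeial percentage tier about the batch mean (7.5% for tablets in
the 130-324 mg band), friability below 1% mass loss, disintegration within
the 3-minute ODT limit, and assay within a configurable label-claim band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "BatchMeasurements",
    "TestVerdict",
    "QualityReport",
    "weight_variation",
    "limit_checks",
]


@dataclass
class BatchMeasurements:
    """Measured attributes of one tablet batch; missing fields are skipped."""

    label: str
    tablet_weights_mg: Sequence[float] | None = None
    thickness_mm: float | None = None
    hardness_kg: float | None = None
    friability_pct: float | None = None
    disintegration_s: float | None = None
    wetting_s: float | None = None
    assay_pct: float | None = None
    dissolution_pct: float | None = None


@dataclass(frozen=True)
class TestVerdict:
    test: str
    measured: float | str
    limit: str
    passed: bool | None  # None when not evaluated

    def __str__(self) -> str:
        status = {True: "pass", False: "FAIL", None: "not evaluated"}[self.passed]
        return f"{self.test}: {self.measured} (limit {self.limit}) -> {status}"


@dataclass
class QualityReport:
    label: str
    verdicts: list[TestVerdict]

    @property
    def overall_pass(self) -> bool:
        """True iff every evaluated test passed."""
        evaluated = [v.passed for v in self.verdicts if v.passed is not None]
        return bool(evaluated) and all(evaluated)

    def summary(self) -> str:
        lines = [f"Quality report for {self.label}:"]
        lines += [f"  {v}" for v in self.verdicts]
        lines.append(f"  overall: {'pass' if self.overall_pass else 'FAIL'}")
        return "\n".join(lines)


def weight_variation(
    weights: Sequence[float], tolerance_pct: float = 7.5
) -> TestVerdict:
    """Every tablet within ``tolerance_pct`` of the batch mean weight."""
    w = np.asarray(weights, dtype=float)
    if w.size < 2:
        raise ValueError("weight variation needs at least 2 tablets")
    mean = float(w.mean())
    max_dev = float(np.max(np.abs(w - mean)) / mean * 100.0)
    return TestVerdict(
        test="weight_variation",
        measured=round(max_dev, 3),
        limit=f"max deviation <= {tolerance_pct}% of mean",
        passed=max_dev <= tolerance_pct,
    )


def limit_checks(
    batch: BatchMeasurements,
    friability_limit: float = 1.0,
    disintegration_limit_s: float = 180.0,
    assay_band: tuple[float, float] = (95.0, 105.0),
    weight_tolerance_pct: float = 7.5,
) -> QualityReport:
    """Assemble the per-batch quality report; absent fields are marked
    "not evaluated" rather than failed."""
    verdicts: list[TestVerdict] = []

    if batch.tablet_weights_mg is not None and len(batch.tablet_weights_mg) >= 2:
        verdicts.append(weight_variation(batch.tablet_weights_mg, weight_tolerance_pct))
    else:
        verdicts.append(
            TestVerdict("weight_variation", "n/a", f"<= {weight_tolerance_pct}%", None)
        )

    def check(test, value, limit_txt, ok):
        verdicts.append(
            TestVerdict(test, "n/a" if value is None else value, limit_txt,
                        None if value is None else ok)
        )

    f = batch.friability_pct
    check("friability", f, f"< {friability_limit}%", None if f is None else f < friability_limit)
    d = batch.disintegration_s
    check("disintegration", d, f"< {disintegration_limit_s:g} s",
          None if d is None else d < disintegration_limit_s)
    a = batch.assay_pct
    check("assay", a, f"{assay_band[0]:g}-{assay_band[1]:g}%",
          None if a is None else assay_band[0] <= a <= assay_band[1])
    return QualityReport(label=batch.label, verdicts=verdicts)
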