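"""The full study workflow as one configurable run.

Stage order follows the development workflow: SeDeM scoring of the raw
materials and blends, central composite design and tablet compositions,
tablet quality checks, dissolution release-kinetics model selection, and
stability shelf-life estimation. By default every stage runs on the shipped
study tables; any stage can instead be pointed at user CSV files.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Any

import numpy as np
from pydantic import BaseModel, Field

from . import datasets, io
from .doe import FactorSpec, composition_from_point, generate_ccd
from .kinetics import MODELS, KineticFitResult, fit_all_models, select_best_model
from .quality import limit_checks
from .scoring import (
    RELIABILITY_FACTOR,
    incidence_means,
    index_summary,
    radar_polygon,
)
from .stability import estimate_shelf_life

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("sedem_odt")


class FactorConfig(BaseModel):
    name: str
    center: float
    step: float


class PipelineConfig(BaseModel):
    """Settings of every stage; the defaults reproduce the study's."""

    variant: str = "odt15"
    reliability_factors: dict[str, float] = Field(
        default_factory=lambda: dict(RELIABILITY_FACTOR)
    )
    factors: list[FactorConfig] = Field(
        default_factory=lambda: [
            FactorConfig(name="ludipress", center=52.0, step=3.0),
            FactorConfig(name="croscarmellose", center=3.0, step=2.0),
        ]
    )
    alpha: float = 2.0**0.5
    n_center: int = 1
    api_dose_mg: float = 100.0
    kinetic_models: list[str] = Field(default_factory=lambda: list(MODELS))
    spec_limit: float = 90.0
    confidence: float = 0.95
    horizon_months: float = 600.0
    assay_band: tuple[float, float] = (95.0, 105.0)
    # optional user inputs; None -> shipped study tables
    powder_csv: str | None = None
    powder_mode: str = "radii"
    dissolution_csv: str | None = None
    stability_csv: str | None = None
    output_dir: str | None = None
    svg: bool = False


def _score_stage(cfg: PipelineConfig) -> dict[str, Any]:
    if cfg.powder_csv is not None:
        items = io.read_powder_csv(cfg.powder_csv, cfg.variant, mode=cfg.powder_mode)
        if cfg.powder_mode == "values":
            from .scoring import convert_parameters

            items = [convert_parameters(p) for p in items]
        profiles = items
    else:
        profiles = datasets.radius_profiles("classic12") + datasets.radius_profiles(
            "odt15"
        )
    out = {}
    for prof in profiles:
        f = cfg.reliability_factors[prof.variant]
        summ = index_summary(prof, f=f)
        _, area = radar_polygon(prof)
        out[prof.label] = {
            "variant": prof.variant,
            "incidences": incidence_means(prof).rounded(),
            "IP": summ.ip,
            "IPP": summ.ipp,
            summ.index_name: summ.index,
            "verdict": summ.verdict,
            "polygon_area": round(area, 3),
        }
    return out


def _design_stage(cfg: PipelineConfig) -> dict[str, Any]:
    design = generate_ccd(
        [FactorSpec(f.name, f.center, f.step) for f in cfg.factors],
        alpha=cfg.alpha,
        n_center=cfg.n_center,
    )
    disp = design.display()
    f1, f2 = cfg.factors[0].name, cfg.factors[1].name
    rows = {}
    for _, row in disp.iterrows():
        comp = composition_from_point(
            row[f"{f1}_pct"], row[f"{f2}_pct"], api_dose_mg=cfg.api_dose_mg,
            label=row["run"],
        )
        rows[row["run"]] = {
            "coded": [row["c1"], row["c2"]],
            f"{f1}_pct": row[f"{f1}_pct"],
            f"{f2}_pct": row[f"{f2}_pct"],
            "api_percent": round(comp.api_percent, 6),
            "milligrams": comp.display(),
        }
    return rows


def _quality_stage(cfg: PipelineConfig) -> dict[str, Any]:
    out = {}
    for batch in datasets.quality_batches():
        rep = limit_checks(batch, assay_band=cfg.assay_band)
        out[batch.label] = {
            "tests": {
                v.test: {"measured": v.measured, "limit": v.limit, "pass": v.passed}
                for v in rep.verdicts
            },
            "overall_pass": rep.overall_pass,
        }
    return out


def _kinetics_stage(cfg: PipelineConfig, outdir: Path | None) -> dict[str, Any]:
    out: dict[str, Any] = {}
    if cfg.dissolution_csv is not None:
        profiles = io.read_dissolution_csv(cfg.dissolution_csv)
        for prof in profiles:
            fits = fit_all_models(prof, cfg.kinetic_models)
            out[prof.label] = {
                "best_model": select_best_model(fits),
                "fits": {
                    f.model: {"r_squared": round(f.r_squared, 4), **f.parameters}
                    for f in fits
                },
            }
            if cfg.svg and outdir is not None:
                from .plotting import release_plot

                release_plot(prof, fits, outdir / f"kinetics_{prof.label}.svg")
    else:
        # published fits: select the best model from the tabulated r-squared
        table = datasets.load_kinetics_table()
        for _, row in table.iterrows():
            fits = [
                KineticFitResult(m, {}, float(row[f"{m}_r2"]), np.empty(0))
                for m in ("first_order", "higuchi", "hixson_crowell", "weibull")
            ]
            out[row["formulation"]] = {
                "best_model": select_best_model(fits),
                "r_squared": {f.model: f.r_squared for f in fits},
            }
    return out


def _stability_stage(cfg: PipelineConfig, outdir: Path | None) -> dict[str, Any]:
    series = (
        io.read_stability_csv(cfg.stability_csv)
        if cfg.stability_csv is not None
        else datasets.stability_series()
    )
    out = {}
    for s in series:
        est = estimate_shelf_life(
            s, spec_limit=cfg.spec_limit, confidence=cfg.confidence,
            horizon=cfg.horizon_months,
        )
        out[s.label] = {
            "slope_pct_per_month": round(est.slope, 6),
            "intercept_pct": round(est.intercept, 6),
            "shelf_life_months": round(est.shelf_life_months, 3)
            if est.is_finite
            else "inf",
            "mean_crossing_months": round(est.mean_crossing_months, 3)
            if np.isfinite(est.mean_crossing_months)
            else "inf",
        }
        if cfg.svg and outdir is not None:
            from .plotting import stability_plot

            stability_plot(s, est, outdir / f"stability_{s.label}.svg")
    return out


def run_pipeline(config: PipelineConfig | None = None) -> dict[str, Any]:
    """Run every stage and return the machine-readable report.

    Stage failures are collected (not raised) under ``errors`` so one bad
    input does not mask the remaining stages; callers treating the run as a
    unit should check that ``errors`` is empty.
    """
    cfg = config or PipelineConfig()
    outdir = Path(cfg.output_dir) if cfg.output_dir else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"config": cfg.model_dump(mode="json"), "errors": {}}
    stages = {
        "sedem_scores": lambda: _score_stage(cfg),
        "design": lambda: _design_stage(cfg),
        "quality": lambda: _quality_stage(cfg),
        "kinetics": lambda: _kinetics_stage(cfg, outdir),
        "stability": lambda: _stability_stage(cfg, outdir),
    }
    for name, stage in stages.items():
        try:
            report[name] = stage()
            log.info("stage %s complete", name)
        except Exception as exc:  # noqa: BLE001 - aggregated per stage
            log.error("stage %s failed: %s", name, exc)
            report["errors"][name] = f"{type(exc).__name__}: {exc}"
    if outdir is not None:
        io.write_json_report(report, outdir / "report.json")
    return report
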