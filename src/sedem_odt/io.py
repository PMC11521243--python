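"""Readers and writers for the pipeline's delimited-text interfaces.

All CSV files are UTF-8, comma-separated, with a mandatory header row and
decimal points; percentages are on the 0-100 scale throughout. JSON reports
are written with sorted keys and no timestamps, so re-running on identical
inputs yields byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .kinetics import DissolutionProfile
from .scoring import PowderParameterSet, RadiusProfile, _variant_params
from .stability import StabilitySeries

__all__ = [
    "read_powder_csv",
    "read_dissolution_csv",
    "read_stability_csv",
    "read_responses_csv",
    "write_json_report",
]


def read_powder_csv(
    path: str | Path, variant: str = "odt15", mode: str = "values"
) -> list[PowderParameterSet] | list[RadiusProfile]:
    """One row per material; columns = parameter names (plus ``label``).

    ``mode="values"`` reads experimental values, ``mode="radii"`` reads
    pre-converted radii directly.
    """
    df = pd.read_csv(path, comment="#")
    if "label" not in df.columns:
        raise ValueError(f"{path}: missing required 'label' column")
    params = _variant_params(variant)
    missing = [p for p in params if p not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing parameter column(s) {missing}")
    out: list[Any] = []
    for _, row in df.iterrows():
        data = {p: float(row[p]) for p in params}
        if mode == "values":
            out.append(PowderParameterSet(str(row["label"]), variant, data))
        elif mode == "radii":
            out.append(RadiusProfile(str(row["label"]), variant, data))
        else:
            raise ValueError(f"mode must be 'values' or 'radii', got {mode!r}")
    return out


def read_dissolution_csv(path: str | Path) -> list[DissolutionProfile]:
    """Long format: columns label, time_min, release_pct."""
    df = pd.read_csv(path, comment="#")
    required = {"label", "time_min", "release_pct"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: needs columns {sorted(required)}")
    return [
        DissolutionProfile(
            grp.sort_values("time_min")["time_min"].to_numpy(float),
            grp.sort_values("time_min")["release_pct"].to_numpy(float),
            label=str(label),
        )
        for label, grp in df.groupby("label", sort=True)
    ]


def read_stability_csv(path: str | Path) -> list[StabilitySeries]:
    """Long format: columns label, month, assay_pct."""
    df = pd.read_csv(path, comment="#")
    required = {"label", "month", "assay_pct"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: needs columns {sorted(required)}")
    return [
        StabilitySeries(
            label=str(label),
            months=grp.sort_values("month")["month"].to_numpy(float),
            assay=grp.sort_values("month")["assay_pct"].to_numpy(float),
        )
        for label, grp in df.groupby("label", sort=True)
    ]


def read_responses_csv(path: str | Path) -> pd.DataFrame:
    """Run label plus one column per response (hardness, disintegration, ...)."""
    df = pd.read_csv(path, comment="#")
    if "run" not in df.columns:
        raise ValueError(f"{path}: missing required 'run' column")
    return df


def _jsonify(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return _jsonify(obj.item())
    if isinstance(obj, float) and not math.isfinite(obj):
        return str(obj)  # "inf" / "-inf" / "nan" — keep the report strict JSON
    return obj


def write_json_report(report: dict, path: str | Path) -> None:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonify(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
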