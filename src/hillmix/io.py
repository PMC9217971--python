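"""Reading dose-effect tables, run configuration, and result serialisation.

Tables are delimited text (comma or tab, autodetected) with a header row;
one dose column per compound and one effect column.  Effects may be given
as fractions or percentages (``effect_scale``).  Results serialise to JSON
at full double precision; configs load from YAML or JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import FitResult, ParameterMask
from .models import HillCurve
from .table import DoseResponseTable

__all__ = [
    "RunConfig",
    "read_table",
    "fit_result_to_dict",
    "write_fit_result",
    "read_fit_result_dict",
    "curve_to_dict",
    "curve_from_dict",
]

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Configuration of a fitting/analysis run.

    ``compound_columns`` maps compound name -> input column name (identity
    by default); ``effect_scale`` is ``"fraction"`` or ``"percent"``
    (percent values are divided by 100 exactly once, on read).
    """

    input: str = ""
    compounds: list[str] = field(default_factory=list)
    compound_columns: dict[str, str] = field(default_factory=dict)
    effect_column: str = "effect"
    effect_scale: str = "fraction"
    units: str = ""
    pure_curves: dict[str, dict] = field(default_factory=dict)
    fix_e0: float | None = None
    fix_emax: float | None = None
    start_mask: list[str] | None = None
    bounds: dict[str, list[float]] = field(default_factory=dict)
    grid_points: int | None = None
    seed: int = 0
    n_starts: int = 16
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.effect_scale not in ("fraction", "percent"):
            raise ValueError("effect_scale must be 'fraction' or 'percent'")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


def read_table(path: str | Path, config: RunConfig | None = None) -> DoseResponseTable:
    """Read and validate a delimited dose-effect table.

    Raises descriptive errors (with row numbers) for missing columns,
    negative doses, and effects outside [0, 1] after scaling.
    """
    cfg = config or RunConfig()
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    compounds = cfg.compounds or [c for c in df.columns if c != cfg.effect_column]
    colmap = {c: cfg.compound_columns.get(c, c) for c in compounds}
    missing = [col for col in list(colmap.values()) + [cfg.effect_column] if col not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    doses = df[[colmap[c] for c in compounds]].to_numpy(dtype=float)
    effects = df[cfg.effect_column].to_numpy(dtype=float)
    if cfg.effect_scale == "percent":
        effects = effects / 100.0
    bad = np.where((doses < 0).any(axis=1))[0]
    if bad.size:
        raise ValueError(f"{path}: negative dose in row(s) {(bad + 2).tolist()} (file line numbers)")
    bad = np.where((effects < 0) | (effects > 1))[0]
    if bad.size:
        raise ValueError(
            f"{path}: effect outside [0, 1] in row(s) {(bad + 2).tolist()} "
            f"(file line numbers; scale={cfg.effect_scale})"
        )
    return DoseResponseTable(compounds, doses, effects, cfg.units or "")


# ---------------------------------------------------------------------------
# result serialisation
# ---------------------------------------------------------------------------

def curve_to_dict(curve: HillCurve) -> dict:
    return {
        "name": curve.name,
        "e0": curve.e0,
        "emax": curve.emax,
        "ec50": curve.ec50,
        "slope": curve.slope,
    }


def curve_from_dict(d: dict) -> HillCurve:
    return HillCurve(d["name"], d["e0"], d["emax"], d["ec50"], d["slope"])


def fit_result_to_dict(fr: FitResult) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "compounds": fr.model.names,
        "curves": [curve_to_dict(c) for c in fr.model.curves],
        "mask": sorted(fr.mask.active),
        "params": fr.params,
        "stderr": fr.stderr,
        "rss": fr.rss,
        "rmse": fr.rmse,
        "adjusted_r2": fr.adjusted_r2,
        "aic": fr.aic,
        "mw_p": fr.mw_p,
        "shapiro_p": fr.shapiro_p,
        "n_obs": fr.n_obs,
        "n_params": fr.n_params,
        "subset_rmse": fr.subset_rmse,
        "trail": fr.trail,
        "predicted": np.asarray(fr.predicted).tolist(),
    }


def write_fit_result(fr: FitResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(fit_result_to_dict(fr), fh, indent=1)


def read_fit_result_dict(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
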