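"""Batch processing: measurement tables in, tidy results table out.

Input is a long-format delimited table — one measurement per row — with a
leaf id, a group/genotype label, an abscissa (thermal time in °Cd, a
calendar day to be converted via a temperature log, or a position along
the leaf axis in mm) and a value (leaf length in mm or cell length in μm).
Each leaf is fitted independently; every input leaf yields exactly one
output row, with failures flagged rather than aborting the batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import derived, thermal_time
from .derived import DeriveConfig
from .errors import InputDataError
from .fitting import (
    MIN_GROWTH_POINTS,
    MIN_PROFILE_POINTS,
    CellProfile,
    FitOptions,
    LeafSeries,
    fit_cell_profile,
    fit_growth,
    pool_series,
)

__all__ = [
    "Schema",
    "BatchConfig",
    "ExperimentTable",
    "ResultsTable",
    "read_measurements",
    "run_batch",
    "write_results",
    "wide_to_long",
]

log = logging.getLogger(__name__)

_DEFAULT_COLS = {
    "growth": ("thermal_time", "length"),
    "cells": ("position", "cell_length"),
}


@dataclass(frozen=True)
class Schema:
    """Column names of the long-format input table."""

    id_col: str = "leaf_id"
    group_col: str = "group"
    x_col: str | None = None  # default depends on mode
    y_col: str | None = None

    def resolved(self, mode: str) -> tuple[str, str, str, str]:
        x_default, y_default = _DEFAULT_COLS[mode]
        return (
            self.id_col,
            self.group_col,
            self.x_col or x_default,
            self.y_col or y_default,
        )


@dataclass
class BatchConfig:
    """Everything run_batch needs besides the data."""

    derive: DeriveConfig = field(default_factory=DeriveConfig)
    fit: FitOptions = field(default_factory=FitOptions)
    family: str = "beta"
    pool_groups: bool = False
    temperature_log: thermal_time.TemperatureLog | None = None
    base_temp: float | None = None


class ExperimentTable:
    """Validated collection of series keyed by leaf id."""

    def __init__(self, mode: str, series: dict, rejected: list) -> None:
        self.mode = mode
        self.series = series
        self.rejected = rejected  # list of (leaf_id, reason)

    def __len__(self) -> int:
        return len(self.series)


class ResultsTable:
    """One row per input leaf plus run metadata."""

    def __init__(self, df: pd.DataFrame, metadata: dict) -> None:
        self.df = df
        self.metadata = metadata

    def __len__(self) -> int:
        return len(self.df)


def read_measurements(
    path,
    mode: str = "growth",
    schema: Schema | None = None,
    sep: str | None = None,
) -> ExperimentTable:
    """Read and validate a long-format measurement table.

    Rows that fail validation (unparseable numerics, negative lengths) are
    dropped with a logged reason; a series with duplicate abscissa values
    is rejected whole; a series left with too few points is rejected.  An
    empty result is an error.
    """
    if mode not in _DEFAULT_COLS:
        raise InputDataError(f"mode must be 'growth' or 'cells', got {mode!r}")
    schema = schema or Schema()
    id_col, group_col, x_col, y_col = schema.resolved(mode)
    df = pd.read_csv(path, sep=sep, engine="python")
    missing = [c for c in (id_col, group_col, x_col, y_col) if c not in df.columns]
    if missing:
        raise InputDataError(f"missing columns in {path}: {missing}")

    df = df.copy()
    for col in (x_col, y_col):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    min_points = MIN_GROWTH_POINTS if mode == "growth" else MIN_PROFILE_POINTS
    series: dict = {}
    rejected: list = []
    for (leaf_id, group), sub in df.groupby([id_col, group_col], sort=True):
        leaf_id = str(leaf_id)
        sub = sub.sort_values(x_col, kind="stable")
        bad = sub[x_col].isna() | sub[y_col].isna()
        if mode == "growth":
            bad |= sub[y_col] < 0
        else:
            bad |= sub[y_col] <= 0
        for _, row in sub[bad].iterrows():
            log.warning("leaf %s: dropped row (%s=%r, %s=%r)", leaf_id,
                        x_col, row[x_col], y_col, row[y_col])
        sub = sub[~bad]
        if sub[x_col].duplicated().any():
            rejected.append((leaf_id, "duplicate abscissa values"))
            continue
        if len(sub) < min_points:
            rejected.append((leaf_id, f"fewer than {min_points} valid points"))
            continue
        try:
            if mode == "growth":
                obj: object = LeafSeries(leaf_id, str(group),
                                         sub[x_col].to_numpy(),
                                         sub[y_col].to_numpy())
            else:
                obj = CellProfile(leaf_id, str(group),
                                  sub[x_col].to_numpy(),
                                  sub[y_col].to_numpy())
        except InputDataError as exc:
            rejected.append((leaf_id, str(exc)))
            continue
        series[leaf_id] = obj
    for leaf_id, reason in rejected:
        log.warning("leaf %s rejected: %s", leaf_id, reason)
    if not series:
        raise InputDataError("no usable series in the input table")
    return ExperimentTable(mode=mode, series=series, rejected=rejected)


def _growth_row(leaf_id, series, config: BatchConfig) -> dict:
    row = {"leaf_id": leaf_id, "group": series.group, "n_points": len(series),
           "converged": False, "error": ""}
    try:
        fit = fit_growth(series, config.fit)
    except InputDataError as exc:
        row["error"] = str(exc)
        return row
    row["converged"] = fit.converged
    row["sse"] = fit.sse
    row["r_squared"] = fit.r_squared
    if fit.params is None:
        row["error"] = fit.message or "fit did not converge"
        return row
    p = fit.params
    row.update({"Lm": p.Lm, "t0": p.t0, "tm": p.tm, "te": p.te})
    d = derived.derive_growth(p, config.derive)
    row["lermax"] = d.lermax
    for name, value in {**d.fraction_times, **d.length_times}.items():
        row[name] = value
    for name, value in d.leds.items():
        row[name] = value
    for frac, (lo, hi, width) in d.steady_windows.items():
        tag = f"steady{frac * 100:g}"
        row[f"{tag}_lo"] = lo
        row[f"{tag}_hi"] = hi
        row[f"{tag}_width"] = width
    for name, value in d.day_equivalents.items():
        row[f"{name}_days"] = value
    return row


def _cells_row(leaf_id, profile, config: BatchConfig) -> dict:
    row = {"leaf_id": leaf_id, "group": profile.group, "n_points": len(profile),
           "converged": False, "error": "", "family": config.family}
    try:
        fit = fit_cell_profile(profile, family=config.family, options=config.fit)
    except InputDataError as exc:
        row["error"] = str(exc)
        return row
    row["converged"] = fit.converged
    row["sse"] = fit.sse
    row["r_squared"] = fit.r_squared
    if fit.params is None:
        row["error"] = fit.message or "fit did not converge"
        return row
    if config.family == "beta":
        p = fit.params
        row.update({"Lb": p.Lb, "Lm": p.Lm, "Pm": p.Pm, "Pe": p.Pe})
        try:
            zones = derived.zone_lengths(p, config.derive.zone_threshold)
            row["division_zone"] = zones.division_zone
            row["elongation_zone"] = zones.elongation_zone
        except Exception as exc:
            row["error"] = f"zone estimation failed: {exc}"
    else:
        p = fit.params
        row.update({"lower": p.lower, "upper": p.upper, "a": p.a, "b": p.b})
    return row


def run_batch(table: ExperimentTable, config: BatchConfig | None = None) -> ResultsTable:
    """Fit and derive every leaf of an experiment.

    Optional thermal-time conversion (abscissa given as calendar day plus a
    temperature log) happens first; then per-leaf fit → goodness → derived
    parameters.  Deterministic for identical inputs and config; per-leaf
    failures land in that leaf's row, never abort the batch.
    """
    config = config or BatchConfig()
    if not len(table):
        raise InputDataError("empty experiment table")
    abscissa = "native"
    items = sorted(table.series.items())
    if (
        table.mode == "growth"
        and config.temperature_log is not None
        and config.base_temp is not None
    ):
        scale = thermal_time.ThermalScale(config.base_temp)
        converted = []
        for leaf_id, s in items:
            t = thermal_time.thermal_time_for_days(
                s.t, config.temperature_log, scale
            )
            converted.append(
                (leaf_id, LeafSeries(s.leaf_id, s.group, t, s.length))
            )
        items = converted
        abscissa = "day->gdd"
    if table.mode == "growth" and config.pool_groups:
        by_group: dict = {}
        for _, s in items:
            by_group.setdefault(s.group, []).append(s)
        items = [
            (f"pooled_{g}", pool_series(ss, leaf_id=f"pooled_{g}"))
            for g, ss in sorted(by_group.items())
        ]

    rows = []
    for leaf_id, obj in items:
        if table.mode == "growth":
            rows.append(_growth_row(leaf_id, obj, config))
        else:
            rows.append(_cells_row(leaf_id, obj, config))
    df = pd.DataFrame(rows)
    n_ok = int(df["converged"].sum())
    log.info("batch: %d leaves, %d converged, %d flagged",
             len(df), n_ok, len(df) - n_ok)
    metadata = {
        "mode": table.mode,
        "abscissa": abscissa,
        "n_leaves": len(df),
        "n_converged": n_ok,
        "n_rejected": len(table.rejected),
    }
    return ResultsTable(df=df, metadata=metadata)


def write_results(results: ResultsTable, path, sep: str = ",") -> None:
    """Write the results table with a header and >= 6 significant digits."""
    if results.df.empty:
        raise InputDataError("refusing to write an empty results table")
    results.df.to_csv(path, sep=sep, index=False, float_format="%.8g")


def wide_to_long(
    df: pd.DataFrame,
    id_col: str = "leaf_id",
    group_col: str = "group",
    x_name: str = "thermal_time",
    y_name: str = "length",
) -> pd.DataFrame:
    """Convert a wide table (one leaf per row, one column per abscissa
    value) into the long format this package reads.

    Non-id columns must be named by their abscissa value; blank cells are
    dropped.
    """
    value_cols = [c for c in df.columns if c not in (id_col, group_col)]
    long = df.melt(
        id_vars=[id_col, group_col],
        value_vars=value_cols,
        var_name=x_name,
        value_name=y_name,
    )
    long[x_name] = pd.to_numeric(long[x_name], errors="raise")
    long = long.dropna(subset=[y_name])
    return long.sort_values([id_col, x_name], kind="stable").reset_index(drop=True)
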