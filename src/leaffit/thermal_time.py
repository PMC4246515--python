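"""Thermal time (growing degree days) accumulation and conversion.

Grass leaf growth is clocked in thermal time: the cumulative sum of daily
mean temperature excess over a species-specific base temperature (°Cd).
Days with a mean at or below the base contribute nothing (the standard GDD
clipping convention — plants do not grow, or grow very slowly, below base).
Typical bases: maize 10 °C, Miscanthus 8 °C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputDataError, ParameterDomainError

__all__ = [
    "TemperatureLog",
    "ThermalScale",
    "accumulate_gdd",
    "gdd_days_convert",
    "thermal_time_for_days",
    "read_temperature_log",
]


@dataclass(frozen=True)
class ThermalScale:
    """Base temperature (°C) below which no thermal time accumulates."""

    base_temp: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.base_temp):
            raise ParameterDomainError("base temperature must be finite")


class TemperatureLog:
    """Ordered daily mean temperatures.

    Parameters
    ----------
    day : sequence of int or float
        Strictly increasing day indices (day 1 = first day after sowing,
        or any consistent origin).
    temp : sequence of float
        Daily mean temperature, °C.
    """

    def __init__(self, day, temp) -> None:
        day = np.asarray(day, dtype=float)
        temp = np.asarray(temp, dtype=float)
        if day.size == 0:
            raise InputDataError("temperature log is empty")
        if day.size != temp.size:
            raise InputDataError("day and temperature columns differ in length")
        if not np.all(np.diff(day) > 0):
            raise InputDataError("days must be strictly increasing")
        if not np.all(np.isfinite(temp)):
            raise InputDataError("temperatures must be finite")
        self.day = day
        self.temp = temp

    def __len__(self) -> int:
        return int(self.day.size)

    @classmethod
    def constant(cls, temp_c: float, n_days: int) -> "TemperatureLog":
        """A constant-temperature log of ``n_days`` days (growth chamber)."""
        return cls(np.arange(1, n_days + 1), np.full(n_days, float(temp_c)))


def accumulate_gdd(log: TemperatureLog, scale: ThermalScale) -> np.ndarray:
    """Cumulative thermal time (°Cd) at the end of each logged day.

    The result is nonnegative and nondecreasing.
    """
    daily = np.clip(log.temp - scale.base_temp, 0.0, None)
    return np.cumsum(daily)


def gdd_days_convert(
    value: float,
    constant_temp: float,
    scale: ThermalScale,
    to: str = "days",
) -> float:
    """Convert between °Cd and days under a constant temperature.

    At a constant temperature ``T > base``, every day accrues ``T - base``
    °Cd, so ``days = °Cd / (T - base)``; ``to`` selects the direction
    ("days" or "gdd").
    """
    rate = constant_temp - scale.base_temp
    if rate <= 0:
        raise ParameterDomainError(
            f"constant temperature {constant_temp} °C does not exceed the "
            f"base {scale.base_temp} °C: zero daily accumulation"
        )
    if to == "days":
        return value / rate
    if to == "gdd":
        return value * rate
    raise ParameterDomainError(f"direction must be 'days' or 'gdd', got {to!r}")


def thermal_time_for_days(days, log: TemperatureLog, scale: ThermalScale) -> np.ndarray:
    """Cumulative °Cd reached at each measurement day.

    ``days`` are matched against the log's day column; each must be present.
    """
    days = np.asarray(days, dtype=float)
    cum = accumulate_gdd(log, scale)
    idx = np.searchsorted(log.day, days)
    if np.any(idx >= len(log)) or not np.allclose(log.day[np.clip(idx, 0, len(log) - 1)], days):
        raise InputDataError("measurement days missing from the temperature log")
    return cum[idx]


def read_temperature_log(path, sep: str | None = None) -> TemperatureLog:
    """Read a two-column delimited file (day, daily mean °C).

    Sub-daily records (repeated day values) are aggregated to daily means
    before accumulation.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    if df.shape[1] < 2:
        raise InputDataError("temperature log needs two columns: day, mean_temp_C")
    day_col, temp_col = df.columns[:2]
    daily = df.groupby(day_col, sort=True)[temp_col].mean()
    return TemperatureLog(daily.index.to_numpy(), daily.to_numpy())
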