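"""Biologically relevant parameters derived from a fitted growth curve.

Because the fitted curve is continuous, the length at any thermal time and
the thermal time at any length are both available, giving timing points
(t20%, t50%, t90%, t100 mm, ...), leaf elongation durations (LEDs) between
any pair of those points, the maximal elongation rate LERmax, steady-state
growth windows (thermal-time intervals over which LER stays above a given
fraction of LERmax), and — for cell-length profiles — division and
elongation zone lengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from . import models, thermal_time
from .errors import ParameterDomainError
from .models import CellProfileParams, GrowthParams

__all__ = [
    "DeriveConfig",
    "DerivedGrowthParams",
    "ZoneEstimate",
    "derive_growth",
    "led",
    "zone_lengths",
]

log = logging.getLogger(__name__)


def fraction_label(f: float) -> str:
    """t20% style label for a fraction of final length."""
    pct = f * 100
    return f"t{pct:g}%"


def length_label(L: float) -> str:
    """t100 style label for an absolute length milestone (mm)."""
    return f"t{L:g}"


def _led_label(early: str, late: str) -> str:
    def short(name: str) -> str:
        if name == "te":
            return "e"
        return name[1:] if name.startswith("t") else name

    return f"LED({short(early)}-{short(late)})"


@dataclass(frozen=True)
class DeriveConfig:
    """Which derived quantities to extract.

    Defaults mirror a typical maize analysis: fractional timing points 20,
    50 and 90 %, the absolute milestone t100 (time to reach 100 mm — for
    small-leaved species replace with e.g. 20 mm), LEDs between those
    points, and steady-state windows at 90 and 95 % of LERmax.  Day
    equivalents of all timing values are added when a constant temperature
    and base temperature are configured.
    """

    fractions: tuple = (0.2, 0.5, 0.9)
    lengths: tuple = (100.0,)
    led_pairs: tuple = (("t100", "te"), ("t20%", "t90%"), ("t20%", "te"))
    steady_fractions: tuple = (0.90, 0.95)
    zone_threshold: float = 40.0
    constant_temp: float | None = None
    base_temp: float | None = None


@dataclass
class DerivedGrowthParams:
    """Derived quantities of one fitted leaf."""

    lermax: float
    tm: float
    te: float
    fraction_times: dict = field(default_factory=dict)
    length_times: dict = field(default_factory=dict)
    leds: dict = field(default_factory=dict)
    steady_windows: dict = field(default_factory=dict)
    day_equivalents: dict = field(default_factory=dict)

    def time_points(self) -> dict:
        """All named timing points, including tm and te."""
        pts = {"tm": self.tm, "te": self.te}
        pts.update(self.fraction_times)
        pts.update(self.length_times)
        return pts


@dataclass(frozen=True)
class ZoneEstimate:
    """Division / elongation zone lengths of one cell profile (mm)."""

    division_zone: float
    elongation_zone: float
    threshold: float


def derive_growth(
    params: GrowthParams, config: DeriveConfig | None = None
) -> DerivedGrowthParams:
    """Extract every configured derived quantity from fitted parameters.

    An absolute-length milestone beyond the leaf's final length is not an
    error: it is logged and omitted (so a batch over genotypes of very
    different sizes does not abort), and any LED referencing it is omitted
    with it.
    """
    config = config or DeriveConfig()
    _, lermax = models.max_rate(params)
    out = DerivedGrowthParams(lermax=lermax, tm=params.tm, te=params.te)

    for f in config.fractions:
        out.fraction_times[fraction_label(f)] = models.time_at_fraction(params, f)
    for L in config.lengths:
        label = length_label(L)
        if L > params.Lm:
            log.warning(
                "milestone %s mm exceeds final length %.4g mm; omitted", L, params.Lm
            )
            continue
        out.length_times[label] = models.time_at_length(params, L)

    points = out.time_points()
    for early, late in config.led_pairs:
        if early not in points or late not in points:
            log.warning("LED pair (%s, %s) references a missing point; omitted",
                        early, late)
            continue
        out.leds[_led_label(early, late)] = led(points[early], points[late])

    for frac in config.steady_fractions:
        out.steady_windows[frac] = models.rate_window(params, frac)

    if config.constant_temp is not None and config.base_temp is not None:
        scale = thermal_time.ThermalScale(config.base_temp)
        for name, value in out.time_points().items():
            out.day_equivalents[name] = thermal_time.gdd_days_convert(
                value, config.constant_temp, scale, to="days"
            )
    return out


def led(t_early: float, t_late: float) -> float:
    """Leaf elongation duration between two thermal-time points (°Cd)."""
    if t_late < t_early:
        raise ParameterDomainError(
            f"LED endpoints out of order: {t_early} > {t_late}"
        )
    return t_late - t_early


def zone_lengths(
    params: CellProfileParams, threshold: float = 40.0
) -> ZoneEstimate:
    """Division and elongation zone lengths from a fitted cell profile.

    The division zone is the basal stretch over which the fitted cell
    length does not exceed ``threshold`` μm (default 40, the conventional
    dividing-cell cutoff); the elongation zone runs from its end to ``Pe``.
    """
    if not (params.Lb < threshold < params.Lm):
        raise ParameterDomainError(
            f"threshold {threshold} μm must lie strictly between Lb={params.Lb} "
            f"and Lm={params.Lm}"
        )
    eps = 1e-12 * params.Pe
    division = float(
        brentq(
            lambda p: models.cell_length_at(params, p) - threshold,
            eps,
            params.Pe,
            xtol=1e-12,
            rtol=1e-15,
        )
    )
    return ZoneEstimate(
        division_zone=division,
        elongation_zone=params.Pe - division,
        threshold=threshold,
    )
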