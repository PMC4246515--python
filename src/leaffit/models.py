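"""Determinate-growth sigmoid models for grass leaf phenotyping.

The central object is the beta sigmoid function for determinate growth.
Leaf length ``L`` (mm) as a function of thermal time ``t`` (°Cd, growing
degree days) is

    L(t) = Lm * (1 + (te - t)/(te - tm)) * ((t - t0)/(te - t0))**((te - t0)/(te - tm))

for ``t0 <= t <= te``, with ``L = 0`` for ``t < t0`` and ``L = Lm`` for
``t > te`` (the mature leaf stops elongating).  The four parameters are
directly interpretable: ``Lm`` is the final leaf length, ``t0`` the start
of growth, ``tm`` the moment of maximal elongation rate, and ``te`` the
moment growth ceases.  Unlike the logistic or Gompertz curves, the rate is
exactly zero at both ends of the growth period, which is what "determinate
growth" means for a grass leaf.

The leaf elongation rate (LER, mm/°Cd) is the analytic first derivative of
the curve; its maximum LERmax is attained at ``tm`` and has the closed form

    LERmax = Lm * (2*te - tm - t0) / ((te - tm)*(te - t0))
             * ((tm - t0)/(te - t0))**((tm - t0)/(te - tm))

Cell-length profiles along the growing leaf axis follow the same shape but
start from a non-zero basal cell length ``Lb`` (cells in the division zone
already have a length before elongating).  The extended form, with position
``p`` (mm from the leaf base, base fixed at position zero) replacing time,

    l(p) = Lb + (Lm - Lb) * (1 + (Pe - p)/(Pe - Pm)) * (p/Pe)**(Pe/(Pe - Pm))

uses ``Pm`` (position of maximal cell elongation) and ``Pe`` (position at
which cells reach their final length ``Lm``).

This module holds only the pure mathematics: evaluation, derivatives,
inverses and closed-form derived quantities.  Fitting and I/O live in
sibling modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import ConfigurationError, ParameterDomainError

__all__ = [
    "GrowthParams",
    "CellProfileParams",
    "SigmoidFamily",
    "length_at",
    "rate_at",
    "max_rate",
    "time_at_length",
    "time_at_fraction",
    "rate_window",
    "cell_length_at",
    "alt_sigmoid_at",
]

# relative bracket shrink for root searches on [t0, te]
_BRACKET_EPS = 1e-9


@dataclass(frozen=True)
class GrowthParams:
    """Beta sigmoid parameters of one leaf.

    Attributes
    ----------
    Lm : float
        Final leaf length, mm.  Must be positive.
    t0 : float
        Thermal time at which growth starts, °Cd.
    tm : float
        Thermal time of maximal elongation rate, °Cd.
    te : float
        Thermal time at which growth ceases, °Cd.

    The ordering ``t0 <= tm < te`` is required.
    """

    Lm: float
    t0: float
    tm: float
    te: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.Lm, self.t0, self.tm, self.te]).all():
            raise ParameterDomainError("growth parameters must be finite")
        if self.Lm <= 0:
            raise ParameterDomainError(f"Lm must be positive, got {self.Lm}")
        if not (self.t0 <= self.tm < self.te):
            raise ParameterDomainError(
                f"require t0 <= tm < te, got t0={self.t0}, tm={self.tm}, te={self.te}"
            )


@dataclass(frozen=True)
class CellProfileParams:
    """Extended beta sigmoid parameters of one cell-length profile.

    Attributes
    ----------
    Lb : float
        Initial (basal, dividing-cell) length, μm.  0 < Lb < Lm.
    Lm : float
        Final (mature) cell length, μm.
    Pm : float
        Position of maximal cell elongation, mm from the leaf base.
    Pe : float
        Position at which cells reach their final length, mm.
        Requires 0 <= Pm < Pe.
    """

    Lb: float
    Lm: float
    Pm: float
    Pe: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.Lb, self.Lm, self.Pm, self.Pe]).all():
            raise ParameterDomainError("cell profile parameters must be finite")
        if not (0 < self.Lb < self.Lm):
            raise ParameterDomainError(
                f"require 0 < Lb < Lm, got Lb={self.Lb}, Lm={self.Lm}"
            )
        if not (0 <= self.Pm < self.Pe):
            raise ParameterDomainError(
                f"require 0 <= Pm < Pe, got Pm={self.Pm}, Pe={self.Pe}"
            )


_FAMILIES = ("beta", "weibull", "gompertz", "logistic")


@dataclass(frozen=True)
class SigmoidFamily:
    """A 4-parameter sigmoid with lower asymptote ``lower`` and upper ``upper``.

    The two shape parameters ``a`` and ``b`` carry family-specific meaning
    (abscissa units throughout):

    - ``logistic``:  a = midpoint x0, b = steepness k > 0;
      ``f(x) = lower + (upper-lower) / (1 + exp(-k (x - x0)))``
    - ``gompertz``:  a = shift x0, b = steepness k > 0;
      ``f(x) = lower + (upper-lower) * exp(-exp(-k (x - x0)))``
    - ``weibull``:   a = scale λ > 0, b = shape k > 0 (x >= 0);
      ``f(x) = lower + (upper-lower) * (1 - exp(-(x/λ)**k))``
    - ``beta``:      a = Pm, b = Pe with 0 <= Pm < Pe (start pinned at 0);
      the extended beta sigmoid above.

    All share the same asymptote semantics so goodness of fit is comparable
    across families.
    """

    family: str
    lower: float
    upper: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ConfigurationError(
                f"unknown sigmoid family {self.family!r}; expected one of {_FAMILIES}"
            )
        if not np.isfinite([self.lower, self.upper, self.a, self.b]).all():
            raise ParameterDomainError("sigmoid parameters must be finite")
        if self.upper <= self.lower:
            raise ParameterDomainError("require upper asymptote > lower asymptote")
        if self.family in ("logistic", "gompertz") and self.b <= 0:
            raise ParameterDomainError("steepness must be strictly positive")
        if self.family == "weibull" and not (self.a > 0 and self.b > 0):
            raise ParameterDomainError("Weibull scale and shape must be positive")
        if self.family == "beta" and not (0 <= self.a < self.b):
            raise ParameterDomainError("beta family requires 0 <= Pm < Pe")


def _beta_unit(x, x0: float, xm: float, xe: float):
    """Unit-amplitude beta sigmoid: 0 at ``x0``, 1 at and beyond ``xe``."""
    x = np.asarray(x, dtype=float)
    span = xe - x0
    tail = xe - xm
    c = span / tail
    u = np.clip((x - x0) / span, 0.0, 1.0)
    xc = np.clip(x, x0, xe)
    val = (1.0 + (xe - xc) / tail) * u**c
    val = np.where(x >= xe, 1.0, val)
    val = np.where(x <= x0, 0.0, val)
    return val


def _beta_unit_rate(x, x0: float, xm: float, xe: float):
    """Derivative of :func:`_beta_unit`; zero outside (x0, xe)."""
    x = np.asarray(x, dtype=float)
    span = xe - x0
    tail = xe - xm
    c = span / tail
    u = np.clip((x - x0) / span, 0.0, 1.0)
    xc = np.clip(x, x0, xe)
    # dL/dx = 1/tail * u**(c-1) * (1 - u + (xe - x)/tail); c >= 1 always
    bracket = 1.0 - u + (xe - xc) / tail
    with np.errstate(invalid="ignore"):
        val = (1.0 / tail) * u ** (c - 1.0) * bracket
    inside = (x > x0) & (x < xe)
    return np.where(inside, val, 0.0)


def _scalarize(x_in, val):
    return float(val) if np.ndim(x_in) == 0 else val


def length_at(params: GrowthParams, t):
    """Leaf length (mm) at thermal time ``t`` (°Cd); scalar or array."""
    return _scalarize(t, params.Lm * _beta_unit(t, params.t0, params.tm, params.te))


def rate_at(params: GrowthParams, t):
    """Leaf elongation rate (mm/°Cd) at thermal time ``t``.

    Analytic first derivative of :func:`length_at`; zero outside
    ``(t0, te)`` as growth is determinate.
    """
    return _scalarize(
        t, params.Lm * _beta_unit_rate(t, params.t0, params.tm, params.te)
    )


def max_rate(params: GrowthParams) -> tuple[float, float]:
    """Return ``(tm, LERmax)``, the location and value of the rate maximum.

    LERmax has a closed form (module docstring) and equals ``rate_at(tm)``.
    """
    Lm, t0, tm, te = params.Lm, params.t0, params.tm, params.te
    lermax = (
        Lm
        * (2 * te - tm - t0)
        / ((te - tm) * (te - t0))
        * ((tm - t0) / (te - t0)) ** ((tm - t0) / (te - tm))
    )
    return tm, lermax


def time_at_length(params: GrowthParams, L: float) -> float:
    """Invert the growth curve: thermal time at which length ``L`` is reached.

    The curve is strictly increasing on ``(t0, te)``, so the root is unique;
    it is located by a bracketed root search.  ``L = Lm`` maps to ``te``.

    Raises
    ------
    ParameterDomainError
        If ``L <= 0`` or ``L > Lm``.
    """
    if not (0 < L <= params.Lm):
        raise ParameterDomainError(
            f"length must lie in (0, Lm={params.Lm}], got {L}"
        )
    t0, te = params.t0, params.te
    eps = _BRACKET_EPS * (te - t0)
    if L >= params.Lm * (1.0 - 1e-13):
        return te
    return float(
        brentq(lambda t: length_at(params, t) - L, t0 + eps, te, xtol=1e-12, rtol=1e-15)
    )


def time_at_fraction(params: GrowthParams, f: float) -> float:
    """Thermal time at which the leaf reaches fraction ``f`` of ``Lm``.

    ``f`` must lie in (0, 1]; ``f = 1`` returns ``te`` exactly.
    """
    if not (0 < f <= 1):
        raise ParameterDomainError(f"fraction must lie in (0, 1], got {f}")
    return time_at_length(params, f * params.Lm)


def rate_window(params: GrowthParams, frac: float) -> tuple[float, float, float]:
    """Steady-state growth window at a given fraction of LERmax.

    Returns ``(t_lo, t_hi, width)`` where ``t_lo < tm < t_hi`` are the two
    thermal times at which the elongation rate equals ``frac * LERmax``
    (found by bracketed root search on each flank of the rate maximum) and
    ``width = t_hi - t_lo``.  ``frac = 1`` degenerates to ``(tm, tm, 0)``.
    """
    if not (0 < frac <= 1):
        raise ParameterDomainError(f"fraction must lie in (0, 1], got {frac}")
    tm, lermax = max_rate(params)
    if frac == 1:
        return tm, tm, 0.0
    target = frac * lermax
    t0, te = params.t0, params.te
    eps = _BRACKET_EPS * (te - t0)

    def f(t: float) -> float:
        return rate_at(params, t) - target

    if tm > t0 and f(t0 + eps) < 0:
        t_lo = float(brentq(f, t0 + eps, tm, xtol=1e-12, rtol=1e-15))
    else:
        t_lo = t0  # rate already above the target at the start of growth
    t_hi = float(brentq(f, tm, te - eps, xtol=1e-12, rtol=1e-15))
    return t_lo, t_hi, t_hi - t_lo


def cell_length_at(params: CellProfileParams, p):
    """Cell length (μm) at position ``p`` (mm from the leaf base).

    ``Lb`` at the base, ``Lm`` at and beyond ``Pe``.  Negative positions are
    unphysical and rejected.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr < 0):
        raise ParameterDomainError("positions along the leaf axis must be >= 0")
    val = params.Lb + (params.Lm - params.Lb) * _beta_unit(
        p_arr, 0.0, params.Pm, params.Pe
    )
    return _scalarize(p, val)


def alt_sigmoid_at(family: SigmoidFamily, x):
    """Evaluate any of the four comparable sigmoid families at ``x``.

    All families run from ``family.lower`` to ``family.upper`` and are
    monotone nondecreasing; see :class:`SigmoidFamily` for the closed forms.
    """
    lo, hi, a, b = family.lower, family.upper, family.a, family.b
    amp = hi - lo
    x_arr = np.asarray(x, dtype=float)
    if family.family == "logistic":
        val = lo + amp / (1.0 + np.exp(-b * (x_arr - a)))
    elif family.family == "gompertz":
        val = lo + amp * np.exp(-np.exp(-b * (x_arr - a)))
    elif family.family == "weibull":
        xa = np.clip(x_arr, 0.0, None)
        val = lo + amp * (1.0 - np.exp(-((xa / a) ** b)))
    else:  # beta
        val = lo + amp * _beta_unit(np.clip(x_arr, 0.0, None), 0.0, a, b)
    return _scalarize(x, val)
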