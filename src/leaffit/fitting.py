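"""Per-leaf nonlinear least-squares fitting of the growth sigmoids.

Fits the beta sigmoid to one leaf's length-vs-thermal-time series, or the
extended beta sigmoid (and the comparable Weibull / Gompertz / logistic
families) to one cell-length-vs-position profile.  Starting values are
derived automatically from the data; on failure the fit restarts from a
deterministic sequence of perturbed starting values.  All ordering
constraints (tm < te, Pm < Pe) are kept exact by optimizing positive
increments rather than the raw endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from . import models
from .errors import (
    ConfigurationError,
    DegenerateSeriesError,
    InputDataError,
)
from .models import CellProfileParams, GrowthParams, SigmoidFamily

__all__ = [
    "LeafSeries",
    "CellProfile",
    "FitResult",
    "FitOptions",
    "initial_guess",
    "fit_growth",
    "fit_cell_profile",
    "goodness",
    "predicted_vs_observed",
    "empirical_ler",
    "pool_series",
]

MIN_GROWTH_POINTS = 5
MIN_PROFILE_POINTS = 8

# deterministic ±20% perturbation multipliers for restarts (per parameter,
# cycled); index 0 is the unperturbed start
_RESTART_PATTERNS = (
    (1.0, 1.0, 1.0, 1.0),
    (1.2, 0.8, 1.1, 0.9),
    (0.8, 1.2, 0.9, 1.1),
    (1.2, 1.2, 1.2, 1.2),
    (0.8, 0.8, 0.8, 0.8),
    (1.1, 0.9, 1.2, 0.8),
)


def _as_series_arrays(x, y, x_name: str) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InputDataError(f"{x_name} and value columns differ in length")
    if x.size < 2:
        raise InputDataError("a series needs at least 2 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InputDataError("measurements must be finite")
    if not np.all(np.diff(x) > 0):
        raise InputDataError(f"{x_name} must be strictly increasing")
    return x, y


@dataclass
class LeafSeries:
    """One leaf's ordered (thermal time °Cd, length mm) measurements."""

    leaf_id: str
    group: str
    t: np.ndarray
    length: np.ndarray

    def __post_init__(self) -> None:
        self.t, self.length = _as_series_arrays(self.t, self.length, "thermal time")
        if np.any(self.length < 0):
            raise InputDataError("leaf lengths must be >= 0")

    def __len__(self) -> int:
        return int(self.t.size)


@dataclass
class CellProfile:
    """One leaf's ordered (position mm, cell length μm) measurements."""

    leaf_id: str
    group: str
    position: np.ndarray
    cell_length: np.ndarray

    def __post_init__(self) -> None:
        self.position, self.cell_length = _as_series_arrays(
            self.position, self.cell_length, "position"
        )
        if np.any(self.position < 0):
            raise InputDataError("positions must be >= 0")
        if np.any(self.cell_length <= 0):
            raise InputDataError("cell lengths must be > 0")

    def __len__(self) -> int:
        return int(self.position.size)


@dataclass
class FitResult:
    """Outcome of one least-squares fit.

    ``params`` is the typed parameter object (GrowthParams,
    CellProfileParams or SigmoidFamily) or None when the optimizer landed
    outside the valid domain; ``residuals`` are observed − fitted per point.
    """

    params: object | None
    sse: float
    r_squared: float
    residuals: np.ndarray
    converged: bool
    n_iter: int
    start: tuple
    message: str = ""
    family: str = "beta"


@dataclass
class FitOptions:
    """Optimizer controls; defaults suit daily leaf measurements."""

    fix_t0: bool = True
    tolerance: float = 1e-10
    max_iterations: int = 200
    max_restarts: int = 5
    bounds: dict = field(default_factory=dict)


def initial_guess(series: LeafSeries) -> GrowthParams:
    """Data-driven starting values for a growth fit.

    Lm starts at 1.05×max(L); te at the first time the series reaches 95 %
    of its maximum; tm at the midpoint of the interval with the steepest
    finite-difference rate; t0 at 0 (sowing).
    """
    if len(series) < MIN_GROWTH_POINTS:
        raise InputDataError(
            f"need >= {MIN_GROWTH_POINTS} points to fit, got {len(series)}"
        )
    t, y = series.t, series.length
    ymax = float(y.max())
    if ymax <= float(y.min()):
        raise DegenerateSeriesError("series is constant: no growth signal")
    lm0 = 1.05 * ymax
    te0 = float(t[np.argmax(y >= 0.95 * ymax)])
    rates = np.diff(y) / np.diff(t)
    k = int(np.argmax(rates))
    tm0 = float(0.5 * (t[k] + t[k + 1]))
    if te0 <= 0:
        te0 = float(t[-1])
    if not (0 <= tm0 < te0):
        tm0 = 0.5 * te0
    return GrowthParams(Lm=lm0, t0=0.0, tm=tm0, te=te0)


def _r_squared(y: np.ndarray, residuals: np.ndarray) -> float:
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0:
        raise DegenerateSeriesError("zero variance in observations: R² undefined")
    return 1.0 - float(np.sum(residuals**2)) / sstot


def _run_least_squares(resid_fn, x0, lo, hi, options: FitOptions):
    """One bounded TRF solve; returns (x, sse, n_iter, success, message)."""
    x0 = np.clip(np.asarray(x0, dtype=float), lo, hi)
    try:
        res = least_squares(
            resid_fn,
            x0,
            bounds=(lo, hi),
            method="trf",
            ftol=options.tolerance,
            xtol=options.tolerance,
            gtol=None,
            max_nfev=options.max_iterations * len(x0),
        )
    except Exception as exc:  # numerical blow-up counts as non-convergence
        return None, np.inf, 0, False, str(exc)
    sse = float(2.0 * res.cost)
    return res.x, sse, int(res.nfev), bool(res.success), res.status and ""


def fit_growth(series: LeafSeries, options: FitOptions | None = None) -> FitResult:
    """Fit the beta sigmoid to one leaf series by bounded least squares.

    ``t0`` is fixed at 0 by default (free-t0 estimates are often negative
    and biologically meaningless for seedlings); set ``options.fix_t0``
    False to release it.  ``tm < te`` is enforced structurally.  On solver
    failure the fit restarts from perturbed starting values, up to
    ``max_restarts`` times; a fit that never succeeds is returned flagged
    ``converged=False``, never raised.
    """
    options = options or FitOptions()
    guess = initial_guess(series)
    t, y = series.t, series.length
    ymax, t_last = float(y.max()), float(t[-1])
    tiny = 1e-9

    if options.fix_t0:
        def unpack(x):
            lm, tm, dte = x
            return lm, 0.0, tm, tm + dte

        x0 = np.array([guess.Lm, guess.tm, guess.te - guess.tm])
        lo = np.array([tiny, tiny, tiny])
        hi = np.array([10 * ymax, 2 * t_last, 2 * t_last])
    else:
        def unpack(x):
            lm, t0, dtm, dte = x
            return lm, t0, t0 + dtm, t0 + dtm + dte

        x0 = np.array([guess.Lm, 0.0, guess.tm, guess.te - guess.tm])
        lo = np.array([tiny, -t_last, tiny, tiny])
        hi = np.array([10 * ymax, t_last, 2 * t_last, 2 * t_last])
    lo_b = np.asarray(options.bounds.get("lower", lo), dtype=float)
    hi_b = np.asarray(options.bounds.get("upper", hi), dtype=float)

    def resid(x):
        lm, t0, tm, te = unpack(x)
        return (
            lm * models._beta_unit(t, t0, tm, te) - y
        )

    start_sse = float(np.sum(resid(x0) ** 2))
    best = None
    for k in range(min(options.max_restarts + 1, len(_RESTART_PATTERNS))):
        mult = np.array(_RESTART_PATTERNS[k][: len(x0)])
        xk = x0 * mult
        x, sse, nit, ok, msg = _run_least_squares(resid, xk, lo_b, hi_b, options)
        if best is None or sse < best[1]:
            best = (x, sse, nit, ok, msg)
        if ok and sse <= start_sse:
            break
    x, sse, nit, ok, msg = best
    if x is None:
        return FitResult(
            params=None,
            sse=start_sse,
            r_squared=np.nan,
            residuals=np.full_like(y, np.nan),
            converged=False,
            n_iter=nit,
            start=tuple(x0),
            message=msg or "optimizer failed",
        )
    lm, t0f, tmf, tef = unpack(x)
    residuals = y - lm * models._beta_unit(t, t0f, tmf, tef)
    try:
        params = GrowthParams(lm, t0f, tmf, tef)
    except Exception as exc:
        return FitResult(None, sse, np.nan, residuals, False, nit, tuple(x0), str(exc))
    return FitResult(
        params=params,
        sse=sse,
        r_squared=_r_squared(y, residuals),
        residuals=residuals,
        converged=ok and sse <= start_sse + 1e-12,
        n_iter=nit,
        start=tuple(x0),
        message=msg or "",
    )


def _profile_guess(profile: CellProfile, family: str):
    p, y = profile.position, profile.cell_length
    ymin, ymax = float(y.min()), float(y.max())
    if ymax <= ymin:
        raise DegenerateSeriesError("profile is constant: no elongation signal")
    lb0 = max(ymin, 1e-3)
    lm0 = 1.05 * ymax
    half = 0.5 * (ymin + ymax)
    p_half = float(p[np.argmax(y >= half)])
    pe0 = float(p[np.argmax(y >= ymin + 0.95 * (ymax - ymin))])
    slopes = np.diff(y) / np.diff(p)
    k = int(np.argmax(slopes))
    pm0 = float(0.5 * (p[k] + p[k + 1]))
    if pe0 <= pm0:
        pe0 = max(pm0 * 1.5, pm0 + 1.0)
    if family == "beta":
        return np.array([lb0, lm0, pm0, pe0 - pm0])
    if family == "weibull":
        return np.array([lb0, lm0, max(p_half, 1e-3), 2.0])
    # logistic / gompertz: midpoint + steepness from the max slope
    k0 = 4.0 * float(slopes.max()) / (ymax - ymin)
    return np.array([lb0, lm0, max(p_half, 1e-3), max(k0, 1e-3)])


def fit_cell_profile(
    profile: CellProfile,
    family: str = "beta",
    options: FitOptions | None = None,
) -> FitResult:
    """Fit a 4-parameter sigmoid to one cell-length profile.

    ``family`` selects beta (default, parameters Lb, Lm, Pm, Pe), weibull,
    gompertz or logistic; all share the asymptote semantics so R² values
    are comparable across families.
    """
    if family not in models._FAMILIES:
        raise ConfigurationError(f"unknown family {family!r}")
    options = options or FitOptions()
    if len(profile) < MIN_PROFILE_POINTS:
        raise InputDataError(
            f"need >= {MIN_PROFILE_POINTS} points for a profile fit, got {len(profile)}"
        )
    p, y = profile.position, profile.cell_length
    ymax, p_last = float(y.max()), float(p[-1])
    tiny = 1e-9
    x0 = _profile_guess(profile, family)

    if family == "beta":
        def unpack(x):
            lb, lm, pm, dpe = x
            return lb, lm, pm, pm + dpe

        def curve(x):
            lb, lm, pm, pe = unpack(x)
            return lb + (lm - lb) * models._beta_unit(p, 0.0, pm, pe)

        lo = np.array([tiny, tiny, tiny, tiny])
        hi = np.array([ymax, 10 * ymax, 2 * p_last, 2 * p_last])
    else:
        def unpack(x):
            return tuple(x)

        def curve(x):
            lb, lm, a, b = x
            fam = SigmoidFamily(family, lb, lm, a, b)
            return np.asarray(models.alt_sigmoid_at(fam, p))

        lo = np.array([tiny, tiny, tiny, tiny])
        hi = np.array([ymax, 10 * ymax, 4 * p_last, 100.0])

    def resid(x):
        return curve(x) - y

    start_sse = float(np.sum(resid(x0) ** 2))
    best = None
    for k in range(min(options.max_restarts + 1, len(_RESTART_PATTERNS))):
        xk = x0 * np.array(_RESTART_PATTERNS[k])
        x, sse, nit, ok, msg = _run_least_squares(resid, xk, lo, hi, options)
        if best is None or sse < best[1]:
            best = (x, sse, nit, ok, msg)
        if ok and sse <= start_sse:
            break
    x, sse, nit, ok, msg = best
    if x is None:
        return FitResult(
            None, start_sse, np.nan, np.full_like(y, np.nan), False, nit,
            tuple(x0), msg or "optimizer failed", family,
        )
    residuals = y - curve(x)
    try:
        if family == "beta":
            lb, lm, pm, pe = unpack(x)
            params: object = CellProfileParams(lb, lm, pm, pe)
        else:
            lb, lm, a, b = x
            params = SigmoidFamily(family, lb, lm, a, b)
    except Exception as exc:
        return FitResult(None, sse, np.nan, residuals, False, nit, tuple(x0),
                         str(exc), family)
    return FitResult(
        params=params,
        sse=sse,
        r_squared=_r_squared(y, residuals),
        residuals=residuals,
        converged=ok and sse <= start_sse + 1e-12,
        n_iter=nit,
        start=tuple(x0),
        message=msg or "",
        family=family,
    )


def goodness(fit: FitResult, series) -> dict:
    """Recompute {R², SSE} for a fit against its series.

    R² is the centred coefficient of determination, 1 − SSE/SStot with
    SStot about the observed mean.
    """
    y = series.length if isinstance(series, LeafSeries) else series.cell_length
    if fit.residuals.size != y.size:
        raise InputDataError("fit and series do not match")
    sse = float(np.sum(fit.residuals**2))
    return {"r_squared": _r_squared(y, fit.residuals), "sse": sse}


def predicted_vs_observed(pairs) -> dict:
    """Pooled linear regression of fitted on observed values.

    ``pairs`` is an iterable of (FitResult, series).  Returns slope,
    intercept and R² of the ordinary least-squares line through all
    (observed, fitted) points — a batch-level goodness-of-fit summary.
    """
    obs, fitted = [], []
    for fit, series in pairs:
        y = series.length if isinstance(series, LeafSeries) else series.cell_length
        obs.append(y)
        fitted.append(y - fit.residuals)
    if not obs:
        raise InputDataError("no fits supplied")
    obs_arr = np.concatenate(obs)
    fit_arr = np.concatenate(fitted)
    if obs_arr.size < 2 or np.ptp(obs_arr) == 0:
        raise InputDataError("need >= 2 distinct pooled points for a regression")
    res = stats.linregress(obs_arr, fit_arr)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
    }


def empirical_ler(series: LeafSeries) -> tuple[np.ndarray, np.ndarray]:
    """Finite-difference elongation rates between consecutive measurements.

    Returns (interval midpoints °Cd, ΔL/Δt mm/°Cd); the maximum of the
    second array is the "calculated LERmax" that model-free analyses report.
    """
    t, y = series.t, series.length
    mid = 0.5 * (t[:-1] + t[1:])
    rates = np.diff(y) / np.diff(t)
    return mid, rates


def pool_series(series_list, leaf_id: str = "pooled") -> LeafSeries:
    """Pool several replicate series of one group into a single series.

    Points are merged and sorted by thermal time; exact duplicate times are
    jittered is NOT done — instead the mean of coincident measurements is
    used, keeping the abscissa strictly increasing for the fit.
    """
    if not series_list:
        raise InputDataError("no series to pool")
    group = series_list[0].group
    t = np.concatenate([s.t for s in series_list])
    y = np.concatenate([s.length for s in series_list])
    order = np.argsort(t, kind="stable")
    t, y = t[order], y[order]
    uniq, inv = np.unique(t, return_inverse=True)
    mean_y = np.zeros_like(uniq)
    counts = np.bincount(inv)
    np.add.at(mean_y, inv, y)
    mean_y /= counts
    return LeafSeries(leaf_id=leaf_id, group=group, t=uniq, length=mean_y)
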