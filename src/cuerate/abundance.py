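"""Calling-rate extrapolation and abundance back-estimation.

Daily calling rates are only observable on days with both acoustic and
visual effort.  To estimate whale numbers on acoustic-only days (early
December, before the visual census starts) a two-term power model

    f(x) = a * x**b + c          (x = day index, x = 1 on 1 December)

is fit to the observed daily rates by nonlinear least squares and
extrapolated back toward x = 1.  The model family keeps the
extrapolated rate roughly constant before the census start rather than
letting it sink to zero, which would blow the whale estimate up to
infinity.  Per-day whale numbers follow from inverting the cue-rate
relation:

    N_W(t) = N_C(t) / (r(t) * P_SA * t_SA)

with uncertainty carried by the pointwise (non-simultaneous) 95%
prediction interval of the fitted rate curve: the upper rate bound gives
the minimum whale count and the lower bound the maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .cue_rates import UndefinedRateError
from .geometry import TransitTime

__all__ = [
    "PowerModel",
    "WhaleEstimate",
    "fit_power_model",
    "prediction_interval",
    "whales_from_cues",
    "december_backestimate",
]


class FitError(RuntimeError):
    """Nonlinear fit failed to converge or is rank deficient."""


class LowRateWarning(UserWarning):
    """Cue rate at or below the floor: the whale estimate is unbounded."""


def _power(x: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    return a * np.power(x, b) + c


@dataclass
class PowerModel:
    """Fitted two-term power calling-rate curve with uncertainty.

    ``a``, ``b``, ``c`` are the coefficients of ``f(x) = a*x**b + c``
    (calls/whale/day against day index), ``covariance`` the 3x3
    coefficient covariance from the linearized fit, ``sse`` the summed
    squared residuals and ``dof`` the residual degrees of freedom.
    """

    a: float
    b: float
    c: float
    covariance: np.ndarray
    sse: float
    dof: int

    def __post_init__(self) -> None:
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.covariance.shape != (3, 3):
            raise ValueError("covariance must be 3x3")
        if self.dof <= 0:
            raise ValueError("need positive residual degrees of freedom")

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        return _power(np.asarray(x, dtype=float), self.a, self.b, self.c)

    @property
    def sigma2(self) -> float:
        """Residual variance estimate sse/dof."""
        return self.sse / self.dof

    def gradient(self, x: np.ndarray | float) -> np.ndarray:
        """Coefficient gradient of f at x: (x**b, a*x**b*ln x, 1)."""
        x = np.asarray(x, dtype=float)
        xb = np.power(x, self.b)
        g = np.stack(
            [xb, self.a * xb * np.log(x), np.ones_like(x)], axis=-1
        )
        return g


def fit_power_model(days: np.ndarray, rates: np.ndarray) -> PowerModel:
    """Least-squares fit of ``a*x**b + c`` to daily calling rates.

    Initialization is deterministic: c starts at the smallest observed
    rate (nudged down so the log is defined) and (a, b) come from a
    log-log regression of the remainder on day.  Requires at least four
    points on positive integer days.
    """
    x = np.asarray(days, dtype=float)
    y = np.asarray(rates, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need at least 4 (day, rate) points")
    if np.any(x <= 0):
        raise ValueError("day indices must be positive")

    if np.ptp(y) == 0:
        # constant limit: a = 0, b unidentifiable (pinned at 1 with zero
        # variance), c = the common value with exact-fit covariance
        return PowerModel(
            a=0.0, b=1.0, c=float(y[0]), covariance=np.zeros((3, 3)),
            sse=0.0, dof=int(x.size - 3),
        )

    c0 = float(y.min())
    resid0 = y - c0 + 1e-6
    slope, intercept = np.polyfit(np.log(x), np.log(resid0), 1)
    p0 = (float(np.exp(intercept)), float(slope), c0)

    with warnings.catch_warnings():
        warnings.simplefilter("error", optimize.OptimizeWarning)
        try:
            popt, pcov = optimize.curve_fit(
                _power, x, y, p0=p0, maxfev=20000, method="lm"
            )
        except (RuntimeError, optimize.OptimizeWarning, TypeError) as exc:
            raise FitError(f"power-model fit failed: {exc}") from exc
    if not np.all(np.isfinite(pcov)):
        raise FitError("power-model fit is rank deficient (infinite covariance)")
    resid = y - _power(x, *popt)
    sse = float(resid @ resid)
    return PowerModel(
        a=float(popt[0]),
        b=float(popt[1]),
        c=float(popt[2]),
        covariance=pcov,
        sse=sse,
        dof=int(x.size - 3),
    )


def prediction_interval(
    model: PowerModel, x: np.ndarray | float, level: float = 0.95
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Pointwise prediction interval for a new daily rate at day ``x``.

    Delta-method construction: ``f(x) +/- t_{dof,q} * sqrt(s2 + g'Vg)``
    with g the coefficient gradient at x, V the coefficient covariance,
    s2 the residual variance and q = (1+level)/2.  The lower limit is
    floored at zero (a rate cannot be negative).
    """
    xarr = np.asarray(x, dtype=float)
    if np.any(xarr <= 0):
        raise ValueError("day index must be positive")
    f = _power(xarr, model.a, model.b, model.c)
    g = model.gradient(xarr)
    var_fit = np.einsum("...i,ij,...j->...", g, model.covariance, g)
    half = stats.t.ppf((1.0 + level) / 2.0, model.dof) * np.sqrt(
        model.sigma2 + var_fit
    )
    low = np.maximum(f - half, 0.0)
    high = f + half
    if np.isscalar(x) or xarr.ndim == 0:
        return float(low), float(high)
    return low, high


@dataclass(frozen=True)
class WhaleEstimate:
    """Per-day whale count inverted from a corrected cue count."""

    day: int
    n_whales: float
    lower: float
    upper: float
    rate_used: float


def whales_from_cues(
    n_c_corrected: float,
    rate: float,
    p_sa: float,
    t_sa: TransitTime,
    rate_bounds: tuple[float, float] | None = None,
    unit: str = "day",
    rate_floor: float = 1e-6,
    day: int = 0,
) -> WhaleEstimate:
    """Whale count from a corrected cue count and a known cue rate.

    ``N_W = N_C / (r * P_SA * t_SA)``, the algebraic inverse of the
    cue-rate relation.  ``rate_bounds`` (low, high), typically the
    prediction interval of the rate curve, map to (upper, lower) whale
    bounds.  A rate bound at or below ``rate_floor`` yields an unbounded
    estimate: the corresponding whale bound is capped at the floor-based
    value and a :class:`LowRateWarning` is emitted.  The central rate
    itself must exceed the floor.
    """
    if not 0.0 < p_sa <= 1.0:
        raise ValueError("P_SA must be in (0, 1]")
    t = t_sa.value_days if unit == "day" else t_sa.value_hours
    if t <= 0:
        raise ValueError("transit time must be positive")
    if n_c_corrected < 0:
        raise ValueError("cue count must be nonnegative")
    if rate <= rate_floor:
        raise UndefinedRateError(
            f"cue rate {rate:g} at or below floor {rate_floor:g}: abundance diverges"
        )

    def _n(r: float) -> float:
        return n_c_corrected / (r * p_sa * t)

    n = _n(rate)
    if rate_bounds is None:
        lower = upper = n
    else:
        r_low, r_high = rate_bounds
        lower = _n(r_high) if r_high > rate_floor else _n(rate_floor)
        if r_low > rate_floor:
            upper = _n(r_low)
        else:
            upper = _n(rate_floor)
            warnings.warn(
                f"lower rate bound {r_low:g} at or below floor; whale upper bound "
                f"capped at {upper:.0f}",
                LowRateWarning,
                stacklevel=2,
            )
    return WhaleEstimate(day=day, n_whales=n, lower=lower, upper=upper, rate_used=rate)


def december_backestimate(
    daily_corrected_calls: dict[int, float],
    model: PowerModel,
    p_sa: float,
    t_sa: TransitTime,
    level: float = 0.95,
    rate_floor: float = 1e-6,
) -> tuple[list[WhaleEstimate], float, float]:
    """Whale numbers for acoustic-only days via the extrapolated rate curve.

    For each day index (key of ``daily_corrected_calls``) the calling
    rate is extrapolated from ``model`` and inverted through
    :func:`whales_from_cues`.  Returns the per-day estimates, the period
    total, and the minimum total (per-day counts at the upper prediction
    bound of the rate).  Days where the inversion fails are excluded
    from the totals with a warning.
    """
    estimates: list[WhaleEstimate] = []
    total = 0.0
    minimum_total = 0.0
    for day in sorted(daily_corrected_calls):
        n_c = daily_corrected_calls[day]
        rate = float(model(day))
        low, high = prediction_interval(model, day, level=level)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", LowRateWarning)
                est = whales_from_cues(
                    n_c,
                    rate,
                    p_sa,
                    t_sa,
                    rate_bounds=(low, high),
                    unit="day",
                    rate_floor=rate_floor,
                    day=day,
                )
        except (UndefinedRateError, ValueError) as exc:
            warnings.warn(f"day {day} excluded from totals: {exc}", stacklevel=2)
            continue
        estimates.append(est)
        total += est.n_whales
        minimum_total += est.lower
    return estimates, total, minimum_total
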