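"""Occupancy-to-OD600 calibration and Baranyi-Roberts growth-curve fitting.

Droplet occupancy (percent of droplet area covered by cells) is a proxy for
culture turbidity. A linear calibration against bulk cultures of known OD600
converts it to optical density; growth parameters (maximum specific growth
rate ``mu_max`` and lag time) are then extracted from OD600 time courses by
nonlinear least squares on the Baranyi-Roberts model.

The model, on the log-density scale y(t) = ln OD(t):

    y(t) = y0 + mu*A(t) - ln(1 + (exp(mu*A(t)) - 1) / exp(ymax - y0))
    A(t) = t + (1/mu) * ln(exp(-mu*t) + exp(-h0) - exp(-mu*t - h0))

``h0`` parameterizes the physiological state of the inoculum; the lag time
is the standard identity ``lag = h0 / mu_max``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "CalibrationCurve",
    "GrowthSeries",
    "GrowthFit",
    "fit_calibration",
    "occupancy_to_od",
    "baranyi_log_od",
    "baranyi_predict",
    "fit_growth",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Least-squares line mapping occupancy (%) to OD600."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    occupancy_range: tuple[float, float]

    def extrapolates(self, occupancy_pct):
        """True where a query lies outside the fitted occupancy range."""
        occ = np.asarray(occupancy_pct, dtype=float)
        lo, hi = self.occupancy_range
        return (occ < lo) | (occ > hi)


@dataclass(frozen=True)
class GrowthSeries:
    """An OD600 time course; times in hours, strictly increasing."""

    times_h: np.ndarray
    od600: np.ndarray
    sd: np.ndarray | None = None

    def __post_init__(self):
        t = np.asarray(self.times_h, dtype=float)
        od = np.asarray(self.od600, dtype=float)
        if t.shape != od.shape:
            raise ValueError("times and OD600 must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(od <= 0):
            raise ValueError("OD600 values must be positive")
        if self.sd is not None and np.any(np.asarray(self.sd) < 0):
            raise ValueError("standard deviations must be non-negative")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "od600", od)


@dataclass(frozen=True)
class GrowthFit:
    """Fitted Baranyi-Roberts parameters.

    ``lag_h = h0 / mu_max`` when ``mu_max > 0``; for a flat series the fit
    degenerates to ``mu_max = 0`` with the lag reported as 0 and
    ``lag_defined = False``.
    """

    mu_max_per_h: float
    lag_h: float
    y0_ln: float
    ymax_ln: float
    h0: float
    rss: float
    lag_defined: bool = True


def fit_calibration(pairs) -> CalibrationCurve:
    """Ordinary least squares of OD600 on occupancy.

    Parameters
    ----------
    pairs
        Iterable of ``(occupancy_pct, od600)`` tuples, or a 2-column array.
    """
    arr = np.asarray(list(pairs) if not isinstance(pairs, np.ndarray) else pairs,
                     dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (occupancy_pct, od600) tuples")
    if arr.shape[0] < 3:
        raise ValueError(f"need at least 3 calibration points, got {arr.shape[0]}")
    occ, od = arr[:, 0], arr[:, 1]
    if np.ptp(occ) == 0:
        raise ValueError("occupancy values are all identical; cannot fit a line")
    res = stats.linregress(occ, od)
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=arr.shape[0],
        occupancy_range=(float(occ.min()), float(occ.max())),
    )


def occupancy_to_od(curve: CalibrationCurve, occupancy_pct):
    """Convert occupancy (%) to OD600 through a fitted calibration curve.

    Extrapolation outside the fitted range is allowed; use
    :meth:`CalibrationCurve.extrapolates` to flag such queries.
    """
    occ = np.asarray(occupancy_pct, dtype=float)
    od = curve.slope * occ + curve.intercept
    return float(od) if np.isscalar(occupancy_pct) else od


def baranyi_log_od(t_h, y0_ln: float, ymax_ln: float, mu_max: float, h0: float):
    """Baranyi-Roberts log-density y(t) = ln OD(t).

    Satisfies y(0) = y0, y(t) -> ymax as t -> inf, and is monotone
    non-decreasing for mu_max >= 0.
    """
    if mu_max < 0:
        raise ValueError(f"mu_max must be >= 0, got {mu_max}")
    if h0 < 0:
        raise ValueError(f"h0 must be >= 0, got {h0}")
    t = np.asarray(t_h, dtype=float)
    if mu_max == 0:
        out = np.full_like(t, y0_ln)
        return float(out) if np.isscalar(t_h) else out
    # adjustment function: A(t) = t + ln(e^-mu t + e^-h0 - e^-mu t - h0)/mu,
    # written as ln(e^-mu t (1 - e^-h0) + e^-h0) for stability
    mt = mu_max * t
    if h0 > 1e-12:
        # ln(e^-mu t + e^-h0 - e^-(mu t + h0)) = ln(e^-mu t (1 - e^-h0) + e^-h0)
        log_inner = np.logaddexp(-mt + np.log1p(-np.exp(-h0)), -h0)
        a = t + log_inner / mu_max
    else:
        a = t
    m = mu_max * a
    d = ymax_ln - y0_ln
    if d < 0:
        raise ValueError("ymax_ln must be >= y0_ln")
    # ln(1 + (e^m - 1)/e^d) = ln(1 - e^-d + e^(m-d)), computed in log space
    c = -np.expm1(-d)  # 1 - e^-d in [0, 1)
    if c == 0.0:
        brake = m  # no headroom: y stays at y0
    else:
        brake = np.logaddexp(np.log(c), m - d)
    y = y0_ln + m - brake
    return float(y) if np.isscalar(t_h) else y


def baranyi_predict(fit: GrowthFit, t_h):
    """ln OD at time(s) ``t_h`` under a fitted Baranyi-Roberts model."""
    return baranyi_log_od(t_h, fit.y0_ln, fit.ymax_ln, fit.mu_max_per_h, fit.h0)


def _initial_guesses(t: np.ndarray, ln_od: np.ndarray):
    """Multi-start initial parameter sets from a log-linear segment scan."""
    y0 = float(ln_od[: max(2, len(ln_od) // 4)].min())
    ymax = float(ln_od.max())
    # steepest 3-point slope as the mu_max guess
    slopes = [
        (ln_od[i + 2] - ln_od[i]) / (t[i + 2] - t[i]) for i in range(len(t) - 2)
    ]
    i_best = int(np.argmax(slopes))
    mu = max(float(slopes[i_best]), 1e-3)
    # tangent-intercept lag estimate at the steepest point
    t_mid = 0.5 * (t[i_best] + t[i_best + 2])
    y_mid = 0.5 * (ln_od[i_best] + ln_od[i_best + 2])
    lag_est = max(t_mid - (y_mid - y0) / mu, 0.0)
    starts = []
    for lag in {0.0, 0.5 * lag_est, lag_est, 1.5 * lag_est}:
        starts.append((y0, max(ymax, y0 + 0.1), mu, mu * lag))
    return starts


def fit_growth(series: GrowthSeries, rss_tol: float = 1e-8) -> GrowthFit:
    """Fit the Baranyi-Roberts model to an OD600 time course.

    Nonlinear least squares on ln(OD) with multiple starting points drawn
    from a log-linear segment scan; the best (lowest-RSS) solution is kept.
    A flat series is reported as ``mu_max = 0`` with ``lag_defined=False``.
    """
    t = series.times_h
    ln_od = np.log(series.od600)
    if len(t) < 6:
        raise ValueError(f"need at least 6 time points, got {len(t)}")
    if np.ptp(ln_od) < 1e-8:
        return GrowthFit(
            mu_max_per_h=0.0, lag_h=0.0, y0_ln=float(ln_od.mean()),
            ymax_ln=float(ln_od.mean()), h0=0.0,
            rss=float(np.sum((ln_od - ln_od.mean()) ** 2)), lag_defined=False,
        )

    def residuals(theta):
        y0, ymax, mu, h0 = theta
        return baranyi_log_od(t, y0, ymax, mu, h0) - ln_od

    lo = [ln_od.min() - 2.0, ln_od.min(), 0.0, 0.0]
    hi = [ln_od.max(), ln_od.max() + 5.0, 50.0, 500.0]
    best = None
    for start in _initial_guesses(t, ln_od):
        x0 = np.clip(start, lo, hi)
        try:
            sol = optimize.least_squares(
                residuals, x0, bounds=(lo, hi), xtol=1e-12, ftol=rss_tol, gtol=1e-12
            )
        except ValueError:
            continue
        rss = float(2 * sol.cost)
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        raise RuntimeError("growth fit failed to converge from any starting point")
    rss, (y0, ymax, mu, h0) = best
    lag = h0 / mu if mu > 0 else 0.0
    return GrowthFit(
        mu_max_per_h=float(mu), lag_h=float(lag), y0_ln=float(y0),
        ymax_ln=float(ymax), h0=float(h0), rss=rss, lag_defined=mu > 0,
    )
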