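"""Logistic grain-filling model: fitting and derived filling parameters.

Thousand-grain dry weight y over the middle and late filling period (t in
days, t=0 at 27 days after flowering) is modelled with the logistic curve

    y(t) = k / (1 + a * exp(-b * t)),

where k (g) is the theoretical maximum thousand-grain weight and a, b > 0
are shape coefficients.  The instantaneous filling rate is its derivative

    V(t) = k * a * b * exp(-b*t) / (1 + a*exp(-b*t))^2.

From a fitted (k, a, b) the standard filling parameters follow in closed
form:

====== ======================================== =====================
C0     initial grain weight y(0) = k/(1+a)       g
Vmax   maximum filling rate = k*b/4              g/day (at inflection)
Vmean  mean filling rate = k*b/6                 g/day
D      active filling period = 6/b               days (k = Vmean * D)
T      filling end time: y(T) = 0.96*k           days
V      late filling rate V(T)                    g/day
Y      late grain accumulation y(T) = 0.96*k     g
====== ======================================== =====================

A fit is flagged inadequate when R^2 <= 0.95, the screening bound used to
accept that the logistic class truly describes a series.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "LogisticFit",
    "logistic",
    "filling_rate",
    "fit_logistic",
    "derive_parameters",
    "fit_table",
    "R2_ADEQUATE",
]

#: Fits with R^2 at or below this bound are flagged inadequate.
R2_ADEQUATE = 0.95


def logistic(t, k, a, b):
    """y(t) = k / (1 + a * exp(-b*t))."""
    t = np.asarray(t, dtype=float)
    return k / (1.0 + a * np.exp(-b * t))


@dataclasses.dataclass(frozen=True)
class LogisticFit:
    """Fitted logistic parameters with goodness of fit.

    ``adequate`` is True iff R^2 exceeds :data:`R2_ADEQUATE`.
    """

    k: float
    a: float
    b: float
    r2: float

    def __post_init__(self) -> None:
        if not (self.k > 0 and self.a > 0 and self.b > 0):
            raise ValueError("k, a, b must all be positive")

    @property
    def adequate(self) -> bool:
        return self.r2 > R2_ADEQUATE

    def predict(self, t):
        return logistic(t, self.k, self.a, self.b)

    def rate(self, t):
        return filling_rate(self, t)


def filling_rate(fit: LogisticFit, t):
    """Instantaneous filling rate V(t) = k a b e^(-bt) / (1 + a e^(-bt))^2.

    Positive for all finite t, vanishing in both limits, and maximal at the
    inflection t* = ln(a)/b where V(t*) = k*b/4.
    """
    t = np.asarray(t, dtype=float)
    e = fit.a * np.exp(-fit.b * t)
    return fit.k * fit.b * e / (1.0 + e) ** 2


def _init_candidates(t: np.ndarray, y: np.ndarray) -> list[tuple[float, float, float]]:
    """Starting points: log-linearized estimate first, then a coarse grid."""
    cands = []
    ymax = float(y.max())
    for infl in (1.05, 1.2, 1.5):
        k0 = infl * ymax
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.log(np.clip(k0 / np.clip(y, 1e-9, None) - 1.0, 1e-9, None))
        good = np.isfinite(z)
        if good.sum() >= 2 and np.ptp(t[good]) > 0:
            slope, intercept = np.polyfit(t[good], z[good], 1)
            b0, a0 = -float(slope), float(math.exp(intercept))
            if b0 > 0 and a0 > 0:
                cands.append((k0, a0, b0))
    # coarse multi-start fallback spanning realistic filling dynamics
    for k0 in (1.05 * ymax, 1.3 * ymax):
        for a0 in (5.0, 20.0, 50.0):
            for b0 in (0.1, 0.2, 0.35):
                cands.append((k0, a0, b0))
    return cands


def fit_logistic(t: Sequence[float], y: Sequence[float]) -> LogisticFit:
    """Nonlinear least-squares fit of the logistic filling curve.

    Parameters
    ----------
    t : array-like of days (t=0 at 27 days after flowering), strictly
        increasing, length >= 4 (three free parameters).
    y : array-like of thousand-grain weights (g), non-negative, not all
        equal.

    Returns
    -------
    LogisticFit with R^2 = 1 - SSE/SST.  A fit that converges but explains
    the data poorly (non-sigmoid input) is returned with
    ``adequate == False`` rather than rejected silently.

    Raises
    ------
    ValueError
        On invalid input (too few points, non-increasing t, negative or
        constant y).
    RuntimeError
        If no initialization converges.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("t and y must be 1-D arrays of equal length")
    if len(t) < 4:
        raise ValueError(f"need >=4 observations to fit 3 parameters, got {len(t)}")
    if np.any(np.diff(t) <= 0):
        raise ValueError("t must be strictly increasing")
    if np.any(y < 0):
        raise ValueError("grain weights must be non-negative")
    if np.ptp(y) == 0:
        raise ValueError("y is constant; logistic fit undefined")

    sst = float(((y - y.mean()) ** 2).sum())
    best, best_sse = None, np.inf
    errors = []
    bounds = ([1e-9, 1e-9, 1e-9], [np.inf, np.inf, np.inf])
    for p0 in _init_candidates(t, y):
        try:
            popt, _ = optimize.curve_fit(logistic, t, y, p0=p0, bounds=bounds,
                                         maxfev=20000)
        except (RuntimeError, optimize.OptimizeWarning) as exc:  # no convergence
            errors.append(str(exc))
            continue
        sse = float(((y - logistic(t, *popt)) ** 2).sum())
        if sse < best_sse:
            best, best_sse = popt, sse
    if best is None:
        raise RuntimeError(
            "logistic fit failed to converge from all initializations; "
            f"diagnostics: {errors[:3]}")
    r2 = 1.0 - best_sse / sst
    return LogisticFit(k=float(best[0]), a=float(best[1]), b=float(best[2]),
                       r2=float(r2))


def derive_parameters(fit: LogisticFit, y_definition: str = "at_T") -> dict:
    """All derived filling parameters from a fitted curve.

    Parameters
    ----------
    fit : LogisticFit
    y_definition : {"at_T", "remaining"}
        Reading of the late grain accumulation Y: the weight accumulated
        by the filling end time T (``y(T) = 0.96k``, the default, literal
        reading) or the increment still to come (``k - y(T) = 0.04k``).
        Both are reported; this switch selects which one ``y_late`` names.

    Returns
    -------
    dict with keys ``c0, vmax, vmean, d, t_end, v_late, y_late,
    y_at_T, y_remaining`` (grams, g/day and days on the t=0-at-27-DAP
    scale).
    """
    if y_definition not in ("at_T", "remaining"):
        raise ValueError(f"unknown y_definition {y_definition!r}")
    k, a, b = fit.k, fit.a, fit.b
    c0 = k / (1.0 + a)
    vmax = k * b / 4.0
    vmean = k * b / 6.0
    d = 6.0 / b
    # y(T) = 0.96 k  =>  T = -ln[(100/96 - 1)/a] / b
    t_end = -math.log((100.0 / 96.0 - 1.0) / a) / b
    v_late = float(filling_rate(fit, t_end))
    y_at_t = float(logistic(t_end, k, a, b))
    y_remaining = k - y_at_t
    return {
        "c0": c0, "vmax": vmax, "vmean": vmean, "d": d, "t_end": t_end,
        "v_late": v_late,
        "y_late": y_at_t if y_definition == "at_T" else y_remaining,
        "y_at_T": y_at_t, "y_remaining": y_remaining,
    }


def fit_table(series: pd.DataFrame, y_definition: str = "at_T") -> pd.DataFrame:
    """Fit every line in a long filling table.

    ``series`` has columns ``line, t_days, tgw_g``.  Returns one row per
    line with k, a, b, r2, adequate and every derived parameter.
    """
    rows = []
    for line, sub in series.groupby("line", sort=True):
        sub = sub.sort_values("t_days")
        fit = fit_logistic(sub["t_days"].to_numpy(), sub["tgw_g"].to_numpy())
        row = {"line": line, "k": fit.k, "a": fit.a, "b": fit.b,
               "r2": fit.r2, "adequate": fit.adequate}
        row.update(derive_parameters(fit, y_definition=y_definition))
        rows.append(row)
    return pd.DataFrame(rows)
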