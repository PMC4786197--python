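"""Scalar summary statistics extracted from occupancy traces.

These are the readouts the optimizer fits: peak open probability, time to 50%
decay of the open-state trace (Tau50), single/double exponential fits of
recovery time courses, the voltage dependence of the recovery rate, and the
analytic mean open time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .core_model import RateParams, eval_rates
from .errors import (
    DegenerateRegressionError,
    FitFailureError,
    ReadoutUndefinedError,
)


def peak_open(t: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Maximum of an open-occupancy trace and the time it occurs at.

    An all-zero trace is degenerate: a warning is emitted and (0.0, 0.0)
    returned.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size == 0:
        raise ReadoutUndefinedError("empty trace")
    if np.all(y == 0):
        warnings.warn("all-zero trace; peak undefined", stacklevel=2)
        return 0.0, 0.0
    i = int(np.argmax(y))
    return float(y[i]), float(t[i])


def time_to_half_decay(
    t: Sequence[float],
    y: Sequence[float],
    refine: Optional[Callable[[float], float]] = None,
    refine_deriv: Optional[Callable[[float], float]] = None,
    rtol: float = 1e-12,
) -> float:
    """First time after the peak at which the trace falls to half its peak.

    The sampled trace locates the peak and brackets the crossing; if
    ``refine`` (an analytic evaluation of O(t) at arbitrary t, e.g. the
    matrix-exponential segment solution) is given, the crossing is polished by
    bisection on it, otherwise linear interpolation between samples is used.
    Tau50 is measured from the peak time.  Raises if the trace never decays
    below half-peak.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    peak, t_peak = peak_open(t, y)
    if peak <= 0:
        raise ReadoutUndefinedError("trace has no positive peak; Tau50 undefined")
    if refine is not None:
        # polish the peak on the analytic solution so the readout does not
        # inherit the sampling grid: prefer the derivative root, fall back to
        # bounded scalar maximization
        i = int(np.argmax(y))
        lo_b = t[max(i - 1, 0)]
        hi_b = t[min(i + 1, t.size - 1)]
        if hi_b > lo_b:
            if refine_deriv is not None:
                from scipy.optimize import brentq

                d_lo, d_hi = refine_deriv(lo_b), refine_deriv(hi_b)
                if d_lo > 0 > d_hi:
                    tp = brentq(refine_deriv, lo_b, hi_b, xtol=1e-13)
                    if refine(tp) >= peak:
                        peak, t_peak = float(refine(tp)), float(tp)
            else:
                from scipy.optimize import minimize_scalar

                res = minimize_scalar(
                    lambda x: -refine(x), bounds=(lo_b, hi_b), method="bounded",
                    options={"xatol": 1e-12},
                )
                if -res.fun >= peak:
                    peak, t_peak = float(-res.fun), float(res.x)
    half = 0.5 * peak
    after = t >= t_peak
    ta, ya = t[after], y[after]
    below = np.nonzero(ya <= half)[0]
    crossing = None
    for i in below:
        if i > 0:
            crossing = (ta[i - 1], ta[i])
            break
    if crossing is None:
        raise ReadoutUndefinedError("trace never decays below half of its peak")
    lo, hi = crossing
    if refine is not None:
        # monotone bisection on the analytic segment solution
        f = lambda x: refine(x) - half
        flo, fhi = f(lo), f(hi)
        if flo < 0:  # numerical edge: sampled point already below
            return float(lo - t_peak)
        if fhi < 0:
            from scipy.optimize import brentq

            return float(brentq(f, lo, hi, xtol=1e-13) - t_peak)
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if f(mid) > 0:
                lo = mid
            else:
                hi = mid
            if hi - lo <= rtol * max(1.0, hi):
                break
        return float(0.5 * (lo + hi) - t_peak)
    y0, y1 = np.interp([lo, hi], ta, ya)
    if y1 == y0:
        return float(lo - t_peak)
    frac = (y0 - half) / (y0 - y1)
    return float(lo + frac * (hi - lo) - t_peak)


@dataclass(frozen=True)
class ExpFit:
    """Result of fitting y = C1 - A1*exp(-t/tau1) [- A2*exp(-t/tau2)].

    For double-exponential fits the components are ordered tau1 <= tau2.
    """

    C1: float
    A1: float
    tau1: float
    A2: Optional[float] = None
    tau2: Optional[float] = None
    residual_norm: float = 0.0

    @property
    def n_components(self) -> int:
        return 1 if self.A2 is None else 2


def _exp_model(theta: np.ndarray, t: np.ndarray, n: int) -> np.ndarray:
    if n == 1:
        C1, A1, tau1 = theta
        return C1 - A1 * np.exp(-t / tau1)
    C1, A1, tau1, A2, tau2 = theta
    return C1 - A1 * np.exp(-t / tau1) - A2 * np.exp(-t / tau2)


def fit_exponential(
    t: Sequence[float],
    y: Sequence[float],
    n_components: int = 1,
    initial: Optional[Sequence[float]] = None,
) -> ExpFit:
    """Least-squares fit of the rising-exponential recovery form.

    The functional form is y = C1 - A1 e^(-t/tau1) (- A2 e^(-t/tau2) for
    ``n_components=2``).  Time constants are constrained positive; the result
    is deterministic given the initial guess.  ``initial`` is
    (C1, A1, tau1[, A2, tau2]); a heuristic guess is built when omitted.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    n_free = 3 if n_components == 1 else 5
    if t.size < 2 * n_free // 2 or t.size < n_free:
        raise ValueError(f"need at least {n_free} points for a {n_components}-component fit")
    span = max(t.max() - t.min(), 1.0)
    if initial is None:
        c0 = float(y.max())
        a0 = max(float(y.max() - y.min()), 1e-6)
        if n_components == 1:
            initial = (c0, a0, span / 5)
        else:
            initial = (c0, 0.7 * a0, span / 20, 0.3 * a0, span / 2)
    theta0 = np.asarray(initial, dtype=float)
    if theta0.size != n_free:
        raise ValueError(f"initial guess must have {n_free} entries")
    lb = np.full(n_free, -np.inf)
    ub = np.full(n_free, np.inf)
    if n_components == 1:
        lb[2] = 1e-12
    else:
        lb[2] = lb[4] = 1e-12
    theta0 = np.clip(theta0, lb + 1e-12, None)
    res = least_squares(
        lambda th: _exp_model(th, t, n_components) - y,
        theta0,
        bounds=(lb, ub),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=20000,
    )
    if not res.success and res.cost > 1e-6:
        raise FitFailureError("exponential fit failed to converge", best=res.x)
    theta = res.x
    rnorm = float(np.linalg.norm(res.fun))
    if n_components == 1:
        return ExpFit(C1=theta[0], A1=theta[1], tau1=theta[2], residual_norm=rnorm)
    C1, A1, tau1, A2, tau2 = theta
    if tau1 > tau2:  # ordering convention: tau1 is the fast component
        A1, tau1, A2, tau2 = A2, tau2, A1, tau1
    return ExpFit(C1=C1, A1=A1, tau1=tau1, A2=A2, tau2=tau2, residual_norm=rnorm)


def rate_from_recovery(
    fits: dict[float, "ExpFit | float"],
    proportionality: float = 1.0,
) -> Tuple[float, float]:
    """Extract (a, b) of the recovery rate alpha3(V) = a * exp(-V/b).

    The recovery rate at each voltage is taken proportional to 1/tau1 of the
    (double-) exponential fit there (``proportionality`` is the constant of
    proportionality, default 1).  log(rate) is regressed linearly on V:
    slope = -1/b, intercept = log(a).  A flat dependence (zero slope) or
    duplicated voltages raise DegenerateRegressionError.
    """
    if len(fits) < 2:
        raise DegenerateRegressionError("need fits at >= 2 voltages")
    V = np.array(sorted(fits), dtype=float)
    if np.unique(V).size != V.size:
        raise DegenerateRegressionError("identical voltages in recovery fits")
    taus = np.array(
        [fits[v].tau1 if isinstance(fits[v], ExpFit) else float(fits[v]) for v in sorted(fits)]
    )
    if np.any(taus <= 0):
        raise DegenerateRegressionError("non-positive tau1 in recovery fits")
    logk = np.log(proportionality / taus)
    slope, intercept = np.polyfit(V, logk, 1)
    if abs(slope) < 1e-12 or not math.isfinite(slope):
        raise DegenerateRegressionError("zero voltage slope: b is unbounded")
    return float(math.exp(intercept)), float(-1.0 / slope)


def mean_open_time(params: RateParams, V: float) -> float:
    """Analytic mean open time at V: reciprocal of the total exit rate from O.

    MOT = 1 / (beta13 + alpha2 + alphax); an (unreachable for positive
    parameters) zero exit rate raises ReadoutUndefinedError.
    """
    r = eval_rates(params, V)
    exit_rate = r.b13 + r.a2 + r.ax
    if exit_rate <= 0:
        raise ReadoutUndefinedError("zero exit rate from O: mean open time infinite")
    return 1.0 / exit_rate
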