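"""Growth-kinetics classification: linear vs exponential fits on normalized curves.

Each normalized curve (time and volume mapped to the unit interval, see
:mod:`gliogrow.trajectory`) is fit with two models:

    poly1:  y = p1 * x + p2          (ordinary least squares)
    exp1:   y = a * exp(b * x)       (nonlinear least squares, multi-start)

A curve is classified *exponential* when its exp1 sum of squared errors is
strictly below 0.6 times the linear sse — a factor chosen so that curves
passing the rule fit the exponential model with r^2 > 0.85.  Curves with
nonlinear kinetics can additionally be pooled into a single exp1 fit over
the union of their points, summarizing the cohort's nonlinear growth shape.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .errors import FitConvergenceError, InvalidInputError
from .trajectory import NormalizedCurve

__all__ = [
    "GrowthFit",
    "PooledFit",
    "fit_linear",
    "fit_exponential",
    "classify_curve",
    "fit_growth",
    "pooled_fit",
    "SSE_RATIO",
]

#: Exponential-classification rule: sse_exp < SSE_RATIO * sse_lin.
SSE_RATIO = 0.6

_SSE_TOL = 1e-10


@dataclass(frozen=True)
class GrowthFit:
    """Both model fits for one curve plus the kinetics classification."""

    p1: float
    p2: float
    a: float
    b: float
    sse_lin: float
    sse_exp: float
    r2: float
    classification: str
    case_id: str = ""


@dataclass(frozen=True)
class PooledFit:
    """Single exp1 fit over the pooled points of several curves."""

    a: float
    b: float
    sse: float
    r2: float
    n_points: int
    n_curves: int


def _xy(curve: NormalizedCurve) -> Tuple[np.ndarray, np.ndarray]:
    return np.asarray(curve.times, float), np.asarray(curve.volumes, float)


def fit_linear(curve: NormalizedCurve) -> Tuple[float, float, float]:
    """OLS fit of y = p1*x + p2; returns (p1, p2, sse)."""
    x, y = _xy(curve)
    if len(np.unique(x)) < 2:
        raise InvalidInputError("linear fit needs at least 2 distinct x values")
    p1, p2 = np.polyfit(x, y, 1)
    resid = y - (p1 * x + p2)
    return float(p1), float(p2), float(resid @ resid)


def _exp_model(params: np.ndarray, x: np.ndarray) -> np.ndarray:
    a, b = params
    return a * np.exp(np.clip(b * x, -700.0, 700.0))


def _exp_starts(x: np.ndarray, y: np.ndarray) -> List[Tuple[float, float]]:
    """Multi-start initializations for exp1 (the model is start-sensitive)."""
    eps = 1e-6
    a0 = y[0] if y[0] > 0 else eps
    pos = y > 0
    if pos.sum() >= 2 and len(np.unique(x[pos])) >= 2:
        b0 = float(np.polyfit(x[pos], np.log(y[pos]), 1)[0])
    else:
        b0 = 1.0
    return [(float(a0), b0), (float(max(y.max(), eps)), 1.0), (0.01, 3.0)]


# Rate bound on the normalized time domain [0, 1].  Unbounded, curves that
# exp1 cannot represent drive the fit to the degenerate single-point spike
# a -> 0, b -> inf (sse plateaus while the parameters diverge); |b| <= 50
# is far beyond any observable kinetics on [0, 1] yet keeps the problem
# well-posed.
_B_BOUND = 50.0


def _fit_exp_points(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    best = None
    best_converged = False
    for a0, b0 in _exp_starts(x, y):
        b0 = float(np.clip(b0, -_B_BOUND + 1e-3, _B_BOUND - 1e-3))
        try:
            res = least_squares(
                lambda p: _exp_model(p, x) - y,
                x0=[a0, b0],
                method="trf",
                bounds=([-np.inf, -_B_BOUND], [np.inf, _B_BOUND]),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=20_000,
            )
        except Exception:
            continue
        sse = float(2 * res.cost)
        if best is None or sse < best[2]:
            best = (float(res.x[0]), float(res.x[1]), sse)
        best_converged = best_converged or bool(res.success)
    if best is None or not best_converged:
        raise FitConvergenceError("exp1 fit failed to converge from every start", best)
    return best


def fit_exponential(curve: NormalizedCurve) -> Tuple[float, float, float]:
    """Nonlinear least-squares fit of y = a*exp(b*x); returns (a, b, sse).

    Runs from several starts (log-linear slope, amplitude-based, and a
    generic nonlinear-growth start) and keeps the lowest converged sse.
    """
    x, y = _xy(curve)
    if len(x) < 3:
        raise InvalidInputError("exponential fit needs at least 3 points")
    return _fit_exp_points(x, y)


def classify_curve(sse_lin: float, sse_exp: float) -> str:
    """Kinetics label: exponential iff sse_exp < 0.6 * sse_lin (strict)."""
    if sse_lin < 0 or sse_exp < 0:
        raise InvalidInputError("sse values must be nonnegative")
    return "exponential" if sse_exp < SSE_RATIO * sse_lin else "linear"


def _r_squared(y: np.ndarray, sse: float) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if sse <= _SSE_TOL else 0.0
    return 1.0 - sse / ss_tot


def fit_growth(curve: NormalizedCurve) -> GrowthFit:
    """Fit both models, classify, and report r^2 of the selected model."""
    p1, p2, sse_lin = fit_linear(curve)
    a, b, sse_exp = fit_exponential(curve)
    label = classify_curve(sse_lin, sse_exp)
    _, y = _xy(curve)
    r2 = _r_squared(y, sse_exp if label == "exponential" else sse_lin)
    return GrowthFit(p1, p2, a, b, sse_lin, sse_exp, r2, label, case_id=curve.case_id)


def pooled_fit(curves: Iterable[NormalizedCurve]) -> PooledFit:
    """One exp1 fit over the union of all curves' (time, volume) points."""
    curves = list(curves)
    if not curves:
        raise InvalidInputError("need at least one curve to pool")
    x = np.concatenate([np.asarray(c.times, float) for c in curves])
    y = np.concatenate([np.asarray(c.volumes, float) for c in curves])
    if len(x) < 3:
        raise InvalidInputError("pooled fit needs at least 3 points")
    a, b, sse = _fit_exp_points(x, y)
    return PooledFit(a, b, sse, _r_squared(y, sse), n_points=len(x), n_curves=len(curves))
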