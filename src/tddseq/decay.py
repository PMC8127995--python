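"""Exponential decay fitting for probe:loading-control time courses.

The model is a single exponential with a steady-state floor, fitted in log
space::

    log y(t) = log(A * exp(-k t) + B)

where ``y`` is the probe:control ratio (e.g. transfected miR-7 normalized to
endogenous miR-11), ``A`` the initial ratio of the transfected species, ``B``
the steady-state ratio contributed by the endogenous species, and ``k`` a
first-order rate constant that folds together molecular decay and dilution by
cell division. The reported half-life is ln(2)/k and therefore also reflects
both processes.

Fitting minimizes the sum of squared log-residuals with bounded L-BFGS-B,
re-launched in a warm-started chain (up to ``n_chain`` rounds) so the result
is robust to the optimizer's local stopping behaviour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "DecayCourse",
    "DecayFit",
    "fit_decay",
    "half_life",
    "loglinear_reference_fit",
    "DEFAULT_BOUNDS",
]

#: (lower, upper) bounds for (rate_k, amplitude_A, baseline_B). The amplitude
#: is confined to [0.001, 10]; rate and baseline are bounded below at 1e-8 and
#: unbounded above.
DEFAULT_BOUNDS = ((1e-8, None), (1e-3, 10.0), (1e-8, None))


@dataclass
class DecayCourse:
    """A decay time course: hours vs probe:loading-control ratios."""

    times_h: np.ndarray
    ratios: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.times_h.shape != self.ratios.shape:
            raise ValueError("times and ratios must have equal length")
        if (self.ratios <= 0).any():
            raise ValueError("ratios must be positive (the model is fit in log space)")


@dataclass
class DecayFit:
    rate_k: float
    amplitude_A: float
    baseline_B: float
    ssr: float
    n_iterations: int
    converged: bool
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def half_life_h(self) -> float:
        return math.log(2.0) / self.rate_k


def _log_model(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    k, a, b = params
    return np.log(a * np.exp(-k * t) + b)


def _objective(params: np.ndarray, t: np.ndarray, logy: np.ndarray) -> float:
    resid = logy - _log_model(params, t)
    return float(resid @ resid)


def fit_decay(course: DecayCourse, bounds=DEFAULT_BOUNDS, n_chain: int = 100,
              tol: float = 1e-10, fix_baseline_zero: bool = False,
              x0: np.ndarray | None = None) -> DecayFit:
    """Fit the log-transformed single-exponential model to a course.

    The bounded quasi-Newton optimization is chained: each round restarts
    from the previous solution, up to ``n_chain`` rounds, stopping early once
    the parameter vector moves less than ``tol`` (max absolute change).

    ``fix_baseline_zero`` pins B at 0 (pure exponential), in which case the
    fit should agree with :func:`loglinear_reference_fit` on noiseless data.
    """
    t = course.times_h
    if t.size < 3:
        raise ValueError("need at least 3 time points to fit the three-parameter model")
    logy = np.log(course.ratios)

    if x0 is None:
        a0 = float(np.clip(course.ratios[0], bounds[1][0], bounds[1][1]))
        b0 = 0.5 * float(course.ratios[-1])
        span = float(t.max() - t.min()) or 1.0
        x0 = np.array([math.log(2.0) / span, a0, max(b0, 1e-8)])
    x = np.asarray(x0, dtype=float)

    # internally the amplitude is optimized on a log scale, which makes the
    # B = 0 case an exactly quadratic problem in (log A, k)
    def unpack(p):
        b = 0.0 if fix_baseline_zero else p[2]
        return np.array([p[0], math.exp(p[1]), b])

    log_a_bounds = (math.log(bounds[1][0]), math.log(bounds[1][1]))
    if fix_baseline_zero:
        fit_bounds = [bounds[0], log_a_bounds]
        x = np.array([x[0], math.log(x[1])])
    else:
        fit_bounds = [bounds[0], log_a_bounds, bounds[2]]
        x = np.array([x[0], math.log(x[1]), x[2]])

    def obj(p):
        return _objective(unpack(p), t, logy)

    def grad(p):
        k, a, b = unpack(p)
        m = a * np.exp(-k * t)
        s = m + b
        r = logy - np.log(s)
        g_k = float(np.sum(2.0 * r * t * m / s))
        g_loga = float(-np.sum(2.0 * r * m / s))
        if fix_baseline_zero:
            return np.array([g_k, g_loga])
        g_b = float(-np.sum(2.0 * r / s))
        return np.array([g_k, g_loga, g_b])

    if not np.isfinite(obj(x)):
        # fall back to a neutral start inside the bounds
        x = np.array([1e-2, 0.0, 1e-8][: x.size])

    n_done = 0
    converged = False
    res = None
    for _ in range(n_chain):
        res = minimize(obj, x, jac=grad, method="L-BFGS-B", bounds=fit_bounds,
                       options={"ftol": 1e-15, "gtol": 1e-12})
        n_done += 1
        if np.max(np.abs(res.x - x)) < tol:
            x = res.x
            converged = True
            break
        x = res.x

    k, a, b = (float(v) for v in unpack(x))
    flags = []
    if k <= bounds[0][0] * (1 + 1e-6):
        flags.append("half-life unbounded above (rate at lower bound)")
    return DecayFit(rate_k=k, amplitude_A=a, baseline_B=b,
                    ssr=float(res.fun), n_iterations=n_done,
                    converged=converged, flags=tuple(flags))


def half_life(fit: DecayFit) -> float:
    """ln(2)/k, in hours; encapsulates both decay and dilution."""
    if fit.rate_k <= 0:
        raise ValueError("rate must be positive")
    return math.log(2.0) / fit.rate_k


def loglinear_reference_fit(course: DecayCourse) -> tuple[float, float]:
    """Closed-form OLS of log(ratio) on time, valid when B = 0.

    Returns (k, A) with k = -slope and A = exp(intercept). Serves as an
    analytic reference for :func:`fit_decay` with the baseline pinned to 0.
    """
    if course.times_h.size < 2:
        raise ValueError("need at least 2 points for the log-linear fit")
    slope, intercept = np.polyfit(course.times_h, np.log(course.ratios), 1)
    return float(-slope), float(math.exp(intercept))
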