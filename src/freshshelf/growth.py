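"""Primary microbial growth models for log-scale plate counts.

Four sigmoidal primary models widely used in predictive microbiology are
implemented on the log10 CFU/g scale: the modified Gompertz, the modified
Logistic, the Baranyi-Roberts model and the Huang model.  Each maps storage
time ``t`` (days) to a bacterial count ``N(t)`` (log10 CFU per gram) and is
parameterised by the initial count ``N0``, the maximum count ``Nmax``, the
maximum specific growth rate ``mu_max`` (1/d) and the lag time ``lag`` (d).

All four curves are non-decreasing in ``t`` and bounded above by ``Nmax``,
so the time at which a count limit is crossed is unique; :func:`invert_growth`
recovers it in closed form for Gompertz/Logistic and by bracketed
root-finding for Baranyi/Huang.

The Baranyi and Huang right-hand sides contain ``exp`` of quantities like
``Nmax`` that would overflow if evaluated literally for plausible log counts;
they are therefore evaluated in the log domain (shifted log-sum-exp), which
also makes ``N(0) = N0`` hold to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.optimize import brentq

from .errors import (
    LimitAlreadyExceededError,
    LimitNeverReachedError,
    ParameterDomainError,
)

__all__ = [
    "MODEL_KINDS",
    "GrowthParams",
    "evaluate_gompertz",
    "evaluate_logistic",
    "evaluate_baranyi",
    "evaluate_huang",
    "evaluate_growth",
    "invert_growth",
]

#: The closed set of primary growth model identifiers.
MODEL_KINDS = ("gompertz", "logistic", "baranyi", "huang")

_E = math.e


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of a primary growth model.

    Attributes
    ----------
    n0 : float
        Initial count, log10 CFU/g.
    nmax : float
        Maximum (stationary-phase) count, log10 CFU/g.  Must exceed ``n0``.
    mu_max : float
        Maximum specific growth rate, 1/d.  Strictly positive.
    lag : float
        Lag time lambda, d.  Non-negative.
    """

    n0: float
    nmax: float
    mu_max: float
    lag: float

    def __post_init__(self) -> None:
        vals = (self.n0, self.nmax, self.mu_max, self.lag)
        if not all(math.isfinite(v) for v in vals):
            raise ParameterDomainError(f"growth parameters must be finite, got {vals}")
        if self.nmax <= self.n0:
            raise ParameterDomainError(
                f"nmax ({self.nmax}) must exceed n0 ({self.n0})"
            )
        if self.mu_max <= 0:
            raise ParameterDomainError(f"mu_max must be positive, got {self.mu_max}")
        if self.lag < 0:
            raise ParameterDomainError(f"lag must be non-negative, got {self.lag}")

    @property
    def h0(self) -> float:
        """Physiological-state product h0 = lag * mu_max (Baranyi adjustment)."""
        return self.lag * self.mu_max

    def astuple(self) -> tuple[float, float, float, float]:
        return (self.n0, self.nmax, self.mu_max, self.lag)


ArrayLike = Union[float, np.ndarray]


def _check_time(t: ArrayLike) -> np.ndarray:
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise ValueError("storage time t must be non-negative")
    return arr


def _maybe_scalar(x: np.ndarray, t: ArrayLike) -> ArrayLike:
    if np.isscalar(t) or (isinstance(t, np.ndarray) and t.ndim == 0):
        return float(np.ravel(x)[0])
    return x


def evaluate_gompertz(t: ArrayLike, p: GrowthParams) -> ArrayLike:
    """Modified Gompertz count at time ``t`` (days).

    N(t) = N0 + (Nmax - N0) * exp(-exp(mu_max*e/(Nmax-N0) * (lag - t) + 1))
    """
    tt = _check_time(t)
    span = p.nmax - p.n0
    inner = p.mu_max * _E / span * (p.lag - tt) + 1.0
    # exp(inner) may overflow for t far left of the lag; the outer
    # exp(-inf) -> 0 limit is the correct value there.
    with np.errstate(over="ignore"):
        val = p.n0 + span * np.exp(-np.exp(inner))
    return _maybe_scalar(val, t)


def evaluate_logistic(t: ArrayLike, p: GrowthParams) -> ArrayLike:
    """Modified Logistic count at time ``t`` (days).

    N(t) = Nmax / (1 + (Nmax/N0 - 1) * exp(mu_max * (lag - t)))
    """
    if p.n0 <= 0:
        raise ParameterDomainError("logistic model requires n0 > 0")
    tt = _check_time(t)
    with np.errstate(over="ignore"):
        val = p.nmax / (1.0 + (p.nmax / p.n0 - 1.0) * np.exp(p.mu_max * (p.lag - tt)))
    return _maybe_scalar(val, t)


def _baranyi_adjustment(t: np.ndarray, mu: float, h0: float) -> np.ndarray:
    # A(t) = t + (1/mu) * ln(exp(-mu t) + exp(-h0) - exp(-mu t - h0))
    # Stable form: with a = -mu t, b = -h0 (both <= 0) and m = max(a, b),
    #   ln(e^a + e^b - e^{a+b}) = m + log1p(e^{min-m} * (1 - e^m)).
    a = -mu * t
    b = np.full_like(a, -h0)
    m = np.maximum(a, b)
    mn = np.minimum(a, b)
    log_s = m + np.log1p(np.exp(mn - m) * -np.expm1(m))
    return t + log_s / mu


def evaluate_baranyi(t: ArrayLike, p: GrowthParams) -> ArrayLike:
    """Baranyi-Roberts count at time ``t`` (days), log-domain stable.

    N(t) = N0 + mu*A(t) - ln(1 + (exp(mu*A(t)) - 1) / exp(Nmax - N0))
    with adjustment function A(t) built from h0 = lag * mu_max.
    """
    tt = _check_time(np.atleast_1d(np.asarray(t, dtype=float)))
    mu = p.mu_max
    d = p.nmax - p.n0
    x = mu * _baranyi_adjustment(tt, mu, p.h0)
    # ln(1 + (e^x - 1) e^{-d}) = -d + ln(e^x + e^d - 1), shifted by max(x, d).
    m = np.maximum(x, d)
    log_term = -d + m + np.log(np.exp(x - m) + np.exp(d - m) - np.exp(-m))
    val = p.n0 + x - log_term
    return _maybe_scalar(val, t)


def _huang_transition(t: np.ndarray, lag: float) -> np.ndarray:
    # B(t) = t + (1/4) * ln((1 + exp(-4(t - lag))) / (1 + exp(4 lag)))
    return t + 0.25 * (
        np.logaddexp(0.0, -4.0 * (t - lag)) - np.logaddexp(0.0, 4.0 * lag)
    )


def evaluate_huang(t: ArrayLike, p: GrowthParams) -> ArrayLike:
    """Huang count at time ``t`` (days), log-domain stable.

    N(t) = N0 + Nmax - ln(exp(N0) + (exp(Nmax) - exp(N0)) * exp(-mu*B(t)))
    with the smooth lag transition function B(t).
    """
    tt = _check_time(np.atleast_1d(np.asarray(t, dtype=float)))
    c = -p.mu_max * _huang_transition(tt, p.lag)
    # ln(e^{n0} + e^{nmax+c} - e^{n0+c}), shifted by the running maximum.
    t1 = np.full_like(c, p.n0)
    t2 = p.nmax + c
    t3 = p.n0 + c
    m = np.maximum(t1, t2)
    log_term = m + np.log(np.exp(t1 - m) + np.exp(t2 - m) - np.exp(t3 - m))
    # grouping keeps N(0) = n0 exact: log_term == nmax exactly at t = 0
    val = p.n0 + (p.nmax - log_term)
    return _maybe_scalar(val, t)


_EVALUATORS = {
    "gompertz": evaluate_gompertz,
    "logistic": evaluate_logistic,
    "baranyi": evaluate_baranyi,
    "huang": evaluate_huang,
}


def evaluate_growth(kind: str, t: ArrayLike, p: GrowthParams) -> ArrayLike:
    """Evaluate the named primary model at time ``t``."""
    try:
        fn = _EVALUATORS[kind]
    except KeyError:
        raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")
    return fn(t, p)


def _invert_gompertz(p: GrowthParams, limit: float) -> float:
    span = p.nmax - p.n0
    frac = (limit - p.n0) / span
    return p.lag + span / (p.mu_max * _E) * (1.0 - math.log(-math.log(frac)))


def _invert_logistic(p: GrowthParams, limit: float) -> float:
    ratio = (p.nmax / limit - 1.0) / (p.nmax / p.n0 - 1.0)
    return p.lag - math.log(ratio) / p.mu_max


def _invert_bracketed(kind: str, p: GrowthParams, limit: float) -> float:
    fn = _EVALUATORS[kind]
    t_hi = 10.0
    while float(fn(t_hi, p)) <= limit:
        t_hi *= 2.0
        if t_hi > 1e6:
            raise LimitNeverReachedError(
                f"count limit {limit} not reached within 1e6 d"
            )
    return brentq(lambda t: float(fn(t, p)) - limit, 0.0, t_hi, xtol=1e-12)


def invert_growth(kind: str, p: GrowthParams, limit: float) -> float:
    """Time (days) at which the growth curve first reaches ``limit``.

    Closed-form for gompertz/logistic; bracketed Brent root-finding on the
    monotone curve for baranyi/huang (bracket doubled from 10 d).

    Raises
    ------
    LimitAlreadyExceededError
        If ``N(0) >= limit`` (product already out of specification at day 0).
    LimitNeverReachedError
        If ``limit >= Nmax`` (the curve saturates below the limit).
    """
    if kind not in _EVALUATORS:
        raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")
    if not math.isfinite(limit):
        raise ValueError("limit must be finite")
    if limit >= p.nmax:
        raise LimitNeverReachedError(
            f"limit {limit} >= nmax {p.nmax}: never reached"
        )
    n_start = float(evaluate_growth(kind, 0.0, p))
    if limit <= n_start:
        raise LimitAlreadyExceededError(
            f"limit {limit} already exceeded at t=0 (N(0) = {n_start:.4g})"
        )
    if kind == "gompertz":
        return _invert_gompertz(p, limit)
    if kind == "logistic":
        return _invert_logistic(p, limit)
    return _invert_bracketed(kind, p, limit)
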