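"""Zero- and first-order degradation kinetics for quality attributes.

Quality attributes of stored produce (weight loss, firmness, colour, ascorbic
acid, ...) are modelled with the two classical reaction orders:

* zero order:  ``A(t) = A0 + k * t``
* first order: ``A(t) = A0 * exp(k * t)``

The package uses a single signed-rate convention: ``k > 0`` means the
attribute increases with storage time, ``k < 0`` means it declines.  The
textbook way of writing these laws puts an explicit minus sign in front of
``k`` (``A0 - kt``, ``A0 e^{-kt}``); published rate tables frequently drop
that minus sign and print the signed slope directly (negative for declining
attributes).  :func:`k_from_literal` / :func:`k_to_literal` convert between
the signed convention used here and the literal-equation convention.

Both orders invert in closed form, which is how quality-based shelf life
(time to an acceptability cut-off) is computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np

from .errors import (
    LimitAlreadyExceededError,
    LimitNeverReachedError,
    ParameterDomainError,
)

__all__ = [
    "ORDERS",
    "QualityParams",
    "evaluate_quality",
    "invert_quality",
    "k_from_literal",
    "k_to_literal",
]

ORDERS = ("zero", "first")


@dataclass(frozen=True)
class QualityParams:
    """Parameters of a quality-degradation kinetic model.

    Attributes
    ----------
    order : str
        ``"zero"`` or ``"first"``.
    a0 : float
        Initial attribute value (attribute units).  Must be positive for
        first-order kinetics.
    k : float
        Signed rate: attribute units per day (zero order) or 1/d (first
        order).  ``k < 0`` encodes decline; ``k`` must be non-zero.
    """

    order: str
    a0: float
    k: float

    def __post_init__(self) -> None:
        if self.order not in ORDERS:
            raise ParameterDomainError(
                f"order must be one of {ORDERS}, got {self.order!r}"
            )
        if not (math.isfinite(self.a0) and math.isfinite(self.k)):
            raise ParameterDomainError("a0 and k must be finite")
        if self.k == 0:
            raise ParameterDomainError("rate k must be non-zero")
        if self.order == "first" and self.a0 <= 0:
            raise ParameterDomainError("first-order kinetics require a0 > 0")

    @property
    def direction(self) -> str:
        """``"increasing"`` if k > 0 else ``"decreasing"``."""
        return "increasing" if self.k > 0 else "decreasing"


def k_from_literal(k: float) -> float:
    """Signed rate from a literal-equation rate (``A0 - kt`` / ``A0 e^{-kt}``)."""
    return -k


def k_to_literal(k: float) -> float:
    """Literal-equation rate from the signed rate used in this package."""
    return -k


ArrayLike = Union[float, np.ndarray]


def evaluate_quality(t: ArrayLike, q: QualityParams) -> ArrayLike:
    """Attribute value at time ``t`` (days) under the kinetic model ``q``."""
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise ValueError("storage time t must be non-negative")
    if q.order == "zero":
        val = q.a0 + q.k * tt
    else:
        val = q.a0 * np.exp(q.k * tt)
    if np.isscalar(t) or (isinstance(t, np.ndarray) and t.ndim == 0):
        return float(val)
    return val


def invert_quality(q: QualityParams, limit: float) -> float:
    """Time (days) at which the attribute reaches ``limit``.

    ``t = (limit - A0) / k`` (zero order) or ``t = ln(limit / A0) / k``
    (first order).

    Raises
    ------
    LimitAlreadyExceededError
        If the limit is at or behind ``A0`` relative to the direction of
        travel (the attribute starts at or past the limit).
    LimitNeverReachedError
        If the limit lies outside the curve's range (first-order decay
        never reaches zero or below).
    """
    if not math.isfinite(limit):
        raise ValueError("limit must be finite")
    if q.k > 0:
        if limit <= q.a0:
            raise LimitAlreadyExceededError(
                f"limit {limit} already exceeded at t=0 (A0 = {q.a0})"
            )
    else:
        if limit >= q.a0:
            raise LimitAlreadyExceededError(
                f"limit {limit} already exceeded at t=0 (A0 = {q.a0})"
            )
        if q.order == "first" and limit <= 0:
            raise LimitNeverReachedError(
                "first-order decay stays positive; non-positive limit never reached"
            )
    if q.order == "zero":
        return (limit - q.a0) / q.k
    return math.log(limit / q.a0) / q.k
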