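"""Interval values and semi-trapezoidal fuzzy bounds.

Every uncertain coefficient of the planning model is either an interval
``[lower, upper]`` (solved at its two endpoints by the interactive
algorithm) or a flexible *fuzzy* bound with a piecewise-linear membership
rising from 0 at the lower support bound ``b`` to 1 at the upper support
bound ``a``.  The scalar membership level lambda in [0, 1] relaxes every
fuzzified requirement/capacity linearly between its two support bounds.

This module also fixes the reporting conventions used everywhere else:
results of the two deterministic sub-model runs are combined into a sorted
interval (:func:`paired_interval`), and interval spreads are summarised as
a relative range or as a width-reduction ratio against a reference
interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "IntervalValue",
    "FuzzyBound",
    "membership",
    "relaxed_requirement",
    "relaxed_capacity",
    "paired_interval",
    "interval_relative_range",
    "width_reduction_ratio",
]


@dataclass(frozen=True)
class IntervalValue:
    """A closed numeric interval ``[lower, upper]`` with ``lower <= upper``."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lower) and math.isfinite(self.upper)):
            raise ValueError(f"interval bounds must be finite, got {self}")
        if self.lower > self.upper:
            raise ValueError(f"interval lower bound exceeds upper bound: {self}")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    @property
    def mid(self) -> float:
        return 0.5 * (self.lower + self.upper)

    @property
    def is_crisp(self) -> bool:
        return self.lower == self.upper

    def endpoint(self, which: str) -> float:
        """Return the ``"lower"`` or ``"upper"`` endpoint by name."""
        if which == "lower":
            return self.lower
        if which == "upper":
            return self.upper
        raise ValueError(f"endpoint must be 'lower' or 'upper', got {which!r}")

    def scale(self, factor: float) -> "IntervalValue":
        if factor < 0:
            return IntervalValue(self.upper * factor, self.lower * factor)
        return IntervalValue(self.lower * factor, self.upper * factor)

    @classmethod
    def crisp(cls, value: float) -> "IntervalValue":
        return cls(value, value)


@dataclass(frozen=True)
class FuzzyBound:
    """A flexible bound with semi-trapezoidal membership.

    ``b`` is the lower support bound (membership 0) and ``a`` the upper
    support bound (membership 1); membership is linear on ``[b, a]``.  A
    degenerate bound with ``a == b`` behaves as a crisp value: membership
    is a step at ``a`` and both relaxations return ``a`` for every lambda,
    so crisp parameters flow through the fuzzy machinery unchanged.
    """

    b: float
    a: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.b) and math.isfinite(self.a)):
            raise ValueError(f"fuzzy support bounds must be finite, got {self}")
        if self.b > self.a:
            raise ValueError(f"fuzzy lower support exceeds upper support: {self}")

    @property
    def spread(self) -> float:
        return self.a - self.b

    @property
    def is_crisp(self) -> bool:
        return self.a == self.b

    @classmethod
    def crisp(cls, value: float) -> "FuzzyBound":
        return cls(value, value)


def membership(x: float, bound: FuzzyBound) -> float:
    """Semi-trapezoidal membership degree of ``x`` in ``bound``.

    0 for ``x <= b``, linear on ``[b, a]``, 1 for ``x >= a``.  For a
    degenerate bound (``a == b``) the membership is a step: 0 below ``a``
    and 1 at or above it.
    """
    if x >= bound.a:
        return 1.0
    if x <= bound.b:
        return 0.0
    return (x - bound.b) / (bound.a - bound.b)


def _check_lam(lam: float) -> None:
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"membership level must lie in [0, 1], got {lam}")


def relaxed_requirement(bound: FuzzyBound, lam: float) -> float:
    """Fuzzified lower requirement ``a - (1 - lam) * (a - b)``.

    Equals ``b`` at ``lam = 0`` (fully relaxed) and ``a`` at ``lam = 1``
    (fully enforced); nondecreasing in ``lam``.
    """
    _check_lam(lam)
    return bound.a - (1.0 - lam) * (bound.a - bound.b)


def relaxed_capacity(bound: FuzzyBound, lam: float) -> float:
    """Fuzzified upper capacity ``b + (1 - lam) * (a - b)``.

    Equals ``a`` at ``lam = 0`` (loosest) and ``b`` at ``lam = 1``
    (tightest); nonincreasing in ``lam``.
    """
    _check_lam(lam)
    return bound.b + (1.0 - lam) * (bound.a - bound.b)


def paired_interval(lower_run_value: float, upper_run_value: float) -> IntervalValue:
    """Combine the two sub-model runs' values into a sorted interval.

    The run solved at the adverse parameter endpoints does not always
    produce the smaller derived quantity (flood shares are a standing
    example: less total supply makes the flood fraction larger), so the
    pair is always sorted after pairing rather than assigned positionally.
    """
    if math.isnan(lower_run_value) or math.isnan(upper_run_value):
        raise ValueError("cannot pair NaN values into an interval")
    lo, hi = sorted((lower_run_value, upper_run_value))
    return IntervalValue(lo, hi)


def interval_relative_range(v: IntervalValue) -> float:
    """Relative range ``(upper - lower) / lower`` of a positive interval."""
    if v.lower <= 0:
        raise ValueError(f"relative range requires a positive lower bound, got {v}")
    return v.width / v.lower


def width_reduction_ratio(new: IntervalValue, ref: IntervalValue) -> float:
    """Fractional shrinkage of decision space: ``1 - new.width / ref.width``."""
    if ref.width <= 0:
        raise ValueError("reference interval must have positive width")
    return 1.0 - new.width / ref.width
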