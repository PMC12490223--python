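"""Exact and approximate binomial interval estimation.

The trial reports every rate with a two-sided exact (Clopper-Pearson)
confidence interval.  The exact interval inverts the equal-tailed binomial
test: the lower bound solves ``P(X >= x | n, p) = (1 - level)/2`` and the
upper bound solves ``P(X <= x | n, p) = (1 - level)/2``, with the closed
boundary conventions ``lower = 0`` at ``x = 0`` and ``upper = 1`` at
``x = n``.  Those tail equations are solved through the beta-quantile
identity ``P(X >= x | n, p) = I_p(x, n - x + 1)``, which is exact to
floating-point precision (well inside the 1e-10 tolerance the percent
formatting needs).

Wilson and Jeffreys intervals are provided solely for the discordance audit
of printed table cells; :func:`exact_coverage` is a deterministic
enumeration oracle (no Monte Carlo) used to certify conservatism.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable

import numpy as np
from scipy import stats

__all__ = [
    "RateCI",
    "clopper_pearson",
    "alt_interval",
    "exact_coverage",
    "round_half_up",
    "format_percent",
]


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (0.5 -> 1), not banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def format_percent(proportion: float, ndigits: int = 1) -> str:
    """Shared report formatting: x100, half-up, fixed decimals (81.25 -> '81.3')."""
    return f"{round_half_up(100.0 * proportion, ndigits):.{ndigits}f}"


@dataclass(frozen=True)
class RateCI:
    """A binomial proportion with a two-sided confidence interval."""

    x: int
    n: int
    level: float
    point: float
    lower: float
    upper: float
    method: str

    def __post_init__(self) -> None:
        if not 0 <= self.lower <= self.upper <= 1:
            raise ValueError(f"bounds ({self.lower}, {self.upper}) not ordered in [0, 1]")
        # the exact interval always contains the point estimate; score-type
        # intervals need not at the boundaries (Wilson's upper bound at
        # x = n is strictly below 1)
        if self.method == "clopper_pearson" and not (
            self.lower <= self.point + 1e-12 and self.point - 1e-12 <= self.upper
        ):
            raise ValueError(f"point {self.point} outside exact interval")

    def as_percent_string(self, ndigits: int = 1) -> str:
        """'57.1 (28.9-82.3)' under the shared rounding rule."""
        return (
            f"{format_percent(self.point, ndigits)} "
            f"({format_percent(self.lower, ndigits)}-{format_percent(self.upper, ndigits)})"
        )


def _check_inputs(x: int, n: int, level: float) -> None:
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError(f"x={x} outside [0, n={n}]")
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level {level} outside (0, 1)")


def clopper_pearson(x: int, n: int, level: float = 0.95) -> RateCI:
    """Exact equal-tailed binomial interval."""
    _check_inputs(x, n, level)
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return RateCI(x, n, level, x / n, lower, upper, "clopper_pearson")


def _wilson(x: int, n: int, level: float) -> tuple[float, float]:
    z = float(stats.norm.ppf(1 - (1 - level) / 2))
    phat = x / n
    denom = 1 + z * z / n
    centre = phat + z * z / (2 * n)
    half = z * np.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n))
    return (centre - half) / denom, (centre + half) / denom


def _jeffreys(x: int, n: int, level: float) -> tuple[float, float]:
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x + 0.5, n - x + 0.5))
    upper = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 0.5, n - x + 0.5))
    return lower, upper


def alt_interval(x: int, n: int, level: float = 0.95, method: str = "wilson") -> RateCI:
    """Wilson score or Jeffreys equal-tailed interval (audit comparators)."""
    _check_inputs(x, n, level)
    if method == "wilson":
        lower, upper = _wilson(x, n, level)
    elif method == "jeffreys":
        lower, upper = _jeffreys(x, n, level)
    else:
        raise ValueError(f"unknown interval method {method!r}")
    return RateCI(x, n, level, x / n, lower, upper, method)


_METHODS: dict[str, Callable[[int, int, float], RateCI]] = {
    "clopper_pearson": clopper_pearson,
    "wilson": lambda x, n, level: alt_interval(x, n, level, "wilson"),
    "jeffreys": lambda x, n, level: alt_interval(x, n, level, "jeffreys"),
}


def exact_coverage(method: str, n: int, p: float, level: float = 0.95) -> float:
    """Exact coverage probability of an interval method at (n, p).

    Deterministic enumeration over all n + 1 outcomes:
    ``sum_x Binom(x; n, p) * 1[lower(x) <= p <= upper(x)]``.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly inside (0, 1)")
    if method not in _METHODS:
        raise ValueError(f"unknown interval method {method!r}")
    make = _METHODS[method]
    xs = np.arange(n + 1)
    pmf = stats.binom.pmf(xs, n, p)
    covered = 0.0
    for x in xs:
        ci = make(int(x), n, level)
        if ci.lower <= p <= ci.upper:
            covered += float(pmf[x])
    return covered
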