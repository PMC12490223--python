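"""Product-limit survival estimation and follow-up summaries.

Kaplan-Meier fitting is delegated to lifelines; this module adds the pieces
the trial's tables need on top of the fitted event table: the Greenwood
variance, a linear-scale (plain Wald) confidence interval clipped to [0, 1]
-- the published survival cells have that shape; a log-log transform cannot
produce an upper bound of exactly 100% -- the reverse-KM follow-up summary
(censoring treated as the event), and Tukey-hinge quartiles for
time-to-surgery.

Tied events and censorings at the same time are handled events-first, the
standard product-limit convention.

Quantiles of a KM curve use first-crossing, refined at exact ties: the
quantile at level q is the first drop time where S <= q, except when S
lands exactly on q there, in which case the midpoint of that and the next
drop time is returned.  With zero events the reverse-KM curve is the
empirical distribution and this convention reproduces type-2 sample
quantiles (inverse ECDF with averaging), so the median of an
all-censored follow-up column is the ordinary sample median.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from lifelines import KaplanMeierFitter

__all__ = [
    "SurvivalInput",
    "KMCurve",
    "km_fit",
    "survival_at",
    "km_quantile",
    "reverse_km_median_iqr",
    "median_hinges",
]


@dataclass(frozen=True)
class SurvivalInput:
    """Right-censored durations: ``events[i]`` is True for an observed event."""

    times: Sequence[float]
    events: Sequence[bool]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.events):
            raise ValueError("times and events must have equal length")
        if any(t <= 0 for t in self.times):
            raise ValueError("all durations must be positive")

    def __len__(self) -> int:
        return len(self.times)

    def reversed(self) -> "SurvivalInput":
        """Swap event and censoring roles (reverse Kaplan-Meier input)."""
        return SurvivalInput(self.times, [not e for e in self.events])


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: step function with at-risk counts and
    cumulative Greenwood variance at each distinct event time."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    greenwood_var: np.ndarray
    n_subjects: int
    max_followup: float

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "event_times": self.event_times.tolist(),
            "survival": self.survival.tolist(),
            "at_risk": self.at_risk.tolist(),
            "n_events": self.n_events.tolist(),
            "greenwood_var": self.greenwood_var.tolist(),
        }


def km_fit(data: SurvivalInput) -> KMCurve:
    """Fit the Kaplan-Meier product-limit estimator."""
    if len(data) == 0:
        raise ValueError("empty survival input")
    fitter = KaplanMeierFitter()
    fitter.fit(np.asarray(data.times, dtype=float), np.asarray(data.events, dtype=bool))
    table = fitter.event_table
    steps = table[table["observed"] > 0]
    d = steps["observed"].to_numpy(dtype=float)
    n = steps["at_risk"].to_numpy(dtype=float)
    surv = np.cumprod(1.0 - d / n)
    # Greenwood: Var S(t) = S(t)^2 * sum_{t_i <= t} d_i / (n_i (n_i - d_i));
    # the summand is +inf where the last subjects all fail, matching S = 0.
    with np.errstate(divide="ignore", invalid="ignore"):
        increments = np.where(n > d, d / (n * (n - d)), np.inf)
        var = surv**2 * np.cumsum(increments)
    var = np.where(surv == 0.0, 0.0, var)
    return KMCurve(
        event_times=steps.index.to_numpy(dtype=float),
        survival=surv,
        at_risk=n.astype(int),
        n_events=d.astype(int),
        greenwood_var=var,
        n_subjects=len(data),
        max_followup=float(np.max(data.times)),
    )


def _step_index(curve: KMCurve, t: float) -> int:
    """Number of event times <= t (right-continuous step lookup)."""
    return int(np.searchsorted(curve.event_times, t, side="right"))


def survival_at(curve: KMCurve, t: float, level: float = 0.95) -> tuple[float, float, float]:
    """S(t) with a linear-scale Greenwood interval clipped to [0, 1]."""
    if t < 0:
        raise ValueError("time must be nonnegative")
    k = _step_index(curve, t)
    if k == 0:
        return 1.0, 1.0, 1.0
    s = float(curve.survival[k - 1])
    se = float(np.sqrt(curve.greenwood_var[k - 1]))
    from scipy.stats import norm

    z = float(norm.ppf(1 - (1 - level) / 2))
    return s, max(0.0, s - z * se), min(1.0, s + z * se)


def km_quantile(curve: KMCurve, q: float) -> float | None:
    """First-crossing quantile with exact-tie averaging (see module docstring).

    Returns None when the curve never reaches level ``q`` within follow-up.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("quantile level must lie in (0, 1)")
    below = np.nonzero(curve.survival <= q + 1e-12)[0]
    if below.size == 0:
        return None
    k = int(below[0])
    t = float(curve.event_times[k])
    if abs(float(curve.survival[k]) - q) <= 1e-12 and k + 1 < curve.event_times.size:
        return 0.5 * (t + float(curve.event_times[k + 1]))
    return t


def reverse_km_median_iqr(
    data: SurvivalInput,
) -> tuple[float | None, float | None, float | None]:
    """Median follow-up and IQR by the reverse Kaplan-Meier method.

    Censoring is treated as the event of interest (deaths are censored), and
    the median / quartiles are read off the resulting curve at S = 0.5,
    0.75, 0.25.  A quantile the curve never reaches is returned as None.
    """
    curve = km_fit(data.reversed())
    return (
        km_quantile(curve, 0.50),
        km_quantile(curve, 0.75),
        km_quantile(curve, 0.25),
    )


def median_hinges(values: Sequence[float]) -> tuple[float, float, float]:
    """Median with Tukey hinges (medians of the half-samples, middle value
    excluded from both halves when the count is odd)."""
    if len(values) == 0:
        raise ValueError("empty sample")
    srt = np.sort(np.asarray(values, dtype=float))
    n = srt.size
    half = n // 2
    lower = srt[:half] if n % 2 == 0 else srt[: half]
    upper = srt[half:] if n % 2 == 0 else srt[half + 1:]
    if n == 1:
        lower = upper = srt
    return float(np.median(srt)), float(np.median(lower)), float(np.median(upper))
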