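"""Post-surgery marker decay kinetics.

A tumor-derived circulating marker should fall exponentially once its
source is resected.  Given a per-patient series of relative levels (linear
scale, from the quantify step) over hours since surgery, this module:

* rescales to percent of the preoperative baseline (the last sample at
  time <= 0);
* fits log2(level) against time by least squares, reporting the decay rate,
  the half-life (hours), the fit R^2, and whether the raw series declines
  monotonically — fluctuating markers are unreliable for follow-up;
* reads off the descriptive time at which the series first crosses a given
  fraction of baseline by log-linear interpolation (the companion estimate
  to the fitted half-life; the two agree exactly on a pure exponential).

Non-positive post-baseline levels cannot be log-transformed; they are
censored at half the smallest positive observed level and flagged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DecaySeries",
    "DecayFit",
    "percent_of_baseline",
    "fit_decay",
    "time_to_fraction",
]


@dataclass(frozen=True)
class DecaySeries:
    """Relative marker levels of one patient over hours since surgery."""

    patient_id: str
    assay: str
    times_h: tuple[float, ...]
    levels: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times_h) != len(self.levels):
            raise ValueError("times and levels must have equal length")
        if len(self.times_h) < 1:
            raise ValueError("series is empty")
        t = np.asarray(self.times_h)
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if t[0] > 0:
            raise ValueError("baseline sample (time <= 0) required")

    @property
    def baseline(self) -> float:
        """Level of the last preoperative sample (time <= 0)."""
        idx = max(i for i, t in enumerate(self.times_h) if t <= 0)
        return self.levels[idx]


@dataclass(frozen=True)
class DecayFit:
    """Log-linear decay fit of one series."""

    decay_rate_per_h: float      # ln(2)/half-life; negative for rising series
    half_life_h: float           # inf when the series does not decay
    r_squared: float
    monotone_decline: bool
    n_censored: int = 0


def percent_of_baseline(series: DecaySeries) -> DecaySeries:
    """Rescale levels to percent of the preoperative baseline.

    Idempotent; requires a strictly positive baseline.
    """
    base = series.baseline
    if base <= 0:
        raise ValueError("baseline level must be positive")
    return replace(series, levels=tuple(100.0 * lv / base for lv in series.levels))


def fit_decay(series: DecaySeries) -> DecayFit:
    """Least-squares fit of log2(level) vs time.

    The half-life is the time per halving implied by the slope,
    ``-1/slope`` hours (infinite when the slope is non-negative);
    the decay rate is ln(2)/half-life per hour.  ``monotone_decline`` is
    evaluated on the raw levels.  Non-positive levels are censored at half
    the smallest positive level with a warning.
    """
    if len(series.levels) < 3:
        raise ValueError("need at least 3 timepoints to fit decay")
    levels = np.asarray(series.levels, dtype=float)
    times = np.asarray(series.times_h, dtype=float)
    positive = levels[levels > 0]
    if positive.size == 0:
        raise ValueError("no positive level in the series")
    n_censored = int((levels <= 0).sum())
    if n_censored:
        floor = positive.min() / 2.0
        warnings.warn(
            f"{n_censored} non-positive level(s) censored at {floor:g}",
            stacklevel=2,
        )
        levels = np.where(levels > 0, levels, floor)
    res = stats.linregress(times, np.log2(levels))
    slope = float(res.slope)
    if slope < 0:
        half_life = -1.0 / slope
        rate = math.log(2.0) / half_life
    else:
        half_life = math.inf
        rate = 0.0 if slope == 0 else -slope * math.log(2.0)
    monotone = bool(np.all(np.diff(np.asarray(series.levels)) <= 0))
    return DecayFit(
        decay_rate_per_h=rate,
        half_life_h=half_life,
        r_squared=float(res.rvalue) ** 2,
        monotone_decline=monotone,
        n_censored=n_censored,
    )


def time_to_fraction(series: DecaySeries, fraction: float) -> float | None:
    """Hours until the series first falls to ``fraction`` of baseline.

    Linear interpolation on the log2 scale between the bracketing
    timepoints; None (with a warning) when the series never crosses.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    pct = percent_of_baseline(series)
    target = 100.0 * fraction
    times = np.asarray(pct.times_h, dtype=float)
    levels = np.asarray(pct.levels, dtype=float)
    if np.any(levels <= 0):
        raise ValueError("levels must be positive to interpolate on log scale")
    for i in range(1, len(levels)):
        if levels[i] <= target:
            lo, hi = levels[i - 1], levels[i]
            if hi == lo:
                return float(times[i])
            w = (math.log2(lo) - math.log2(target)) / (math.log2(lo) - math.log2(hi))
            return float(times[i - 1] + w * (times[i] - times[i - 1]))
    warnings.warn("series never crosses the requested fraction", stacklevel=2)
    return None
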