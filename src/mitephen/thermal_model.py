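"""Linear thermal-development model for postdiapause egg development.

Under the classic linear degree-day model the developmental rate (1/days to
hatch) of postdiapause eggs held at a constant temperature ``T`` is

    rate(T) = a * T + b          (a > 0)

so development time is ``t = K / (T - T0)`` with the lower temperature
threshold ``T0 = -b / a`` (the x-axis crossing, where predicted development
stops) and the thermal constant ``K = 1 / a`` (degree-days above ``T0``
required to complete development).  The model is fitted by ordinary least
squares of per-trial rates on temperature; trials below the threshold never
hatch and contribute no rate point.
"""

from __future__ import annotations

import datetime
import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .hatch_stats import HatchSeries, ZeroHatchError, apply_censoring, t50

__all__ = [
    "RatePoint",
    "ThermalFit",
    "NonPhysicalFitError",
    "rate_points_from_trials",
    "fit_thermal_model",
    "threshold_temperature",
    "degree_day_requirement",
]

logger = logging.getLogger(__name__)


class NonPhysicalFitError(ValueError):
    """Raised when the fitted slope is not positive (rate must rise with T)."""


@dataclass(frozen=True)
class RatePoint:
    """One constant-temperature trial's developmental rate.

    ``rate`` is the reciprocal of ``development_time`` (days to 50% hatch of
    the eggs that eventually hatched).
    """

    temperature: float
    development_time: float
    year_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.development_time <= 0:
            raise ValueError(f"development_time must be > 0, got {self.development_time}")

    @property
    def rate(self) -> float:
        return 1.0 / self.development_time


@dataclass(frozen=True)
class ThermalFit:
    """OLS fit of rate vs. temperature with the derived thermal parameters.

    ``threshold_T0 = -intercept/slope`` and ``degree_days_K = 1/slope`` hold
    to machine precision by construction; ``slope`` must be positive.
    Standard errors and r² are populated when at least three points are fit.
    """

    slope: float
    intercept: float
    threshold_T0: float
    degree_days_K: float
    r_squared: Optional[float]
    n_points: int
    slope_se: Optional[float] = None
    intercept_se: Optional[float] = None

    def equation(self) -> str:
        sign = "-" if self.intercept < 0 else "+"
        return f"y = {self.slope:.4f}x {sign} {abs(self.intercept):.4f}"


def rate_points_from_trials(
    trials: Sequence[HatchSeries],
    termination_date: Optional[datetime.date] = None,
    *,
    time_summary: str = "t50",
    censor: bool = True,
    year_label: Optional[str] = None,
) -> list[RatePoint]:
    """Convert constant-temperature trials into rate points.

    Development time per trial is the time from the later of incubation start
    and ``termination_date`` to the trial's hatch-time summary:
    ``time_summary="t50"`` (default) uses the 50%-hatch time of the eggs that
    eventually hatched; ``"first"`` uses the interpolated first-hatch time
    (the day of the first observation recording any emergence).  When a trial
    was set up before the termination date, the days in between are deducted.

    Trials with no hatch (e.g. held below the threshold) yield no point; they
    are logged and a warning is emitted if every trial is hatchless.
    """
    if time_summary not in ("t50", "first"):
        raise ValueError(f"time_summary must be 't50' or 'first', got {time_summary!r}")
    points: list[RatePoint] = []
    skipped: list[str] = []
    for trial in trials:
        s = apply_censoring(trial) if censor else trial
        try:
            if time_summary == "t50":
                t_hatch = t50(s)
            else:
                t_hatch = next(d for d, c in s.observations if c > 0)
        except (ZeroHatchError, StopIteration):
            skipped.append(s.arena_id)
            continue
        offset = 0.0
        if termination_date is not None and s.collection_date is not None:
            offset = max(0.0, (termination_date - s.collection_date).days)
        dev_time = t_hatch - offset
        if dev_time <= 0:
            logger.warning(
                "%s: hatch summary %.2f d precedes termination offset %.2f d; skipped",
                s.arena_id, t_hatch, offset,
            )
            skipped.append(s.arena_id)
            continue
        points.append(
            RatePoint(
                temperature=s.treatment.incubation_temp,
                development_time=dev_time,
                year_label=year_label,
            )
        )
    if skipped:
        logger.info("excluded %d hatchless/invalid trials: %s", len(skipped), skipped)
    if not points and trials:
        warnings.warn("all trials hatchless: no rate points produced", stacklevel=2)
    return points


def fit_thermal_model(
    points: Sequence[RatePoint], *, weights: Optional[Sequence[float]] = None
) -> ThermalFit:
    """Fit rate = slope·T + intercept by (optionally weighted) least squares.

    Requires at least two distinct temperatures and a positive fitted slope.
    Unweighted OLS on per-trial rates is the default (the standard practice
    for linear degree-day fits); pass per-point ``weights`` (e.g. hatched
    counts) for a weighted fit.
    """
    if len(points) < 2:
        raise ValueError(f"need at least 2 rate points, got {len(points)}")
    temps = np.array([p.temperature for p in points], dtype=float)
    rates = np.array([p.rate for p in points], dtype=float)
    if np.unique(temps).size < 2:
        raise ValueError("need rate points at >= 2 distinct temperatures")
    if weights is None:
        res = stats.linregress(temps, rates)
        slope, intercept = res.slope, res.intercept
        slope_se = float(res.stderr) if len(points) >= 3 else None
        intercept_se = float(res.intercept_stderr) if len(points) >= 3 else None
        r2 = float(res.rvalue**2) if len(points) >= 3 else None
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != temps.shape or np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be non-negative, same length as points")
        slope, intercept = np.polyfit(temps, rates, 1, w=np.sqrt(w))
        slope_se = intercept_se = r2 = None
    if slope <= 0:
        raise NonPhysicalFitError(
            f"fitted slope {slope:.3g} <= 0: rate does not increase with temperature"
        )
    return ThermalFit(
        slope=float(slope),
        intercept=float(intercept),
        threshold_T0=-float(intercept) / float(slope),
        degree_days_K=1.0 / float(slope),
        r_squared=r2,
        n_points=len(points),
        slope_se=slope_se,
        intercept_se=intercept_se,
    )


def threshold_temperature(fit: ThermalFit) -> float:
    """Lower developmental threshold: the temperature where the fitted rate is zero."""
    if fit.slope <= 0:
        raise NonPhysicalFitError("threshold undefined for non-positive slope")
    return -fit.intercept / fit.slope


def degree_day_requirement(fit: ThermalFit) -> float:
    """Thermal constant K (ºC·days): reciprocal of the fitted slope."""
    if fit.slope <= 0:
        raise NonPhysicalFitError("degree-day requirement undefined for non-positive slope")
    return 1.0 / fit.slope
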