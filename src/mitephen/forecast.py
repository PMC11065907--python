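"""Degree-day accumulation over daily weather and hatch-date prediction.

Postdiapause development is modelled as linear in temperature above a lower
threshold ``T0``: each day contributes ``max(0, t_mean - T0)`` degree-days
(the simple daily-average method), and 50% egg hatch is predicted on the
first day the running sum reaches the thermal constant ``K`` (ºC·days).
Accumulation starts on the start date itself (inclusive); no sub-day
interpolation is applied, matching the daily resolution of station records.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "WeatherSeries",
    "ForecastResult",
    "WeatherGapError",
    "daily_degree_days",
    "predict_hatch_date",
]

DateLike = Union[datetime.date, str, pd.Timestamp]


class WeatherGapError(ValueError):
    """Raised when the accumulation window contains missing days."""


def _as_date(d: DateLike) -> datetime.date:
    if isinstance(d, pd.Timestamp):
        return d.date()
    if isinstance(d, datetime.datetime):
        return d.date()
    if isinstance(d, datetime.date):
        return d
    return pd.Timestamp(d).date()


@dataclass(frozen=True)
class WeatherSeries:
    """Daily temperature record: ``date``, ``t_mean`` and optional ``t_min``/``t_max``.

    Dates must be strictly increasing (gaps are allowed in storage; the
    forecast checks gap-freeness within its own window).  When minima and
    maxima are present they must bracket the mean.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        if "date" not in df.columns or "t_mean" not in df.columns:
            raise ValueError("weather frame needs 'date' and 't_mean' columns")
        df["date"] = pd.to_datetime(df["date"]).dt.normalize()
        df["t_mean"] = df["t_mean"].astype(float)
        if not df["date"].is_monotonic_increasing or df["date"].duplicated().any():
            raise ValueError("weather dates must be strictly increasing")
        if {"t_min", "t_max"} <= set(df.columns):
            ok = (df["t_min"] <= df["t_mean"]) & (df["t_mean"] <= df["t_max"])
            if not ok.fillna(True).all():
                raise ValueError("t_min <= t_mean <= t_max violated")
        object.__setattr__(self, "frame", df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def start(self) -> datetime.date:
        return self.frame["date"].iloc[0].date()

    @property
    def end(self) -> datetime.date:
        return self.frame["date"].iloc[-1].date()

    @classmethod
    def from_csv(cls, path) -> "WeatherSeries":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out["date"] = out["date"].dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)


@dataclass(frozen=True)
class ForecastResult:
    """Degree-day trajectory and the predicted 50%-hatch date.

    ``trajectory`` has one row per day from the start date with columns
    ``date``, ``daily_dd`` and ``cumulative_dd``; ``predicted_date`` is the
    first date whose cumulative sum reaches ``degree_days_K``, or ``None``
    when the weather coverage never accumulates that much.
    """

    start_date: datetime.date
    threshold_T0: float
    degree_days_K: float
    trajectory: pd.DataFrame
    predicted_date: Optional[datetime.date]


def daily_degree_days(t_mean, threshold_T0: float):
    """Degree-days contributed by one day: ``max(0, t_mean - threshold_T0)``.

    Accepts scalars or arrays.
    """
    return np.maximum(0.0, np.asarray(t_mean, dtype=float) - threshold_T0)[()]


def predict_hatch_date(
    weather: WeatherSeries,
    start_date: DateLike,
    threshold_T0: float,
    degree_days_K: float,
    *,
    fill_single_gaps: bool = False,
) -> ForecastResult:
    """Accumulate degree-days from ``start_date`` and predict the 50%-hatch date.

    Parameters
    ----------
    weather:
        Daily record covering the accumulation window.
    start_date:
        First day of accumulation (inclusive); typically the diapause
        termination date.  Must fall within the weather coverage.
    threshold_T0, degree_days_K:
        Fitted lower threshold (ºC) and thermal constant (ºC·days); ``K`` must
        be non-negative.
    fill_single_gaps:
        If True, isolated missing days are filled by linear interpolation of
        ``t_mean``; longer gaps always raise :class:`WeatherGapError`.

    Returns the full trajectory even when ``K`` is never reached, in which
    case ``predicted_date`` is ``None``.
    """
    if degree_days_K < 0:
        raise ValueError(f"degree_days_K must be >= 0, got {degree_days_K}")
    start = _as_date(start_date)
    if start < weather.start or start > weather.end:
        raise ValueError(
            f"start_date {start} outside weather coverage {weather.start}..{weather.end}"
        )
    df = weather.frame[weather.frame["date"] >= pd.Timestamp(start)].copy()
    full = pd.date_range(df["date"].iloc[0], df["date"].iloc[-1], freq="D")
    if len(full) != len(df):
        df = df.set_index("date").reindex(full)
        missing = df["t_mean"].isna()
        runs = missing.astype(int).groupby((~missing).cumsum()).sum()
        if not fill_single_gaps or runs.max() > 1:
            gaps = [d.date().isoformat() for d in df.index[missing][:5]]
            raise WeatherGapError(f"missing days in accumulation window: {gaps} ...")
        df["t_mean"] = df["t_mean"].interpolate(method="linear")
        df = df.rename_axis("date").reset_index()
    dd = daily_degree_days(df["t_mean"].to_numpy(), threshold_T0)
    cum = np.cumsum(dd)
    trajectory = pd.DataFrame(
        {"date": df["date"].to_numpy(), "daily_dd": dd, "cumulative_dd": cum}
    )
    hit = np.nonzero(cum >= degree_days_K)[0]
    predicted = pd.Timestamp(trajectory["date"].iloc[hit[0]]).date() if hit.size else None
    return ForecastResult(
        start_date=start,
        threshold_T0=threshold_T0,
        degree_days_K=degree_days_K,
        trajectory=trajectory,
        predicted_date=predicted,
    )
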