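"""Per-arena hatch statistics for winter-egg incubation assays.

The experimental unit is an *arena*: a batch of diapausing eggs moved to
incubation conditions and inspected on a fixed cadence, recording the
cumulative number of larvae emerged.  This module implements the evaluation
protocol applied to every arena:

* the censoring rule — an arena's evaluation ends after two consecutive
  inspections with no new emergence;
* the hatch fraction — final cumulative hatch over initial egg count;
* ``T50%`` — days of incubation until half of the eggs that eventually hatch
  have hatched, obtained by linear interpolation of the cumulative curve.

The cumulative curve is anchored at (0, 0): no egg can have hatched before
incubation starts.  Because inspections happen only every few days, the raw
counts are interval-censored; interpolating the curve (rather than returning
the first inspection day past 50%) makes ``T50%`` robust to the inspection
cadence and reduces to the raw protocol when counts are step-like.
"""

from __future__ import annotations

import dataclasses
import datetime
from collections import namedtuple
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Treatment",
    "HatchSeries",
    "HatchSummary",
    "ExperimentSummary",
    "ZeroHatchError",
    "normalize_photoperiod",
    "apply_censoring",
    "hatch_fraction",
    "t50",
    "summarize_arena",
    "summarize_experiment",
]

Photoperiod = Literal["long", "short"]

#: Hour-string aliases accepted on input (light:dark per 24 h).
_PHOTOPERIOD_ALIASES = {
    "long": "long",
    "short": "short",
    "16:8": "long",
    "8:16": "short",
}


class ZeroHatchError(ValueError):
    """Raised when a statistic is undefined because no egg hatched."""


def normalize_photoperiod(value: str) -> Photoperiod:
    """Map a photoperiod label (``long``/``short`` or ``16:8``/``8:16``) to the enum."""
    try:
        return _PHOTOPERIOD_ALIASES[str(value).strip().lower()]
    except KeyError:
        raise ValueError(
            f"photoperiod must be one of {sorted(_PHOTOPERIOD_ALIASES)}, got {value!r}"
        ) from None


@dataclass(frozen=True)
class Treatment:
    """Factorial condition applied to an arena.

    Parameters
    ----------
    chill_temp:
        Temperature (ºC) of the cold exposure preceding incubation.
    chill_days:
        Duration (days) of the cold exposure; must be non-negative.
    photoperiod:
        ``"long"`` (16:8 h L:D) or ``"short"`` (8:16 h L:D) during incubation.
    incubation_temp:
        Constant incubation temperature (ºC).
    """

    chill_temp: float
    chill_days: float
    photoperiod: Photoperiod
    incubation_temp: float = 20.0

    def __post_init__(self) -> None:
        if self.chill_days < 0:
            raise ValueError(f"chill_days must be >= 0, got {self.chill_days}")
        object.__setattr__(self, "photoperiod", normalize_photoperiod(self.photoperiod))


@dataclass(frozen=True)
class HatchSeries:
    """One arena's cumulative hatch time course plus its treatment metadata.

    ``observations`` is an ordered sequence of ``(day, cumulative_hatched)``
    pairs with ``day`` counted from the start of incubation.  Invariants
    (strictly increasing days, first day positive, non-decreasing counts
    bounded by ``n_eggs``) are enforced at construction.
    """

    arena_id: str
    treatment: Treatment
    n_eggs: int
    observations: tuple[tuple[float, int], ...]
    collection_date: Optional[datetime.date] = None
    censored_at: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_eggs < 0:
            raise ValueError(f"{self.arena_id}: n_eggs must be >= 0, got {self.n_eggs}")
        obs = tuple((float(d), int(c)) for d, c in self.observations)
        object.__setattr__(self, "observations", obs)
        days = [d for d, _ in obs]
        counts = [c for _, c in obs]
        if days and days[0] <= 0:
            raise ValueError(f"{self.arena_id}: first observation day must be > 0")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError(f"{self.arena_id}: observation days must be strictly increasing")
        if any(b < a for a, b in zip(counts, counts[1:])):
            raise ValueError(f"{self.arena_id}: cumulative counts must be non-decreasing")
        if any(c < 0 for c in counts):
            raise ValueError(f"{self.arena_id}: cumulative counts must be >= 0")
        if counts and counts[-1] > self.n_eggs:
            raise ValueError(
                f"{self.arena_id}: cumulative hatched {counts[-1]} exceeds n_eggs {self.n_eggs}"
            )

    @property
    def days(self) -> np.ndarray:
        return np.array([d for d, _ in self.observations], dtype=float)

    @property
    def counts(self) -> np.ndarray:
        return np.array([c for _, c in self.observations], dtype=float)

    @property
    def n_hatched(self) -> int:
        """Final cumulative hatched count (0 for an empty observation list)."""
        return self.observations[-1][1] if self.observations else 0


@dataclass(frozen=True)
class HatchSummary:
    arena_id: str
    n_eggs: int
    n_hatched: int
    hatch_fraction: float
    t50: Optional[float]
    censored_at: Optional[float]
    treatment: Treatment
    collection_date: Optional[datetime.date] = None


ExperimentSummary = namedtuple("ExperimentSummary", ["arenas", "treatments"])


def _increments(series: HatchSeries) -> list[int]:
    prev = 0
    out = []
    for _, c in series.observations:
        out.append(c - prev)
        prev = c
    return out


def apply_censoring(series: HatchSeries) -> HatchSeries:
    """Truncate a series at the first pair of consecutive zero-emergence checks.

    The evaluation of an arena stops once two consecutive inspections record
    no new emergence; any later observations are discarded and the day of the
    second flat inspection is stored in ``censored_at``.  The first
    observation's emergence is counted from zero, so two leading hatchless
    inspections also trigger the rule.  Series containing no such pair are
    returned unchanged.  The operation is idempotent.
    """
    inc = _increments(series)
    for i in range(len(inc) - 1):
        if inc[i] == 0 and inc[i + 1] == 0:
            truncated = series.observations[: i + 2]
            return dataclasses.replace(
                series, observations=truncated, censored_at=truncated[-1][0]
            )
    return series


def hatch_fraction(series: HatchSeries) -> float:
    """Final cumulative hatched divided by the initial egg count, in [0, 1].

    Computed on the series as given; apply :func:`apply_censoring` first to
    follow the full evaluation protocol.
    """
    if series.n_eggs == 0:
        raise ZeroHatchError(f"{series.arena_id}: hatch fraction undefined for n_eggs = 0")
    return series.n_hatched / series.n_eggs


def t50(series: HatchSeries, *, denominator: str = "hatched") -> float:
    """Days of incubation until 50% of the (eventually hatching) eggs hatched.

    The cumulative curve is linearly interpolated between consecutive
    observations and anchored at (0, 0); the earliest time at which it reaches
    half of the denominator is returned.  An observation exactly at 50%
    returns that observation's day.

    Parameters
    ----------
    denominator:
        ``"hatched"`` (default) divides by the eggs that eventually hatched,
        the convention used throughout; ``"total"`` divides by ``n_eggs`` for
        sensitivity analysis.

    Raises
    ------
    ZeroHatchError
        If no egg hatched (the statistic is undefined).
    """
    final = series.n_hatched
    if final == 0:
        raise ZeroHatchError(f"{series.arena_id}: T50 undefined, no egg hatched")
    if denominator == "hatched":
        denom = final
    elif denominator == "total":
        denom = series.n_eggs
    else:
        raise ValueError(f"denominator must be 'hatched' or 'total', got {denominator!r}")
    half = 0.5 * denom
    if final < half:
        raise ZeroHatchError(
            f"{series.arena_id}: cumulative hatch never reaches 50% of n_eggs"
        )
    d0, c0 = 0.0, 0.0
    for d1, c1 in series.observations:
        if c1 >= half:
            if c1 == c0:  # flat segment already at half
                return d0
            return d0 + (half - c0) * (d1 - d0) / (c1 - c0)
        d0, c0 = d1, float(c1)
    raise AssertionError("unreachable: final >= half guaranteed above")


def summarize_arena(
    series: HatchSeries, *, censor: bool = True, denominator: str = "hatched"
) -> HatchSummary:
    """Apply the evaluation protocol to one arena and return its summary row."""
    s = apply_censoring(series) if censor else series
    frac = hatch_fraction(s)
    try:
        t = t50(s, denominator=denominator)
    except ZeroHatchError:
        t = None
    return HatchSummary(
        arena_id=s.arena_id,
        n_eggs=s.n_eggs,
        n_hatched=s.n_hatched,
        hatch_fraction=frac,
        t50=t,
        censored_at=s.censored_at,
        treatment=s.treatment,
        collection_date=s.collection_date,
    )


_GROUP_KEYS = ["chill_temp", "chill_days", "photoperiod", "incubation_temp"]


def summarize_experiment(
    series_list: Sequence[HatchSeries],
    *,
    censor: bool = True,
    denominator: str = "hatched",
) -> ExperimentSummary:
    """Summarize a factorial experiment into tidy per-arena and per-treatment tables.

    Returns
    -------
    ExperimentSummary
        ``arenas``: one row per arena (id, treatment factors, year, n_eggs,
        n_hatched, hatch_fraction, t50, censored_at).
        ``treatments``: one row per treatment with arena count and mean ±
        standard error of the hatch percentage and of T50 (SE is NaN for a
        single arena; T50 means ignore arenas where it is undefined).
    """
    rows = []
    for s in series_list:
        summ = summarize_arena(s, censor=censor, denominator=denominator)
        rows.append(
            {
                "arena_id": summ.arena_id,
                "year": summ.collection_date.year if summ.collection_date else pd.NA,
                "chill_temp": summ.treatment.chill_temp,
                "chill_days": summ.treatment.chill_days,
                "photoperiod": summ.treatment.photoperiod,
                "incubation_temp": summ.treatment.incubation_temp,
                "n_eggs": summ.n_eggs,
                "n_hatched": summ.n_hatched,
                "hatch_fraction": summ.hatch_fraction,
                "t50": summ.t50 if summ.t50 is not None else np.nan,
                "censored_at": summ.censored_at if summ.censored_at is not None else np.nan,
            }
        )
    arenas = pd.DataFrame(
        rows,
        columns=[
            "arena_id",
            "year",
            "chill_temp",
            "chill_days",
            "photoperiod",
            "incubation_temp",
            "n_eggs",
            "n_hatched",
            "hatch_fraction",
            "t50",
            "censored_at",
        ],
    )
    if arenas.empty:
        treatments = pd.DataFrame(
            columns=["year"] + _GROUP_KEYS
            + ["n_arenas", "mean_hatch_pct", "se_hatch_pct", "mean_t50", "se_t50"]
        )
        return ExperimentSummary(arenas, treatments)

    def _agg(g: pd.DataFrame) -> pd.Series:
        pct = 100.0 * g["hatch_fraction"]
        t = g["t50"].dropna()
        return pd.Series(
            {
                "n_arenas": len(g),
                "mean_hatch_pct": pct.mean(),
                "se_hatch_pct": pct.sem(ddof=1) if len(g) > 1 else np.nan,
                "mean_t50": t.mean() if len(t) else np.nan,
                "se_t50": t.sem(ddof=1) if len(t) > 1 else np.nan,
            }
        )

    keys = ["year"] + _GROUP_KEYS
    treatments = (
        arenas.groupby(keys, dropna=False, sort=True)
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    return ExperimentSummary(arenas, treatments)
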