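"""Diapause-termination date from sequential field-collection batches.

Winter eggs are brought in from the field every few days and incubated under
standard conditions (20 ºC, long photoperiod).  Diapause is considered
terminated on the earliest collection date whose eggs reach at least 50%
hatch within 20 days of incubation — early-winter batches hatch slowly and
sparsely, while batches collected after sufficient chilling hatch promptly.

Fractions are pooled over a batch's replicate arenas (total hatched over
total eggs), matching a population-level reading of "50% of the eggs"; the
hatch count at exactly the cutoff day is linearly interpolated between the
bracketing inspections when none falls on it.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .hatch_stats import HatchSeries

__all__ = ["CollectionBatch", "TerminationResult", "fraction_within", "termination_date"]


@dataclass(frozen=True)
class CollectionBatch:
    """Arenas set up from eggs collected on one field date."""

    collection_date: datetime.date
    series: tuple[HatchSeries, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "series", tuple(self.series))
        if not self.series:
            raise ValueError(f"batch {self.collection_date}: series must be non-empty")
        for s in self.series:
            if s.collection_date is not None and s.collection_date != self.collection_date:
                raise ValueError(
                    f"batch {self.collection_date}: series {s.arena_id} has "
                    f"collection_date {s.collection_date}"
                )

    @property
    def total_eggs(self) -> int:
        return sum(s.n_eggs for s in self.series)


@dataclass(frozen=True)
class TerminationResult:
    """Termination date (None if no batch qualifies) plus the per-batch
    fraction-within-cutoff table used to decide it."""

    termination_date: Optional[datetime.date]
    per_batch_fraction_at_cutoff: pd.DataFrame
    threshold: float
    cutoff: float


def _hatched_at(series: HatchSeries, day: float) -> float:
    """Cumulative hatched at ``day``: 0 before the first inspection, linear
    between inspections, last count beyond the final one."""
    prev_d, prev_c = None, 0.0
    for d, c in series.observations:
        if d == day:
            return float(c)
        if d > day:
            if prev_d is None:
                return 0.0
            return prev_c + (c - prev_c) * (day - prev_d) / (d - prev_d)
        prev_d, prev_c = d, float(c)
    return prev_c


def fraction_within(batch: CollectionBatch, cutoff: float) -> float:
    """Pooled fraction of the batch's eggs hatched within ``cutoff`` days."""
    if cutoff <= 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff}")
    total = batch.total_eggs
    if total == 0:
        raise ValueError(f"batch {batch.collection_date}: zero total eggs")
    hatched = sum(_hatched_at(s, cutoff) for s in batch.series)
    return hatched / total


def termination_date(
    batches: Sequence[CollectionBatch],
    threshold: float = 0.5,
    cutoff: float = 20.0,
) -> TerminationResult:
    """Earliest collection date whose batch reaches ``threshold`` hatch within
    ``cutoff`` days of incubation.

    Batches are sorted by collection date, so input order does not matter.
    When no batch qualifies, ``termination_date`` is ``None`` and the full
    per-batch table is still returned.
    """
    if not batches:
        raise ValueError("batches must be non-empty")
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    ordered = sorted(batches, key=lambda b: b.collection_date)
    rows = [
        {
            "collection_date": b.collection_date,
            "n_eggs": b.total_eggs,
            "fraction_within_cutoff": fraction_within(b, cutoff),
        }
        for b in ordered
    ]
    table = pd.DataFrame(rows, columns=["collection_date", "n_eggs", "fraction_within_cutoff"])
    qualifying = table.loc[table["fraction_within_cutoff"] >= threshold, "collection_date"]
    date = qualifying.iloc[0] if not qualifying.empty else None
    return TerminationResult(
        termination_date=date,
        per_batch_fraction_at_cutoff=table,
        threshold=threshold,
        cutoff=cutoff,
    )
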