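"""Synthetic hatch, postdiapause-trial and weather generators.

Real inputs to this pipeline are field-collected winter eggs scored under
controlled incubation, and a nearby agroclimatic station's daily record.
Neither is distributable, so this module generates data with the statistical
structure the analysis assumes:

* **Chill-factorial experiment** — each egg hatches with a probability that
  is logistic in chill duration (saturating at a cap), higher under long
  photoperiod, and peaks near a chill-temperature optimum of a few ºC;
  hatch times are lognormal with a median that declines linearly with chill
  duration down to a floor.  Counts are recorded on a fixed inspection
  cadence and the two-flat-inspections censoring rule is applied at
  generation time: eggs that would hatch after it triggers go unrecorded.
* **Constant-temperature postdiapause trials** — hatch time centred on
  ``K/(T - T0)`` with multiplicative rate noise; at or below the threshold
  no egg hatches.
* **Daily weather** — a sinusoidal annual cycle plus Gaussian noise, on a
  365-day year (a leap day receives the day-365 value).

The default parameter values are a calibration chosen to reproduce the
qualitative patterns of real chill experiments (hatch success rising from
under ~10% at 10 chill days to ~50–70% at 100 days, long-photoperiod
advantage, T50 falling from ~45–70 to ~11–18 days); they are not measured
quantities.  All generators are deterministic given their seed.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .forecast import WeatherSeries
from .hatch_stats import HatchSeries, Treatment

__all__ = [
    "SimParams",
    "PostdiapauseParams",
    "WeatherParams",
    "simulate_chill_experiment",
    "simulate_postdiapause_trials",
    "simulate_weather",
]

_PROB_CLAMP = 1e-9  # keep logits finite before Bernoulli sampling


@dataclass(frozen=True)
class SimParams:
    """Calibration of the chill-factorial generator.

    hatch_logit_intercept / chill_day_coef / chill_day_cap:
        Logit of per-egg hatch probability rises by ``chill_day_coef`` per
        chill day up to ``chill_day_cap`` days, from the intercept.
    photoperiod_long_bonus:
        Logit bonus under long (16:8) photoperiod.
    chill_temp_optimum / chill_temp_curvature:
        Quadratic logit penalty ``curvature * (chill_temp - optimum)²``
        centred on the most effective chilling temperature.
    t50_base / t50_decay / t50_floor:
        Median hatch day is ``max(floor, base - decay * chill_days)``.
    hatch_time_cv:
        Coefficient of variation of the lognormal egg-level hatch times.
    observation_interval:
        Days between inspections.
    """

    hatch_logit_intercept: float = -3.3
    chill_day_coef: float = 0.035
    chill_day_cap: float = 100.0
    photoperiod_long_bonus: float = 0.8
    chill_temp_optimum: float = 4.0
    chill_temp_curvature: float = 0.02
    t50_base: float = 55.0
    t50_decay: float = 0.45
    t50_floor: float = 12.0
    hatch_time_cv: float = 0.35
    observation_interval: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.observation_interval <= 0:
            raise ValueError("observation_interval must be > 0")
        if self.t50_floor <= 0:
            raise ValueError("t50_floor must be > 0")
        if self.hatch_time_cv < 0:
            raise ValueError("hatch_time_cv must be >= 0")
        if self.chill_day_cap <= 0:
            raise ValueError("chill_day_cap must be > 0")

    def hatch_probability(self, treatment: Treatment) -> float:
        """Per-egg hatch probability for a treatment (clamped logistic)."""
        logit = (
            self.hatch_logit_intercept
            + self.chill_day_coef * min(treatment.chill_days, self.chill_day_cap)
            + (self.photoperiod_long_bonus if treatment.photoperiod == "long" else 0.0)
            - self.chill_temp_curvature
            * (treatment.chill_temp - self.chill_temp_optimum) ** 2
        )
        p = 1.0 / (1.0 + math.exp(-logit))
        return min(max(p, _PROB_CLAMP), 1.0 - _PROB_CLAMP)

    def median_hatch_day(self, treatment: Treatment) -> float:
        return max(self.t50_floor, self.t50_base - self.t50_decay * treatment.chill_days)


@dataclass(frozen=True)
class PostdiapauseParams:
    """Ground truth for constant-temperature trials: threshold T0 (ºC),
    thermal constant K (ºC·days), multiplicative rate noise and arena size."""

    true_threshold: float = 5.47
    true_degree_days: float = 263.2
    rate_noise_sd: float = 0.05
    n_eggs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_degree_days <= 0:
            raise ValueError("true_degree_days must be > 0")
        if self.n_eggs < 0:
            raise ValueError("n_eggs must be >= 0")
        if self.rate_noise_sd < 0:
            raise ValueError("rate_noise_sd must be >= 0")


@dataclass(frozen=True)
class WeatherParams:
    """Sinusoidal annual temperature cycle: mean, half-amplitude, day-of-year
    of the coldest day, and daily Gaussian noise."""

    annual_mean: float = 13.0
    annual_amplitude: float = 8.5
    coldest_day_of_year: int = 15
    daily_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.annual_amplitude < 0:
            raise ValueError("annual_amplitude must be >= 0")
        if self.daily_noise_sd < 0:
            raise ValueError("daily_noise_sd must be >= 0")


def simulate_chill_experiment(
    treatments: Sequence[Treatment],
    replicates: int,
    eggs_per_arena: int,
    params: SimParams,
) -> list[HatchSeries]:
    """Simulate a chill-duration × chill-temperature × photoperiod experiment.

    Returns ``replicates × len(treatments)`` arenas.  Per arena, the number
    of hatching eggs is binomial in the treatment's hatch probability; their
    hatch days are lognormal around the treatment median.  Inspections run
    every ``observation_interval`` days and stop after two consecutive
    inspections without new emergence, so late hatchers can be censored away
    exactly as in the laboratory protocol.
    """
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")
    if eggs_per_arena < 0:
        raise ValueError(f"eggs_per_arena must be >= 0, got {eggs_per_arena}")
    rng = np.random.default_rng(params.seed)
    sigma = math.sqrt(math.log1p(params.hatch_time_cv**2))
    out: list[HatchSeries] = []
    for rep in range(replicates):
        for k, tr in enumerate(treatments):
            p = params.hatch_probability(tr)
            n_hatch = int(rng.binomial(eggs_per_arena, p)) if eggs_per_arena else 0
            median = params.median_hatch_day(tr)
            if sigma > 0:
                times = rng.lognormal(mean=math.log(median), sigma=sigma, size=n_hatch)
            else:
                times = np.full(n_hatch, median)
            obs: list[tuple[float, int]] = []
            day = params.observation_interval
            prev = 0
            flat = 0
            while True:
                c = int(np.count_nonzero(times <= day))
                obs.append((day, c))
                flat = flat + 1 if c == prev else 0
                prev = c
                if flat >= 2:
                    break
                day += params.observation_interval
            out.append(
                HatchSeries(
                    arena_id=f"sim-r{rep}-t{k}",
                    treatment=tr,
                    n_eggs=eggs_per_arena,
                    observations=tuple(obs),
                )
            )
    return out


def simulate_postdiapause_trials(
    temperatures: Sequence[float],
    params: PostdiapauseParams,
    *,
    bracket_halfwidth: float = 1.25,
) -> list[HatchSeries]:
    """Simulate constant-temperature postdiapause trials.

    For ``T > true_threshold`` the arena's developmental rate is
    ``(T - T0)/K`` perturbed by a multiplicative lognormal factor with log-sd
    ``rate_noise_sd``; all eggs of the arena emerge between the two
    inspections that bracket the arena hatch time symmetrically (half-width
    ``bracket_halfwidth`` days, half the 2.5-day field cadence), so the
    interpolated 50%-hatch time equals the arena hatch time exactly.  At or
    below the threshold no egg hatches and the series ends after two empty
    inspections.  Repeat a temperature in ``temperatures`` to get replicate
    arenas.
    """
    if len(temperatures) == 0:
        raise ValueError("temperatures must be non-empty")
    rng = np.random.default_rng(params.seed)
    t0, kdd = params.true_threshold, params.true_degree_days
    out: list[HatchSeries] = []
    for i, temp in enumerate(temperatures):
        arena_id = f"pd-{i}-{temp:g}C"
        tr = Treatment(chill_temp=np.nan, chill_days=0.0, photoperiod="long",
                       incubation_temp=float(temp))
        if temp <= t0:
            obs = ((2.5, 0), (5.0, 0))
        else:
            rate = (temp - t0) / kdd * math.exp(rng.normal(0.0, params.rate_noise_sd))
            t_hatch = 1.0 / rate
            delta = min(bracket_halfwidth, t_hatch / 2.0)
            obs = (
                (t_hatch - delta, 0),
                (t_hatch + delta, params.n_eggs),
                (t_hatch + delta + 2.5, params.n_eggs),
                (t_hatch + delta + 5.0, params.n_eggs),
            )
        out.append(
            HatchSeries(arena_id=arena_id, treatment=tr, n_eggs=params.n_eggs,
                        observations=obs)
        )
    return out


def simulate_weather(
    start_date: datetime.date,
    end_date: datetime.date,
    params: WeatherParams,
) -> WeatherSeries:
    """Generate one record per calendar day between two dates (inclusive).

    Mean temperature follows ``annual_mean - annual_amplitude ·
    cos(2π (doy - coldest_day_of_year)/365)`` plus Gaussian noise, on a
    365-day year (day 366 reuses day 365).
    """
    start = pd.Timestamp(start_date)
    end = pd.Timestamp(end_date)
    if start > end:
        raise ValueError(f"start_date {start.date()} after end_date {end.date()}")
    rng = np.random.default_rng(params.seed)
    dates = pd.date_range(start, end, freq="D")
    doy = np.minimum(dates.dayofyear.to_numpy(), 365)
    t_mean = (
        params.annual_mean
        - params.annual_amplitude
        * np.cos(2.0 * np.pi * (doy - params.coldest_day_of_year) / 365.0)
        + rng.normal(0.0, params.daily_noise_sd, size=len(dates))
    )
    return WeatherSeries(pd.DataFrame({"date": dates, "t_mean": t_mean}))
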