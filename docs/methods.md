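# Methods

`mitephen` analyses the winter-egg phenology of spider mites (built around
the European red mite, *Panonychus ulmi*, a major pest of apple and other
fruit crops). Overwintering eggs enter diapause and need a period of
chilling before they can resume development; once diapause is terminated,
development to hatching is driven by temperature. The package covers the
four stages of that analysis and a synthetic-data generator that emulates
the laboratory assays and the weather record it consumes.

## Hatch statistics

The experimental unit is an *arena*: a batch of eggs moved to incubation and
inspected on a fixed cadence (10 days in the factorial assays, 2–4 days in
the field-collection and constant-temperature assays), recording cumulative
larvae emerged. Three operations define the evaluation protocol:

**Censoring.** An arena's evaluation ends after two consecutive inspections
with no new emergence; later records are discarded. The first inspection's
emergence is counted from zero, so two hatchless leading checks also stop an
arena. This is the stricter of the two possible readings of the stopping
rule ("stop any flat arena" vs. "stop only after hatching has begun"); it is
applied consistently in the statistics and in the generator, and its main
consequence for synthetic data is discussed under *Limitations*.

**Hatch fraction.** Final cumulative hatched over initial egg count, in
[0, 1]; reports render it as a percentage.

**T50%.** Days of incubation until 50% of the eggs *that eventually hatch*
have hatched. Because counts are interval-censored by the inspection
cadence, the cumulative curve is linearly interpolated between consecutive
inspections, anchored at (0, 0) (no egg hatches before incubation starts),
and the earliest time the curve reaches half the final hatched count is
returned; an inspection exactly at 50% returns its own day. Interpolation
makes the statistic cadence-robust and explains fractional day values that a
10-day cadence could not otherwise produce; with step-like counts it reduces
to the raw protocol. The denominator can optionally be switched to all eggs
(`denominator="total"`) for sensitivity analysis; the eventually-hatched
denominator is the standard one.

## Diapause-termination rule

Field-collected batches (every 2–3 days from January, two replicate arenas
per date, incubated at 20 ºC under long photoperiod) are screened for the
earliest collection date whose eggs reach at least 50% hatch within 20 days
of incubation. Fractions are pooled over a batch's arenas (total hatched /
total eggs) — a population-level reading — rather than averaged per arena.
The hatched count at exactly the cutoff day is linearly interpolated between
the bracketing inspections; before the first inspection the count is taken
as zero (nothing has been observed yet), a deliberate difference from the
(0, 0)-anchored T50 curve so that a batch first inspected after the cutoff
cannot qualify on extrapolation alone. Both threshold (default 0.5) and
cutoff (default 20 d) are parameters; the returned table of per-batch
fractions supports auditing and the monotonicity property (raising the
threshold or shrinking the cutoff never yields an earlier date).

## Linear thermal-development model

Constant-temperature trials give a development time `t(T)` per arena: the
time from the later of incubation start and the termination date to 50%
hatch of the eggs that eventually hatched (re-using T50; a
`time_summary="first"` flag offers time-to-first-hatch instead, since a
hatch-time summary must be chosen and 50%-hatch is the one used everywhere
else in the pipeline). The developmental rate `1/t` is regressed on
temperature by unweighted ordinary least squares over per-trial points (the
standard Campbell-style approach; weighting by hatched count is available as
an option):

    rate(T) = a·T + b,    T0 = −b/a,    K = 1/a

`T0` (ºC) is the lower developmental threshold — the x-axis crossing where
predicted development stops — and `K` (ºC·days) the thermal constant.
Trials that never hatch (e.g. held at 4 ºC, below the threshold) contribute
no rate point and are never imputed; a fit requires at least two distinct
temperatures and a positive slope (a non-positive slope raises
`NonPhysicalFitError` rather than returning a negative thermal constant).
Derived identities `K·a = 1` and `a·T0 + b = 0` hold to machine precision by
construction. Standard errors and r² are reported from three points up.
Thresholds and K are rounded to 2 and 1 decimals only at presentation.

## Degree-day forecast

Daily weather drives accumulation of `max(0, t_mean − T0)` degree-days (the
simple daily-average method; single-sine and min/max variants are
deliberately out of scope but the per-day operation is isolated so they
could be added). Accumulation starts on the termination date itself
(inclusive) and the predicted 50%-hatch date is the first day the running
sum reaches `K`, with no sub-day interpolation — matching the daily
resolution of station data. Gaps inside the accumulation window abort with
`WeatherGapError`; isolated single missing days may optionally be filled by
linear interpolation (off by default).

## Synthetic-data generator

No raw hatch counts or station records are distributable, so generators
provide inputs with the structure the analysis assumes.

**Chill factorial.** Each egg hatches with probability
`logistic(b0 + b_d·min(days, cap) + b_L·[long photoperiod] −
c·(T_chill − T_opt)²)`, and hatch days are lognormal with median
`max(floor, base − decay·days)` and fixed coefficient of variation.
Inspections run on the configured cadence and the censoring rule is applied
at generation time, so late hatchers can be lost exactly as in the
protocol. Defaults (`b0 = −3.3`, `b_d = 0.035`/day capped at 100 d,
`b_L = 0.8`, `T_opt = 4 ºC`, `c = 0.02`/ºC², median 55 − 0.45·days floored
at 12 d, CV 0.35, 10-day cadence) are a calibration chosen once to
reproduce the qualitative magnitudes of real assays — hatch success rising
from under ~10% at 10 chill days to ~50–75% at 100 days, a long-photoperiod
advantage, an optimum chilling temperature of a few ºC, and T50 falling
from ~45–70 d to ~11–18 d. They are not measured quantities, and the real
assays fit no such generative model. The probability is clamped to
[1e−9, 1 − 1e−9] so extreme logits stay sampleable.

**Postdiapause trials.** For `T > T0` an arena's rate is `(T − T0)/K` times
a lognormal factor with log-sd `rate_noise_sd` (noise acts multiplicatively
on the rate scale, where the linear model lives); at or below `T0` no egg
hatches. All of an arena's eggs emerge between the two inspections that
bracket the arena hatch time symmetrically (±1.25 d, half the 2.5-day field
cadence). The symmetric bracket makes the interpolated T50 equal the arena
hatch time exactly, so the noise-free generator → rate-points → fit round
trip recovers (T0, K) to machine precision — a designed property used to
separate model error from pipeline error.

**Weather.** One record per day:
`annual_mean − annual_amplitude·cos(2π(doy − coldest_doy)/365)` plus
Gaussian noise, on a 365-day year (a leap day reuses the day-365 value —
forecast accuracy at the day scale is unaffected). Defaults (mean 13 ºC,
half-amplitude 8.5 ºC, coldest day 15, noise sd 2 ºC) describe a temperate
upland Mediterranean site.

All generators are bit-reproducible given their seed; the CLI's `pipeline`
command rebases every generator seed on one master seed.

## Numerical choices and degenerate inputs

* T50 earliest-crossing tie-break: a flat segment already at half returns
  the segment's start.
* Zero hatch makes hatch fraction 0 but T50 undefined (`ZeroHatchError`,
  flagged, not a crash); a zero-egg arena rejects the fraction outright.
* Group standard errors use ddof = 1 and are NaN for a single arena.
* OLS is delegated to `scipy.stats.linregress`; weighted fits to a
  √weight-scaled `numpy.polyfit`, which coincides with replicating points
  for integer weights.
* The forecast trajectory uses a plain prefix sum; `K = 0` predicts the
  start date itself.

## What passing tests do and do not show

The generators encode the very monotonicities and the rate law the pipeline
estimates, so recovery tests demonstrate correctness of the estimation
machinery — censoring, interpolation, pooling, regression, accumulation —
not the truth of the biological model for any real population. Real data
depart from the generator in known ways: egg hatch times within an arena
need not be lognormal (no distributional information exists to calibrate
this); oviposition-date heterogeneity among field eggs is not modelled;
real station weather has autocorrelated, non-sinusoidal anomalies; and
mortality, handling losses and miscounts are absent.

## Limitations

* Under the strict censoring reading, a synthetic 50-egg arena whose median
  hatch day is far beyond the second inspection is usually stopped before
  any hatch and records 0%, which real short-chill assays did not show;
  property checks on hatch-fraction monotonicity therefore use large egg
  numbers (10⁴), where early hatchers keep arenas alive. Analyses of real
  tables are unaffected (censoring only truncates recorded series).
* The linear rate model is used throughout; nonlinear developmental-rate
  models (Brière, Lactin, Sharpe–Schoolfield) and upper thresholds are out
  of scope.
* The termination rule assumes batches are comparable across collection
  dates; it does not model within-season oviposition spread.
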