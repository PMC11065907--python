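"""Censoring, hatch fraction and the interpolated T50 statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitephen.hatch_stats import (
    HatchSeries,
    Treatment,
    ZeroHatchError,
    apply_censoring,
    hatch_fraction,
    summarize_experiment,
    t50,
)

from conftest import make_series


def grid_scan_t50(series, resolution=0.001):
    """Independent oracle: scan the interpolated cumulative curve on a fine
    grid and return the first time it reaches half the final hatched count."""
    days = np.concatenate([[0.0], series.days])
    counts = np.concatenate([[0.0], series.counts])
    half = 0.5 * counts[-1]
    grid = np.arange(0.0, days[-1] + resolution, resolution)
    curve = np.interp(grid, days, counts)
    return grid[np.argmax(curve >= half)]


class TestCensoring:
    @pytest.mark.parametrize(
        "days, counts, expect_days, censored_at",
        [
            # two flat checks at days 30/40 end the arena; the day-50 count is lost
            ([10, 20, 30, 40, 50], [10, 30, 30, 30, 45], [10, 20, 30, 40], 40),
            # strictly increasing counts: nothing to censor
            ([10, 20, 30], [5, 10, 15], [10, 20, 30], None),
            # two hatchless leading checks also stop the arena
            ([10, 20, 30], [0, 0, 5], [10, 20], 20),
        ],
    )
    def test_truncation_rule(self, days, counts, expect_days, censored_at):
        s = make_series(days, counts)
        c = apply_censoring(s)
        assert list(c.days) == expect_days
        assert c.censored_at == censored_at

    def test_leading_zero_pair_matches_bruteforce_scan(self):
        # brute-force scan for the first zero-increment pair over random series
        rng = np.random.default_rng(42)
        for _ in range(200):
            inc = rng.integers(0, 3, size=rng.integers(2, 10))
            counts = np.cumsum(inc)
            days = 10.0 * np.arange(1, len(counts) + 1)
            s = make_series(days, counts, n_eggs=int(counts[-1]) + 5)
            c = apply_censoring(s)
            full = np.concatenate([[0], counts])
            pairs = [
                i for i in range(len(inc) - 1)
                if full[i + 1] == full[i] and full[i + 2] == full[i + 1]
            ]
            if pairs:
                assert len(c.observations) == pairs[0] + 2
            else:
                assert c == s

    def test_idempotent(self):
        s = make_series([10, 20, 30, 40, 50], [10, 30, 30, 30, 45])
        once = apply_censoring(s)
        assert apply_censoring(once) == once

    def test_censoring_never_raises_hatch_fraction(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            counts = np.cumsum(rng.integers(0, 3, size=8))
            s = make_series(10.0 * np.arange(1, 9), counts, n_eggs=int(counts[-1]) + 1)
            assert hatch_fraction(apply_censoring(s)) <= hatch_fraction(s)


class TestHatchFraction:
    def test_basic_and_zero(self):
        assert hatch_fraction(make_series([10, 20], [10, 30])) == 0.30
        assert hatch_fraction(make_series([10, 20], [0, 0])) == 0.0

    def test_no_eggs_rejected(self):
        s = make_series([10], [0], n_eggs=0)
        with pytest.raises(ZeroHatchError):
            hatch_fraction(s)


class TestT50:
    def test_interpolates_between_observations(self):
        # half of 40 hatched is crossed midway between days 10 and 20
        assert t50(make_series([10, 20], [0, 40])) == pytest.approx(15.0)

    def test_observation_exactly_at_half(self):
        assert t50(make_series([10, 20], [20, 40])) == pytest.approx(10.0)

    def test_zero_hatched_flagged(self):
        with pytest.raises(ZeroHatchError):
            t50(make_series([10, 20], [0, 0]))

    def test_total_denominator_option(self):
        # 40 of 100 eggs hatched: 50% of n_eggs is never reached
        s = make_series([10, 20], [0, 40], n_eggs=100)
        with pytest.raises(ZeroHatchError):
            t50(s, denominator="total")
        # a larger denominator crosses 50% later
        s2 = make_series([10, 20], [0, 80], n_eggs=100)
        assert t50(s2, denominator="total") >= t50(s2, denominator="hatched")
        assert t50(s2, denominator="total") == pytest.approx(10 + 50 / 80 * 10)

    def test_matches_grid_scan_oracle_on_random_step_curves(self):
        rng = np.random.default_rng(123)
        for _ in range(300):
            n_obs = rng.integers(1, 8)
            counts = np.cumsum(rng.integers(0, 10, size=n_obs))
            if counts[-1] == 0:
                continue
            days = np.cumsum(rng.integers(1, 15, size=n_obs)).astype(float)
            s = make_series(days, counts, n_eggs=int(counts[-1]))
            assert t50(s) == pytest.approx(grid_scan_t50(s), abs=0.002)

    @given(
        scale=st.floats(min_value=0.1, max_value=50.0,
                        allow_nan=False, allow_infinity=False),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_invariant_under_count_rescaling(self, scale, seed):
        rng = np.random.default_rng(seed)
        counts = np.cumsum(rng.integers(0, 5, size=6))
        if counts[-1] == 0:
            return
        days = 10.0 * np.arange(1, 7)
        base = make_series(days, counts, n_eggs=int(counts[-1]))
        # rescaling needs integer counts: use an integer multiplier
        c = max(1, int(scale))
        scaled = make_series(days, counts * c, n_eggs=int(counts[-1]) * c)
        assert t50(scaled) == pytest.approx(t50(base))

    def test_single_burst_lies_within_preceding_interval(self):
        # all hatch recorded at day d: T50 in (d - interval, d]
        s = make_series([10, 20, 30], [0, 35, 35])
        assert 10 < t50(s) <= 20


class TestSeriesValidation:
    @pytest.mark.parametrize(
        "days, counts, n_eggs",
        [
            ([10, 10], [1, 2], 10),   # duplicate day
            ([20, 10], [1, 2], 10),   # decreasing day
            ([10, 20], [5, 3], 10),   # decreasing count
            ([10], [11], 10),         # exceeds n_eggs
            ([0, 10], [0, 1], 10),    # first day not positive
        ],
    )
    def test_invalid_series_rejected(self, days, counts, n_eggs):
        with pytest.raises(ValueError):
            make_series(days, counts, n_eggs=n_eggs)


class TestSummaries:
    def test_single_arena_group_stats(self):
        s = make_series([10, 20], [0, 40])
        summary = summarize_experiment([s])
        row = summary.treatments.iloc[0]
        assert row["n_arenas"] == 1
        assert row["mean_hatch_pct"] == pytest.approx(40.0)
        assert np.isnan(row["se_hatch_pct"])
        assert row["mean_t50"] == pytest.approx(15.0)

    def test_identical_arenas_have_zero_se(self):
        ss = [make_series([10, 20], [0, 40], arena_id=f"a{i}") for i in range(4)]
        row = summarize_experiment(ss).treatments.iloc[0]
        assert row["n_arenas"] == 4
        assert row["se_hatch_pct"] == pytest.approx(0.0)
        assert row["se_t50"] == pytest.approx(0.0)

    def test_grouped_table_has_one_row_per_treatment(self):
        treatments = [
            Treatment(chill_temp=ct, chill_days=cd, photoperiod=pp)
            for ct in (0.0, 4.0) for cd in (10.0, 100.0) for pp in ("long", "short")
        ]
        ss = [
            make_series([10, 20], [0, 10], arena_id=f"a{i}-{r}", treatment=tr)
            for i, tr in enumerate(treatments) for r in range(3)
        ]
        summary = summarize_experiment(ss)
        assert len(summary.treatments) == len(treatments)
        assert len(summary.arenas) == 3 * len(treatments)
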