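import datetime

import pytest

from mitephen.hatch_stats import HatchSeries, Treatment


@pytest.fixture
def treatment():
    return Treatment(chill_temp=4.0, chill_days=60.0, photoperiod="long")


def make_series(days, counts, *, n_eggs=100, arena_id="a1", treatment=None,
                collection_date=None):
    """Build a HatchSeries from parallel day/count lists."""
    tr = treatment or Treatment(chill_temp=4.0, chill_days=60.0, photoperiod="long")
    return HatchSeries(
        arena_id=arena_id,
        treatment=tr,
        n_eggs=n_eggs,
        observations=tuple(zip(days, counts)),
        collection_date=collection_date,
    )


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture
def a_date():
    return datetime.date(2005, 2, 1)
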