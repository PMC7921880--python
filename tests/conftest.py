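import datetime as dt

import numpy as np
import pytest

import pollenprofiles as pp


@pytest.fixture(scope="session")
def pollen_2015():
    """Default synthetic Poaceae year (noise-free curve)."""
    return pp.gen_pollen_year(pp.DEFAULT_TAXA, 2015)


@pytest.fixture(scope="session")
def season_2015(pollen_2015):
    return pp.define_season(pollen_2015, 2015)


@pytest.fixture(scope="session")
def apin_part(pollen_2015, season_2015):
    return pp.apin_tertile_partition(pollen_2015, season_2015)


@pytest.fixture(scope="session")
def phen_part(season_2015):
    return pp.phenology_partition(pp.default_phenology(2015), season_2015)


def uniform_series(year, start_doy, n_days, value=1.0):
    """Constant-concentration series: `value` on n_days consecutive days."""
    jan1 = dt.date(year, 1, 1)
    dates = tuple(jan1 + dt.timedelta(days=start_doy - 1 + i) for i in range(n_days))
    return pp.PollenSeries(
        station_id="t", taxon="Poaceae",
        dates=dates, concentrations=np.full(n_days, value),
    )
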