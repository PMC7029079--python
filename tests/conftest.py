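import numpy as np
import pytest

from plasticlim import AnnualSeries, SeasonalSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_annual(values, variable="precip", site_id="s1", start_year=2000, years=None):
    values = np.asarray(values, float)
    if years is None:
        years = np.arange(start_year, start_year + len(values))
    return AnnualSeries(site_id, variable, np.asarray(years), values)


def make_pair(early_values, late_values, site_id="s1", start_year=2000, years=None):
    early = make_annual(early_values, "tmax_early", site_id, start_year, years)
    late = make_annual(late_values, "tmax_late", site_id, start_year, years)
    return SeasonalSeries(site_id, early, late)


def random_annual(rng, n=60, mean=500.0, sd=60.0, site_id="s1"):
    vals = mean + sd * rng.standard_normal(n)
    return make_annual(vals, site_id=site_id)


def random_pair(rng, n=30, site_id="s1"):
    e = 10.0 + 1.2 * rng.standard_normal(n)
    l = 21.0 + 0.9 * rng.standard_normal(n)
    return make_pair(e, l, site_id=site_id)
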