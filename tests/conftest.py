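import numpy as np
import pandas as pd
import pytest

from bloodcast import DailyCountSeries, GeneratorConfig, generate_series


@pytest.fixture
def flat_profile_config():
    """Noiseless generator: constant level, weekday profile only."""
    return GeneratorConfig(n_weeks=10, base_level=100.0,
                           weekday_profile=(1, 1, 1, 1, 1, 0.5, 0.2),
                           annual_amplitude=0.0, trend_slope=0.0,
                           noise_sd=0.0, holiday_rate=0.0, seed=0)


@pytest.fixture
def deterministic_config():
    """Noiseless trend + weekday profile (no annual cycle, no holidays)."""
    return GeneratorConfig(n_weeks=61, annual_amplitude=0.0, trend_slope=0.9,
                           noise_sd=0.0, holiday_rate=0.0, seed=0)


@pytest.fixture
def default_series():
    return generate_series(GeneratorConfig(n_weeks=61, seed=7))


def make_series(counts, start="2018-03-05"):
    """Build a series from raw counts starting at the given date
    (default a Monday)."""
    counts = np.asarray(counts, dtype=float)
    dates = pd.date_range(start, periods=len(counts), freq="D")
    return DailyCountSeries(dates, counts)


@pytest.fixture
def series_factory():
    return make_series
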