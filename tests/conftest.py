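import numpy as np
import pandas as pd
import pytest

from airqc.qc import VALID, HourlySeries
from airqc.series import RawSensorSeries


@pytest.fixture
def make_raw():
    """Build a RawSensorSeries from (timestamp, value) pairs."""
    def _make(pairs, site="S01"):
        idx = pd.DatetimeIndex([pd.Timestamp(t) for t, _ in pairs])
        return RawSensorSeries(site, pd.Series([v for _, v in pairs], index=idx))
    return _make


@pytest.fixture
def make_hourly():
    """Build an HourlySeries of consecutive valid hours from a list of values."""
    def _make(values, start="2022-03-01", site="S01", n_readings=4, statuses=None):
        idx = pd.date_range(start, periods=len(values), freq="h")
        frame = pd.DataFrame({
            "pm25": np.asarray(values, dtype=float),
            "n_readings": n_readings,
            "status": statuses if statuses is not None else VALID,
        }, index=idx)
        frame.index.name = "hour_start"
        return HourlySeries(site, frame)
    return _make


@pytest.fixture
def quarter_hours():
    """Four 15-minute ticks within the given hour."""
    def _ticks(hour="2022-03-01 06:00", n=4):
        return pd.date_range(hour, periods=n, freq="15min")
    return _ticks
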