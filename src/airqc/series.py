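"""Raw time-series containers shared across the pipeline.

Timestamps are interval-start and timezone-naive throughout; a reading
stamped 09:15 covers [09:15, 09:30) and an hourly average stamped 09:00
covers [09:00, 10:00).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def _as_datetime_index(index) -> pd.DatetimeIndex:
    idx = pd.DatetimeIndex(index)
    if idx.tz is not None:
        raise ValueError("timestamps must be timezone-naive")
    return idx


@dataclass
class RawSensorSeries:
    """Per-site PM2.5 readings (µg/m³) at nominal 15-minute cadence.

    Gaps are allowed; timestamps must be strictly increasing and
    concentrations finite and non-negative.
    """

    site: str
    data: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        s = pd.Series(self.data, dtype=float)
        s.index = _as_datetime_index(s.index)
        if not s.index.is_monotonic_increasing or s.index.has_duplicates:
            raise ValueError(f"{self.site}: timestamps must be strictly increasing")
        vals = s.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"{self.site}: concentrations must be finite")
        if (vals < 0).any():
            raise ValueError(f"{self.site}: concentrations must be >= 0")
        s.name = "pm25_ugm3"
        s.index.name = "timestamp"
        self.data = s

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class MeteorologySeries:
    """Hourly temperature (°C) and relative humidity (%) records."""

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.frame)
        missing = {"temp_c", "rh_pct"} - set(df.columns)
        if missing:
            raise ValueError(f"meteorology missing columns: {sorted(missing)}")
        df.index = _as_datetime_index(df.index)
        if not df.index.is_monotonic_increasing or df.index.has_duplicates:
            raise ValueError("meteorology timestamps must be strictly increasing")
        rh = df["rh_pct"].to_numpy()
        if ((rh < 0) | (rh > 100)).any():
            raise ValueError("relative humidity must lie in [0, 100]")
        df.index.name = "timestamp"
        self.frame = df[["temp_c", "rh_pct"]].astype(float)

    def __len__(self) -> int:
        return len(self.frame)
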