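"""Four-step validation of 15-minute sensor data and data-capture accounting.

The pipeline converts raw 15-minute PM2.5 readings into hourly averages and
applies, once each and in order:

1. **Completeness** — an hour needs >= 3 of its 4 possible readings; a day
   needs >= 18 such hours; a month needs >= 23 such days (a 75% criterion at
   every level).  Hours, days and months falling short are discarded.
2. **Meteorology mask** — keep hours within the manufacturer's operating
   envelope (default −10 °C < t < 35 °C and RH > 35 %, both configurable).
3. **Static (stuck) data** — remove any window of 5 consecutive retained
   hourly values whose moving standard deviation is zero.
4. **MAD outliers** — per site and calendar month, exclude values further
   than 3 scaled median absolute deviations from the monthly median, with
   MAD = b * median(|Xi − X̃|), b = 1.4826 (normal-consistency constant).

Filters only ever change an hour's status, never its value, and each hour
carries the first (and only) reason it was removed, so a Table-of-capture
report partitions the period's potential hours exactly into valid, removed
per step, and missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from airqc.series import MeteorologySeries, RawSensorSeries

__all__ = [
    "VALID",
    "REMOVED_STEP1_HOUR",
    "REMOVED_STEP1_DAY",
    "REMOVED_STEP1_MONTH",
    "REMOVED_STEP2",
    "REMOVED_STEP3",
    "REMOVED_STEP4",
    "STATUSES",
    "ValidationConfig",
    "HourlySeries",
    "CaptureReport",
    "aggregate_to_hourly",
    "apply_completeness",
    "apply_met_filter",
    "apply_static_filter",
    "apply_mad_filter",
    "run_pipeline",
    "capture_report",
]

logger = logging.getLogger(__name__)

VALID = "valid"
REMOVED_STEP1_HOUR = "removed_step1_hour"
REMOVED_STEP1_DAY = "removed_step1_day"
REMOVED_STEP1_MONTH = "removed_step1_month"
REMOVED_STEP2 = "removed_step2"
REMOVED_STEP3 = "removed_step3"
REMOVED_STEP4 = "removed_step4"
STATUSES = (VALID, REMOVED_STEP1_HOUR, REMOVED_STEP1_DAY, REMOVED_STEP1_MONTH,
            REMOVED_STEP2, REMOVED_STEP3, REMOVED_STEP4)

_STATIC_TOL = 1e-12


@dataclass
class ValidationConfig:
    """All thresholds of validation Steps 1–4."""

    min_readings_per_hour: int = 3
    min_hours_per_day: int = 18
    min_days_per_month: int = 23
    temp_low: float = -10.0
    temp_high: float = 35.0
    rh_min: float | None = 35.0   # keep RH > rh_min (literal manufacturer rule)
    rh_max: float | None = None   # optionally also keep RH < rh_max
    static_window: int = 5
    mad_multiplier: float = 3.0
    b: float = 1.4826
    use_signed_deviation: bool = False   # audit-only literal form of the MAD
    reiterate_completeness: bool = False

    def __post_init__(self) -> None:
        for name in ("min_readings_per_hour", "min_hours_per_day",
                     "min_days_per_month", "static_window"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.temp_low >= self.temp_high:
            raise ValueError("temp_low must be below temp_high")
        if self.b <= 0 or self.mad_multiplier <= 0:
            raise ValueError("b and mad_multiplier must be > 0")


@dataclass
class HourlySeries:
    """Hourly-averaged series with per-hour validity status.

    ``frame`` is indexed by hour_start and has columns ``pm25`` (mean of the
    hour's readings, Xi), ``n_readings`` and ``status`` (one of STATUSES).
    Hours with no readings at all are absent and count as missing.
    """

    site: str
    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.frame
        if df.index.has_duplicates:
            raise ValueError("at most one record per hour")
        bad = set(df["status"]) - set(STATUSES)
        if bad:
            raise ValueError(f"unknown statuses: {sorted(bad)}")

    @property
    def valid_mask(self) -> pd.Series:
        return self.frame["status"] == VALID

    def valid_values(self) -> pd.Series:
        return self.frame.loc[self.valid_mask, "pm25"]

    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def with_frame(self, frame: pd.DataFrame) -> "HourlySeries":
        return HourlySeries(self.site, frame)


@dataclass
class CaptureReport:
    """Data-capture accounting for one site over an analysis period.

    potential_hours = number of clock hours in the period;
    valid + sum(removed_by_step) + missing = potential.
    """

    site: str
    potential_hours: int
    valid_hours: int
    missing_hours: int
    removed_by_step: dict[str, int]
    capture_pct: float

    def to_dict(self) -> dict:
        d = {"site": self.site, "potential_hours": self.potential_hours,
             "valid_hours": self.valid_hours, "missing_hours": self.missing_hours,
             "capture_pct": self.capture_pct}
        d.update(self.removed_by_step)
        return d


# --------------------------------------------------------------------------
# pipeline steps
# --------------------------------------------------------------------------

def aggregate_to_hourly(raw: RawSensorSeries, config: ValidationConfig | None = None) -> HourlySeries:
    """Average 15-minute readings into hourly means (Step 1, hour level).

    Hours with fewer than ``min_readings_per_hour`` readings are marked
    ``removed_step1_hour``; hours with no readings are simply absent.
    """
    cfg = config or ValidationConfig()
    s = raw.data
    grouped = s.groupby(s.index.floor("h"))
    df = pd.DataFrame({"pm25": grouped.mean(), "n_readings": grouped.size()})
    df["status"] = np.where(df["n_readings"] >= cfg.min_readings_per_hour,
                            VALID, REMOVED_STEP1_HOUR)
    df.index.name = "hour_start"
    return HourlySeries(raw.site, df)


def apply_completeness(hourly: HourlySeries, config: ValidationConfig | None = None) -> HourlySeries:
    """Step 1, day and month levels.

    A calendar day is covered iff it has >= ``min_hours_per_day`` currently
    valid hours; valid hours of uncovered days become ``removed_step1_day``.
    A calendar month is covered iff it has >= ``min_days_per_month`` covered
    days; remaining valid hours of uncovered months become
    ``removed_step1_month``.
    """
    cfg = config or ValidationConfig()
    df = hourly.frame.copy()
    valid = df["status"] == VALID
    day = df.index.floor("D")

    hours_per_day = valid.groupby(day).sum()
    covered_days = hours_per_day[hours_per_day >= cfg.min_hours_per_day].index
    day_ok = day.isin(covered_days)
    df.loc[valid & ~day_ok, "status"] = REMOVED_STEP1_DAY

    month_of_day = pd.PeriodIndex(covered_days, freq="M")
    covered_per_month = pd.Series(1, index=month_of_day).groupby(level=0).sum()
    good_months = covered_per_month[covered_per_month >= cfg.min_days_per_month].index
    month = df.index.to_period("M")
    still_valid = df["status"] == VALID
    df.loc[still_valid & ~month.isin(good_months), "status"] = REMOVED_STEP1_MONTH
    return hourly.with_frame(df)


def apply_met_filter(hourly: HourlySeries, met: MeteorologySeries,
                     config: ValidationConfig | None = None) -> HourlySeries:
    """Step 2 — mask hours outside the manufacturer's operating envelope.

    Keep condition (strict bounds): temp_low < t < temp_high, RH > rh_min
    (and RH < rh_max if configured).  Hours without a meteorology record are
    retained: absence of covariate data is not evidence of a violation.
    """
    cfg = config or ValidationConfig()
    df = hourly.frame.copy()
    valid = df["status"] == VALID
    joined = met.frame.reindex(df.index)
    have_met = joined["temp_c"].notna() & joined["rh_pct"].notna()

    ok = (joined["temp_c"] > cfg.temp_low) & (joined["temp_c"] < cfg.temp_high)
    if cfg.rh_min is not None:
        ok &= joined["rh_pct"] > cfg.rh_min
    if cfg.rh_max is not None:
        ok &= joined["rh_pct"] < cfg.rh_max

    n_missing = int((valid & ~have_met).sum())
    if n_missing:
        logger.warning("%s: %d valid hours lack meteorology and are retained",
                       hourly.site, n_missing)
    df.loc[valid & have_met & ~ok, "status"] = REMOVED_STEP2
    return hourly.with_frame(df)


def apply_static_filter(hourly: HourlySeries, config: ValidationConfig | None = None) -> HourlySeries:
    """Step 3 — remove stuck-sensor runs (zero moving standard deviation).

    The window slides over the currently valid hourly samples in time order
    (gaps ignored); every member of any window of ``static_window`` identical
    values (tolerance 1e−12) is marked ``removed_step3``.
    """
    cfg = config or ValidationConfig()
    df = hourly.frame.copy()
    valid_idx = df.index[df["status"] == VALID]
    vals = df.loc[valid_idx, "pm25"].to_numpy()
    k = cfg.static_window
    if len(vals) >= k:
        windows = sliding_window_view(vals, k)
        flat = (windows.max(axis=1) - windows.min(axis=1)) <= _STATIC_TOL
        flag = np.zeros(len(vals), dtype=bool)
        for start in np.flatnonzero(flat):
            flag[start:start + k] = True
        df.loc[valid_idx[flag], "status"] = REMOVED_STEP3
    return hourly.with_frame(df)


def apply_mad_filter(hourly: HourlySeries, config: ValidationConfig | None = None) -> HourlySeries:
    """Step 4 — monthly MAD-based outlier exclusion.

    Per calendar month over currently valid values Xi: X̃ = median(Xi),
    MAD = b * median(|Xi − X̃|); values with Xi < X̃ − m*MAD or Xi > X̃ + m*MAD
    become ``removed_step4``.  A month with MAD = 0 (constant values) removes
    nothing — stuck data is Step 3's job.
    """
    cfg = config or ValidationConfig()
    df = hourly.frame.copy()
    valid = df["status"] == VALID
    month = df.index.to_period("M")
    for _, sub in df[valid].groupby(month[valid]):
        x = sub["pm25"].to_numpy()
        med = float(np.median(x))
        dev = (x - med) if cfg.use_signed_deviation else np.abs(x - med)
        mad = cfg.b * float(np.median(dev))
        if mad <= _STATIC_TOL:
            continue
        m = cfg.mad_multiplier
        out = (x < med - m * mad) | (x > med + m * mad)
        df.loc[sub.index[out], "status"] = REMOVED_STEP4
    return hourly.with_frame(df)


def run_pipeline(raw: RawSensorSeries, met: MeteorologySeries | None = None,
                 config: ValidationConfig | None = None,
                 period: tuple | None = None) -> tuple[HourlySeries, CaptureReport]:
    """Apply the four validation steps once, in order, and report capture.

    ``period`` is the (start, end) analysis window defining the potential-hour
    denominator; it defaults to the span of the raw data rounded to whole
    hours.
    """
    cfg = config or ValidationConfig()
    hourly = aggregate_to_hourly(raw, cfg)
    hourly = apply_completeness(hourly, cfg)
    if met is not None:
        hourly = apply_met_filter(hourly, met, cfg)
    hourly = apply_static_filter(hourly, cfg)
    hourly = apply_mad_filter(hourly, cfg)
    if cfg.reiterate_completeness:
        hourly = apply_completeness(hourly, cfg)
    if period is None:
        idx = hourly.frame.index
        period = (idx[0], idx[-1] + pd.Timedelta(hours=1))
    report = capture_report(hourly, period)
    for step, n in report.removed_by_step.items():
        if n:
            logger.info("%s: %d hours %s", hourly.site, n, step)
    return hourly, report


def capture_report(hourly: HourlySeries, period: tuple) -> CaptureReport:
    """Data-capture accounting against the period's potential clock hours."""
    start, end = pd.Timestamp(period[0]), pd.Timestamp(period[1])
    if end <= start:
        raise ValueError("empty analysis period")
    potential = len(pd.date_range(start, end, freq="h", inclusive="left"))
    df = hourly.frame
    in_period = df[(df.index >= start) & (df.index < end)]
    valid = int((in_period["status"] == VALID).sum())
    removed = {s: int((in_period["status"] == s).sum()) for s in STATUSES[1:]}
    missing = potential - len(in_period)
    return CaptureReport(site=hourly.site, potential_hours=potential,
                         valid_hours=valid, missing_hours=missing,
                         removed_by_step=removed,
                         capture_pct=100.0 * valid / potential)


def run_network(network: Mapping[str, RawSensorSeries],
                met: MeteorologySeries | None = None,
                config: ValidationConfig | None = None,
                period: tuple | None = None) -> tuple[dict[str, HourlySeries], list[CaptureReport]]:
    """Run the pipeline over every site of a network."""
    validated: dict[str, HourlySeries] = {}
    reports: list[CaptureReport] = []
    for site, raw in network.items():
        hourly, report = run_pipeline(raw, met, config, period)
        validated[site] = hourly
        reports.append(report)
    return validated, reports
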