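"""WHO-guideline exceedance statistics, time-variation profiles, correlations.

Works on validated hourly series: daily means over well-covered days, summary
statistics with guideline-exceedance percentages (2021 WHO global air quality
guidelines), mean diurnal/weekly/monthly profiles, and pairwise inter-site
Pearson correlation of daily means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from airqc.qc import VALID, HourlySeries

__all__ = [
    "GuidelineSet",
    "ExceedanceSummary",
    "ProfileSet",
    "WHO_PM25",
    "WHO_NO2",
    "daily_means",
    "exceedance_summary",
    "time_variation",
    "site_correlation",
]


@dataclass(frozen=True)
class GuidelineSet:
    """Annual and 24-hour guideline limits for one pollutant (µg/m³)."""

    pollutant: str
    annual_limit: float
    daily_limit: float

    def __post_init__(self) -> None:
        if self.annual_limit <= 0 or self.daily_limit <= 0:
            raise ValueError("guideline limits must be > 0")


#: 2021 WHO global air quality guidelines.
WHO_PM25 = GuidelineSet("PM2.5", annual_limit=5.0, daily_limit=15.0)
WHO_NO2 = GuidelineSet("NO2", annual_limit=10.0, daily_limit=25.0)


@dataclass
class ExceedanceSummary:
    """Summary statistics and guideline exceedance for one site."""

    site: str
    mean: float
    max: float
    p95: float
    p25: float
    median: float
    pct_days_exceeding: float
    n_days: int
    annual_mean_exceeds: bool

    def to_dict(self) -> dict:
        return {"site": self.site, "mean": self.mean, "max": self.max,
                "p95": self.p95, "p25": self.p25, "median": self.median,
                "pct_days_exceeding": self.pct_days_exceeding,
                "n_days": self.n_days,
                "annual_mean_exceeds": self.annual_mean_exceeds}


@dataclass
class ProfileSet:
    """Mean diurnal / weekly / monthly profiles with group sizes.

    ``diurnal`` is indexed by hour-of-day (0–23), ``weekly`` by day-of-week
    (0=Monday), ``monthly`` by calendar month (1–12).  Groups with no data
    are absent, not zero.
    """

    diurnal: pd.Series = field(repr=False)
    weekly: pd.Series = field(repr=False)
    monthly: pd.Series = field(repr=False)
    diurnal_n: pd.Series = field(repr=False)
    weekly_n: pd.Series = field(repr=False)
    monthly_n: pd.Series = field(repr=False)


def daily_means(hourly: HourlySeries, min_hours: int = 18) -> pd.Series:
    """Calendar-day means of valid hours; days with fewer than ``min_hours``
    valid hours are not counted as recorded days."""
    vals = hourly.valid_values()
    if vals.empty:
        return pd.Series(dtype=float)
    grouped = vals.groupby(vals.index.floor("D"))
    means = grouped.mean()
    counts = grouped.size()
    out = means[counts >= min_hours]
    out.index.name = "day"
    return out


def exceedance_summary(hourly: HourlySeries, guidelines: GuidelineSet = WHO_PM25,
                       min_hours: int = 18) -> ExceedanceSummary:
    """Hourly summary statistics plus % of recorded days whose 24-h mean
    strictly exceeds the daily guideline."""
    vals = hourly.valid_values().to_numpy()
    if len(vals) == 0:
        raise ValueError(f"{hourly.site}: no valid data")
    days = daily_means(hourly, min_hours=min_hours)
    n_days = len(days)
    pct = 100.0 * float((days > guidelines.daily_limit).sum()) / n_days if n_days else float("nan")
    mean = float(vals.mean())
    return ExceedanceSummary(
        site=hourly.site,
        mean=mean,
        max=float(vals.max()),
        p95=float(np.percentile(vals, 95)),
        p25=float(np.percentile(vals, 25)),
        median=float(np.percentile(vals, 50)),
        pct_days_exceeding=pct,
        n_days=n_days,
        annual_mean_exceeds=bool(mean > guidelines.annual_limit),
    )


def time_variation(hourly: HourlySeries) -> ProfileSet:
    """Mean diurnal, weekly and monthly profiles of the valid hours."""
    vals = hourly.valid_values()
    if vals.empty:
        empty = pd.Series(dtype=float)
        return ProfileSet(empty, empty, empty, empty, empty, empty)
    idx = vals.index
    by_hour = vals.groupby(idx.hour)
    by_dow = vals.groupby(idx.dayofweek)
    by_month = vals.groupby(idx.month)
    return ProfileSet(diurnal=by_hour.mean(), weekly=by_dow.mean(),
                      monthly=by_month.mean(), diurnal_n=by_hour.size(),
                      weekly_n=by_dow.size(), monthly_n=by_month.size())


def site_correlation(daily: Mapping[str, pd.Series], min_common_days: int = 3) -> pd.DataFrame:
    """Pairwise Pearson correlation of per-site daily means.

    Each pair is correlated over its intersecting recorded days; pairs with
    fewer than ``min_common_days`` common days get NaN.  The matrix is
    symmetric with unit diagonal.
    """
    sites = list(daily)
    if len(sites) < 2:
        raise ValueError("need at least two sites")
    mat = pd.DataFrame(np.nan, index=sites, columns=sites, dtype=float)
    for s in sites:
        mat.loc[s, s] = 1.0
    for i, a in enumerate(sites):
        for b in sites[i + 1:]:
            joined = pd.concat([daily[a], daily[b]], axis=1, join="inner").dropna()
            if len(joined) < min_common_days:
                continue
            r = float(np.corrcoef(joined.iloc[:, 0], joined.iloc[:, 1])[0, 1])
            mat.loc[a, b] = mat.loc[b, a] = r
    return mat
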