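"""Passive NO2 diffusion-tube triplicate aggregation and accuracy checks.

Tubes are deployed in triplicate for nominally four weeks; the lab returns a
period-average NO2 concentration per tube.  Each deployment is assigned to
the calendar month it best represents, the triplicate mean becomes the
location's monthly estimate, and a coefficient-of-variation flag screens
divergent triplicates.  Accuracy against a co-located reference monitor is
expressed as a signed percentage difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TubeDeployment",
    "MonthlyTubeResult",
    "assign_month",
    "triplicate_stats",
    "percent_accuracy",
    "period_summary",
]

_NOMINAL_MIN = pd.Timedelta(weeks=2)
_NOMINAL_MAX = pd.Timedelta(weeks=6)


@dataclass
class TubeDeployment:
    """One location-period deployment with its lab-reported NO2 values (µg/m³)."""

    location: str
    deploy_start: pd.Timestamp
    deploy_end: pd.Timestamp
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        self.deploy_start = pd.Timestamp(self.deploy_start)
        self.deploy_end = pd.Timestamp(self.deploy_end)
        if self.deploy_end <= self.deploy_start:
            raise ValueError(f"{self.location}: deploy_end must be after deploy_start")
        self.values = tuple(float(v) for v in self.values)
        if not self.values:
            raise ValueError(f"{self.location}: no tube values")
        if any(v <= 0 for v in self.values):
            raise ValueError(f"{self.location}: tube concentrations must be > 0")
        duration = self.deploy_end - self.deploy_start
        if not _NOMINAL_MIN <= duration <= _NOMINAL_MAX:
            warnings.warn(f"{self.location}: deployment of {duration} outside the "
                          "nominal 2-6 week range", stacklevel=2)


@dataclass
class MonthlyTubeResult:
    """Monthly location estimate from one triplicate deployment."""

    location: str
    month: pd.Period
    mean_no2: float
    n_tubes: int
    cv: float
    precision_flag: bool


def assign_month(deployment: TubeDeployment) -> pd.Period:
    """Calendar month the deployment best represents.

    Counts the calendar dates touched by the exposure (inclusive of the
    deploy and collect dates) per month; the month with the most dates wins,
    ties going to the earlier month.
    """
    days = pd.date_range(deployment.deploy_start.normalize(),
                         deployment.deploy_end.normalize(), freq="D")
    counts = pd.Series(1, index=days.to_period("M")).groupby(level=0).sum()
    return counts.sort_index().idxmax()   # idxmax takes the first (earlier) max


def triplicate_stats(deployment: TubeDeployment, cv_threshold: float = 0.20) -> MonthlyTubeResult:
    """Triplicate mean, coefficient of variation and precision flag.

    cv = sample (n−1) standard deviation / mean.  The flag raises when the
    triplicate is divergent (cv > threshold) or fewer than two tubes survived.
    """
    vals = np.asarray(deployment.values, dtype=float)
    mean = float(vals.mean())
    n = len(vals)
    cv = float(vals.std(ddof=1) / mean) if n >= 2 else float("nan")
    flagged = n < 2 or cv > cv_threshold
    return MonthlyTubeResult(location=deployment.location,
                             month=assign_month(deployment),
                             mean_no2=mean, n_tubes=n, cv=cv,
                             precision_flag=bool(flagged))


def percent_accuracy(tube_mean: float, reference_mean: float) -> float:
    """Signed % difference of the tube estimate from the reference monitor:
    100 * (tube − reference) / reference."""
    if reference_mean <= 0:
        raise ValueError("reference_mean must be > 0")
    return 100.0 * (tube_mean - reference_mean) / reference_mean


def period_summary(results: Iterable[MonthlyTubeResult],
                   months: Sequence[pd.Period] | None = None) -> pd.DataFrame:
    """Per-location mean of monthly means over a set of months.

    Locations missing some requested months are averaged over the months they
    have, with the count used reported in ``n_months``.
    """
    rows = [(r.location, r.month, r.mean_no2) for r in results]
    if not rows:
        raise ValueError("no monthly results supplied")
    df = pd.DataFrame(rows, columns=["location", "month", "mean_no2"])
    if months is not None:
        months = [pd.Period(m, freq="M") for m in months]
        if not months:
            raise ValueError("empty month selection")
        df = df[df["month"].isin(months)]
        if df.empty:
            raise ValueError("no results in the requested months")
    out = df.groupby("location").agg(mean_no2=("mean_no2", "mean"),
                                     n_months=("month", "nunique"))
    return out.reset_index()
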