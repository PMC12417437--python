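"""Month-matched baseline vs follow-up comparison with Welch's t-test.

The unit of analysis is the monthly triplicate mean: for each location the
calendar months present in both the baseline and follow-up campaigns are
paired, and the two groups of monthly means are compared with Welch's
unequal-variance two-sample t-test (Welch–Satterthwaite degrees of freedom)
and a 95% confidence interval for the baseline − follow-up difference.
A screening step lists the locations with a significant change.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from airqc.tubes import MonthlyTubeResult

__all__ = [
    "InterventionResult",
    "month_match",
    "welch_compare",
    "location_screen",
    "compare_periods",
]

logger = logging.getLogger(__name__)


@dataclass
class InterventionResult:
    """Baseline vs follow-up comparison for one location.

    ``difference`` is baseline_mean − followup_mean (µg/m³); a positive value
    means concentrations fell between the two campaigns.  ``ci_low``/``ci_high``
    bound the difference at the (1 − alpha) level.
    """

    location: str
    months_used: tuple[int, ...]
    baseline_mean: float
    followup_mean: float
    difference: float
    t_stat: float
    df: float
    p_value: float
    ci_low: float
    ci_high: float
    significant: bool

    def to_dict(self) -> dict:
        return {"location": self.location,
                "months_used": ",".join(str(m) for m in self.months_used),
                "baseline_mean": self.baseline_mean,
                "followup_mean": self.followup_mean,
                "difference": self.difference, "t_stat": self.t_stat,
                "df": self.df, "p_value": self.p_value,
                "ci_low": self.ci_low, "ci_high": self.ci_high,
                "significant": self.significant}


def month_match(baseline: Iterable[MonthlyTubeResult],
                followup: Iterable[MonthlyTubeResult]) -> dict[str, list[int]]:
    """Calendar months (1–12) present in both campaigns, per location.

    Unmatched months are excluded; locations with no common month are skipped
    with a warning.
    """
    def by_location(results):
        out: dict[str, set[int]] = {}
        for r in results:
            out.setdefault(r.location, set()).add(r.month.month)
        return out

    base, follow = by_location(baseline), by_location(followup)
    matched: dict[str, list[int]] = {}
    for loc in sorted(set(base) | set(follow)):
        common = sorted(base.get(loc, set()) & follow.get(loc, set()))
        if not common:
            logger.warning("%s: no common months between baseline and follow-up; skipped", loc)
            continue
        matched[loc] = common
    if not matched:
        raise ValueError("no location has months in both periods")
    return matched


def welch_compare(baseline_values: Sequence[float], followup_values: Sequence[float],
                  alpha: float = 0.05, location: str = "",
                  months_used: Sequence[int] = (), pooled: bool = False) -> InterventionResult:
    """Two-sample t comparison of baseline vs follow-up values.

    Welch's unequal-variance statistic by default (``pooled=True`` gives the
    classical equal-variance Student form).  Returns the two-sided p-value
    and the (1 − alpha) confidence interval for mean(baseline) − mean(followup).
    """
    a = np.asarray(baseline_values, dtype=float)
    b = np.asarray(followup_values, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values per group")
    m1, m2 = a.mean(), b.mean()
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    n1, n2 = len(a), len(b)
    diff = float(m1 - m2)

    if pooled:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1 / n1 + 1 / n2)
        df = float(n1 + n2 - 2)
    else:
        se2 = v1 / n1 + v2 / n2
        if se2 > 0:
            df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        else:
            df = float(n1 + n2 - 2)

    if se2 == 0:
        # degenerate: no variance in either group
        t_stat = 0.0 if diff == 0 else math.copysign(math.inf, diff)
        p = 1.0 if diff == 0 else 0.0
        ci_low = ci_high = diff
    else:
        se = math.sqrt(se2)
        t_stat = diff / se
        p = 2.0 * float(stats.t.sf(abs(t_stat), df))
        t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, df))
        ci_low, ci_high = diff - t_crit * se, diff + t_crit * se

    return InterventionResult(location=location, months_used=tuple(months_used),
                              baseline_mean=float(m1), followup_mean=float(m2),
                              difference=diff, t_stat=float(t_stat), df=float(df),
                              p_value=float(p), ci_low=float(ci_low),
                              ci_high=float(ci_high), significant=bool(p < alpha))


def compare_periods(baseline: Iterable[MonthlyTubeResult],
                    followup: Iterable[MonthlyTubeResult],
                    alpha: float = 0.05, pooled: bool = False) -> list[InterventionResult]:
    """Month-match and Welch-compare every location of two campaigns."""
    baseline = list(baseline)
    followup = list(followup)
    matched = month_match(baseline, followup)
    results = []
    for loc, months in matched.items():
        base_vals = [r.mean_no2 for r in baseline
                     if r.location == loc and r.month.month in months]
        follow_vals = [r.mean_no2 for r in followup
                       if r.location == loc and r.month.month in months]
        results.append(welch_compare(base_vals, follow_vals, alpha=alpha,
                                     location=loc, months_used=months,
                                     pooled=pooled))
    return results


def location_screen(results: Iterable[InterventionResult], alpha: float = 0.05,
                    bonferroni: bool = False) -> list[InterventionResult]:
    """Locations with a significant baseline vs follow-up change.

    Returns results with p < alpha (alpha / m under Bonferroni), sorted by
    difference descending.
    """
    results = list(results)
    if not results:
        raise ValueError("no results to screen")
    threshold = alpha / len(results) if bonferroni else alpha
    hits = [r for r in results if r.p_value < threshold]
    return sorted(hits, key=lambda r: r.difference, reverse=True)
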