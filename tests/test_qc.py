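"""Validation Steps 1-4: worked examples, brute-force oracles, conservation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from airqc.qc import (REMOVED_STEP1_DAY, REMOVED_STEP1_HOUR,
                      REMOVED_STEP1_MONTH, REMOVED_STEP2, REMOVED_STEP3,
                      REMOVED_STEP4, VALID, ValidationConfig,
                      aggregate_to_hourly, apply_completeness, apply_mad_filter,
                      apply_met_filter, apply_static_filter, capture_report,
                      run_pipeline)
from airqc.series import MeteorologySeries, RawSensorSeries
from airqc.synth import calm_network_config, generate_meteorology, generate_network

CFG = ValidationConfig()


def _hourly(values, statuses=None, start="2022-03-01", site="S01"):
    idx = pd.date_range(start, periods=len(values), freq="h")
    frame = pd.DataFrame({"pm25": np.asarray(values, dtype=float),
                          "n_readings": 4,
                          "status": statuses if statuses is not None else VALID},
                         index=idx)
    from airqc.qc import HourlySeries
    return HourlySeries(site, frame)


# ---------------------------------------------------------------------------
# independent brute-force oracles
# ---------------------------------------------------------------------------

def brute_static_flags(values, window):
    """Enumerate every window; flag members of any all-identical window."""
    n = len(values)
    flagged = [False] * n
    for start in range(n - window + 1):
        w = values[start:start + window]
        if max(w) - min(w) <= 1e-12:
            for i in range(start, start + window):
                flagged[i] = True
    return flagged


def brute_mad_outliers(values, b=1.4826, m=3.0):
    """Definitional monthly MAD exclusion on a plain list."""
    xs = sorted(values)
    n = len(xs)
    med = xs[n // 2] if n % 2 else (xs[n // 2 - 1] + xs[n // 2]) / 2
    devs = sorted(abs(x - med) for x in values)
    mad = b * (devs[n // 2] if n % 2 else (devs[n // 2 - 1] + devs[n // 2]) / 2)
    if mad <= 1e-12:
        return [False] * n
    return [(x < med - m * mad) or (x > med + m * mad) for x in values]


# ---------------------------------------------------------------------------
# Step 1 — hourly aggregation
# ---------------------------------------------------------------------------

class TestAggregateToHourly:
    @pytest.mark.parametrize("values,expect_status,expect_mean", [
        ([2.0, 4.0, 6.0, 8.0], VALID, 5.0),
        ([3.0, 3.0, 3.0], VALID, 3.0),        # boundary: exactly 3 readings
        ([5.0, 7.0], REMOVED_STEP1_HOUR, 6.0),
    ])
    def test_readings_per_hour(self, make_raw, quarter_hours, values,
                               expect_status, expect_mean):
        ticks = quarter_hours(n=len(values))
        raw = make_raw(list(zip(ticks, values)))
        hourly = aggregate_to_hourly(raw, CFG)
        row = hourly.frame.iloc[0]
        assert row["status"] == expect_status
        assert row["pm25"] == pytest.approx(expect_mean)
        assert row["n_readings"] == len(values)

    def test_empty_hours_are_absent(self, make_raw, quarter_hours):
        pairs = [(t, 1.0) for t in quarter_hours("2022-03-01 06:00")]
        pairs += [(t, 2.0) for t in quarter_hours("2022-03-01 09:00")]
        hourly = aggregate_to_hourly(make_raw(pairs), CFG)
        assert list(hourly.frame.index) == [pd.Timestamp("2022-03-01 06:00"),
                                            pd.Timestamp("2022-03-01 09:00")]


# ---------------------------------------------------------------------------
# Step 1 — day/month completeness
# ---------------------------------------------------------------------------

def _month_raw(n_days=25, hours_per_day=24, readings_per_hour=4,
               start="2022-03-01", value=5.0):
    pairs = []
    day0 = pd.Timestamp(start)
    for d in range(n_days):
        for h in range(hours_per_day):
            for q in range(readings_per_hour):
                pairs.append((day0 + pd.Timedelta(days=d, hours=h, minutes=15 * q),
                              value + 0.01 * (d * 24 * 4 + h * 4 + q) % 3))
    idx = pd.DatetimeIndex([t for t, _ in pairs])
    return RawSensorSeries("S01", pd.Series([v for _, v in pairs], index=idx))


class TestCompleteness:
    @pytest.mark.parametrize("hours,expected", [(18, VALID), (17, REMOVED_STEP1_DAY)])
    def test_day_coverage_boundary(self, hours, expected):
        raw = _month_raw(n_days=24, hours_per_day=24)
        # shorten the final day to `hours` hours
        cutoff = pd.Timestamp("2022-03-24") + pd.Timedelta(hours=hours)
        data = raw.data[(raw.data.index < pd.Timestamp("2022-03-24")) |
                        ((raw.data.index >= pd.Timestamp("2022-03-24")) &
                         (raw.data.index < cutoff))]
        hourly = apply_completeness(aggregate_to_hourly(
            RawSensorSeries("S01", data), CFG), CFG)
        last_day = hourly.frame[hourly.frame.index >= "2022-03-24"]
        assert (last_day["status"] == expected).all()

    @pytest.mark.parametrize("n_days,expected", [(23, VALID), (22, REMOVED_STEP1_MONTH)])
    def test_month_coverage_boundary(self, n_days, expected):
        hourly = apply_completeness(aggregate_to_hourly(_month_raw(n_days=n_days), CFG), CFG)
        assert (hourly.frame["status"] == expected).all()


# ---------------------------------------------------------------------------
# Step 2 — meteorology mask
# ---------------------------------------------------------------------------

class TestMetFilter:
    @pytest.mark.parametrize("temp,rh,expected", [
        (40.0, 50.0, REMOVED_STEP2),   # too hot
        (-15.0, 50.0, REMOVED_STEP2),  # too cold
        (20.0, 30.0, REMOVED_STEP2),   # literal rule keeps only RH > 35
        (20.0, 50.0, VALID),
        (35.0, 50.0, REMOVED_STEP2),   # strict upper bound
    ])
    def test_envelope(self, make_hourly, temp, rh, expected):
        hourly = make_hourly([5.0])
        met = MeteorologySeries(pd.DataFrame(
            {"temp_c": [temp], "rh_pct": [rh]},
            index=pd.DatetimeIndex([hourly.frame.index[0]])))
        out = apply_met_filter(hourly, met, CFG)
        assert out.frame["status"].iloc[0] == expected

    def test_hours_without_meteorology_are_retained(self, make_hourly):
        hourly = make_hourly([5.0, 6.0])
        met = MeteorologySeries(pd.DataFrame(
            {"temp_c": [20.0], "rh_pct": [50.0]},
            index=pd.DatetimeIndex([hourly.frame.index[0]])))
        out = apply_met_filter(hourly, met, CFG)
        assert (out.frame["status"] == VALID).all()

    def test_configurable_high_rh_mask(self, make_hourly):
        cfg = ValidationConfig(rh_min=None, rh_max=85.0)
        hourly = make_hourly([5.0, 6.0])
        met = MeteorologySeries(pd.DataFrame(
            {"temp_c": [20.0, 20.0], "rh_pct": [90.0, 30.0]},
            index=hourly.frame.index))
        out = apply_met_filter(hourly, met, cfg)
        assert list(out.frame["status"]) == [REMOVED_STEP2, VALID]


# ---------------------------------------------------------------------------
# Step 3 — static data
# ---------------------------------------------------------------------------

class TestStaticFilter:
    def test_five_identical_removed(self, make_hourly):
        out = apply_static_filter(make_hourly([4.0] * 5), CFG)
        assert (out.frame["status"] == REMOVED_STEP3).all()

    def test_one_differing_value_keeps_all(self, make_hourly):
        out = apply_static_filter(make_hourly([4.0, 4.0, 4.1, 4.0, 4.0]), CFG)
        assert (out.frame["status"] == VALID).all()

    def test_seven_sample_run_fully_removed(self, make_hourly):
        values = [3.0, 5.0] + [4.0] * 7 + [6.0]
        out = apply_static_filter(make_hourly(values), CFG)
        expected = brute_static_flags(values, CFG.static_window)
        got = (out.frame["status"] == REMOVED_STEP3).tolist()
        assert got == expected
        assert sum(got) == 7

    def test_window_ignores_gaps_in_time(self, make_hourly):
        # 5 identical valid samples separated by a removed hour still count
        statuses = [VALID] * 3 + [REMOVED_STEP2] + [VALID] * 2
        hourly = make_hourly([4.0] * 6, statuses=statuses)
        out = apply_static_filter(hourly, CFG)
        assert (out.frame.loc[out.frame["status"] != REMOVED_STEP2, "status"]
                == REMOVED_STEP3).all()

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from([1.0, 2.0, 3.0]), min_size=1, max_size=60),
           st.integers(min_value=2, max_value=6))
    def test_matches_window_enumeration_oracle(self, values, window):
        cfg = ValidationConfig(static_window=window)
        out = apply_static_filter(_hourly(values), cfg)
        got = (out.frame["status"] == REMOVED_STEP3).tolist()
        assert got == brute_static_flags(values, window)


# ---------------------------------------------------------------------------
# Step 4 — MAD outliers
# ---------------------------------------------------------------------------

class TestMadFilter:
    def test_worked_example_single_outlier(self, make_hourly):
        values = [3.0, 3.0, 4.0, 5.0, 5.0, 6.0, 30.0]
        out = apply_mad_filter(make_hourly(values), CFG)
        got = (out.frame["status"] == REMOVED_STEP4).tolist()
        # X̃=5, median |dev|=1, MAD=1.4826, bounds [0.5522, 9.4478]
        assert got == [False] * 6 + [True]

    def test_constant_month_removes_nothing(self, make_hourly):
        out = apply_mad_filter(make_hourly([7.0] * 30), CFG)
        assert (out.frame["status"] == VALID).all()

    def test_symmetric_small_month_kept(self, make_hourly):
        out = apply_mad_filter(make_hourly([4.0, 5.0, 6.0]), CFG)
        assert (out.frame["status"] == VALID).all()

    def test_months_are_independent(self, make_hourly):
        # 30 µg/m³ is an outlier among ~5s but not among ~28s
        march = [3.0, 3.0, 4.0, 5.0, 5.0, 6.0, 30.0]
        hourly_march = make_hourly(march, start="2022-03-01")
        hourly_april = make_hourly([27.0, 28.0, 29.0, 30.0, 31.0],
                                   start="2022-04-01")
        frame = pd.concat([hourly_march.frame, hourly_april.frame])
        out = apply_mad_filter(hourly_march.with_frame(frame), CFG)
        assert (out.frame.loc["2022-04", "status"] == VALID).all()
        assert (out.frame.loc["2022-03", "status"] == REMOVED_STEP4).sum() == 1

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=100, allow_nan=False,
                              width=32),
                    min_size=1, max_size=80))
    def test_matches_definitional_oracle(self, values):
        out = apply_mad_filter(_hourly(values), CFG)
        got = (out.frame["status"] == REMOVED_STEP4).tolist()
        assert got == brute_mad_outliers(values)


# ---------------------------------------------------------------------------
# full pipeline and capture accounting
# ---------------------------------------------------------------------------

class TestPipelineAndCapture:
    def test_missing_month_capture_fraction(self):
        # one fully missing 31-day month in a 365-day year of clean data
        cfg = calm_network_config("2021-09-01", "2022-09-01", n_sites=1, seed=2)
        net = generate_network(cfg)
        data = net.series["S01"].data
        data = data[(data.index < "2021-12-01") | (data.index >= "2022-01-01")]
        hourly, report = run_pipeline(
            RawSensorSeries("S01", data),
            period=(pd.Timestamp("2021-09-01"), pd.Timestamp("2022-09-01")))
        assert report.potential_hours == 8760
        assert report.missing_hours == 744
        assert report.capture_pct == pytest.approx(100 * (8760 - 744) / 8760)

    def test_capture_partition_identity(self):
        net = generate_network(calm_network_config("2022-01-01", "2022-03-01",
                                                   n_sites=1, seed=5))
        data = net.series["S01"].data
        data = data.drop(data.index[1000:1100])   # puncture some hours
        hourly, report = run_pipeline(RawSensorSeries("S01", data))
        total = (report.valid_hours + report.missing_hours
                 + sum(report.removed_by_step.values()))
        assert total == report.potential_hours

    def test_filters_never_change_values(self, make_hourly):
        values = [3.0, 3.0, 4.0, 5.0, 5.0, 6.0, 30.0] + [4.0] * 6
        hourly = make_hourly(values)
        out = apply_mad_filter(apply_static_filter(hourly, CFG), CFG)
        pd.testing.assert_series_equal(out.frame["pm25"], hourly.frame["pm25"])

    def test_monotone_removal_across_steps(self):
        net = generate_network(calm_network_config("2022-01-01", "2022-03-01",
                                                   n_sites=1, seed=7))
        met = generate_meteorology("2022-01-01", "2022-03-01", seed=8)
        h = aggregate_to_hourly(net.series["S01"], CFG)
        counts = [h.n_valid()]
        for step in (apply_completeness,
                     lambda x, c: apply_met_filter(x, met, c),
                     apply_static_filter, apply_mad_filter):
            h = step(h, CFG)
            counts.append(h.n_valid())
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_capture_report_percentage(self, make_hourly):
        statuses = [VALID] * 8059 + [REMOVED_STEP2] * 701
        hourly = make_hourly([5.0] * 8760, start="2021-09-01", statuses=statuses)
        report = capture_report(hourly, ("2021-09-01", "2022-09-01"))
        assert report.potential_hours == 8760
        assert report.capture_pct == pytest.approx(92.0, abs=0.005)

    def test_all_valid_and_none_valid_extremes(self, make_hourly):
        hourly = make_hourly([5.0] * 48, start="2022-03-01")
        assert capture_report(hourly, ("2022-03-01", "2022-03-03")).capture_pct == 100.0
        removed = make_hourly([5.0] * 48, start="2022-03-01",
                              statuses=[REMOVED_STEP1_DAY] * 48)
        assert capture_report(removed, ("2022-03-01", "2022-03-03")).capture_pct == 0.0

    def test_empty_period_rejected(self, make_hourly):
        with pytest.raises(ValueError, match="period"):
            capture_report(make_hourly([1.0]), ("2022-03-02", "2022-03-02"))

    def test_unsorted_input_rejected(self):
        idx = pd.DatetimeIndex(["2022-03-01 00:15", "2022-03-01 00:00"])
        with pytest.raises(ValueError, match="increasing"):
            RawSensorSeries("S01", pd.Series([1.0, 2.0], index=idx))
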