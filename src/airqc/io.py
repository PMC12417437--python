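"""CSV readers/writers and provenance records.

All interchange formats are plain CSV with ISO 8601, timezone-naive
timestamps:

* sensor:      ``timestamp,site,pm25_ugm3``
* meteorology: ``timestamp,temp_c,rh_pct``
* tubes:       ``location,deploy_start,deploy_end,tube_id,no2_ugm3``
* validated hourly: ``hour_start,site,pm25_ugm3,n_readings,status``
* reference monitor: ``month,no2_ugm3`` (month as YYYY-MM)

Readers validate shape and content and raise descriptive errors naming the
offending row; writers round-trip bit-identically with their readers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from airqc import __version__ as _version
from airqc.qc import CaptureReport, HourlySeries
from airqc.series import MeteorologySeries, RawSensorSeries
from airqc.tubes import MonthlyTubeResult, TubeDeployment

logger = logging.getLogger(__name__)


def _require_columns(df: pd.DataFrame, required: set[str], path) -> None:
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")


def _parse_timestamps(series: pd.Series, path, column: str) -> pd.Series:
    parsed = pd.to_datetime(series, format="ISO8601", errors="coerce")
    bad = parsed.isna() & series.notna()
    if bad.any():
        row = int(bad.idxmax())
        raise ValueError(f"{path}: unparseable {column} at row {row}: {series[row]!r}")
    if parsed.isna().any():
        row = int(parsed.isna().idxmax())
        raise ValueError(f"{path}: empty {column} at row {row}")
    return parsed


# --------------------------------------------------------------------------
# sensor series
# --------------------------------------------------------------------------

def read_sensor_csv(path) -> dict[str, RawSensorSeries]:
    """Read per-site 15-minute readings; sorted and de-duplicated per site.

    Duplicate (site, timestamp) rows with equal values collapse with a
    warning; conflicting duplicates are an error.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, {"timestamp", "site", "pm25_ugm3"}, path)
    df["timestamp"] = _parse_timestamps(df["timestamp"], path, "timestamp")
    neg = df["pm25_ugm3"] < 0
    if neg.any():
        row = int(neg.idxmax())
        raise ValueError(f"{path}: negative concentration at row {row}")

    dup = df.duplicated(["site", "timestamp"], keep=False)
    if dup.any():
        conflicting = (df[dup].groupby(["site", "timestamp"])["pm25_ugm3"]
                       .nunique() > 1)
        if conflicting.any():
            site, ts = conflicting.idxmax()
            raise ValueError(f"{path}: conflicting duplicate rows for {site} at {ts}")
        logger.warning("%s: collapsed %d duplicate rows", path,
                       int(df.duplicated(['site', 'timestamp']).sum()))
        df = df.drop_duplicates(["site", "timestamp"])

    out = {}
    for site, sub in df.groupby("site", sort=True):
        sub = sub.sort_values("timestamp")
        out[str(site)] = RawSensorSeries(
            str(site), pd.Series(sub["pm25_ugm3"].to_numpy(),
                                 index=pd.DatetimeIndex(sub["timestamp"])))
    return out


def write_sensor_csv(network: Mapping[str, RawSensorSeries], path) -> None:
    frames = [pd.DataFrame({"timestamp": r.data.index.strftime("%Y-%m-%dT%H:%M:%S"),
                            "site": site, "pm25_ugm3": r.data.to_numpy()})
              for site, r in sorted(network.items())]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


# --------------------------------------------------------------------------
# meteorology
# --------------------------------------------------------------------------

def read_met_csv(path) -> MeteorologySeries:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, {"timestamp", "temp_c", "rh_pct"}, path)
    ts = _parse_timestamps(df["timestamp"], path, "timestamp")
    return MeteorologySeries(pd.DataFrame(
        {"temp_c": df["temp_c"].to_numpy(), "rh_pct": df["rh_pct"].to_numpy()},
        index=pd.DatetimeIndex(ts)).sort_index())


def write_met_csv(met: MeteorologySeries, path) -> None:
    out = met.frame.copy()
    out.insert(0, "timestamp", out.index.strftime("%Y-%m-%dT%H:%M:%S"))
    out.to_csv(path, index=False, float_format="%.17g")


# --------------------------------------------------------------------------
# diffusion tubes
# --------------------------------------------------------------------------

def read_tube_csv(path) -> list[TubeDeployment]:
    """Group tube rows into deployments keyed by (location, start, end)."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, {"location", "deploy_start", "deploy_end", "tube_id", "no2_ugm3"}, path)
    df["deploy_start"] = _parse_timestamps(df["deploy_start"], path, "deploy_start")
    df["deploy_end"] = _parse_timestamps(df["deploy_end"], path, "deploy_end")
    bad = df["no2_ugm3"] <= 0
    if bad.any():
        row = int(bad.idxmax())
        raise ValueError(f"{path}: non-positive NO2 at row {row}")
    deployments = []
    for (loc, start, end), sub in df.groupby(["location", "deploy_start", "deploy_end"],
                                             sort=True):
        sub = sub.sort_values("tube_id")
        deployments.append(TubeDeployment(str(loc), start, end,
                                          tuple(sub["no2_ugm3"].astype(float))))
    return deployments


def write_tube_csv(deployments: Iterable[TubeDeployment], path) -> None:
    rows = []
    for d in deployments:
        for i, v in enumerate(d.values, start=1):
            rows.append({"location": d.location,
                         "deploy_start": d.deploy_start.strftime("%Y-%m-%dT%H:%M:%S"),
                         "deploy_end": d.deploy_end.strftime("%Y-%m-%dT%H:%M:%S"),
                         "tube_id": i, "no2_ugm3": v})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_reference_csv(path) -> pd.Series:
    """Reference-monitor monthly means: ``month`` (YYYY-MM), ``no2_ugm3``."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, {"month", "no2_ugm3"}, path)
    idx = pd.PeriodIndex(df["month"].astype(str), freq="M")
    return pd.Series(df["no2_ugm3"].to_numpy(), index=idx, name="no2_ugm3")


def read_monthly_results_csv(path) -> list[MonthlyTubeResult]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, {"location", "month", "mean_no2_ugm3", "n_tubes", "cv", "flag"}, path)
    return [MonthlyTubeResult(location=str(r.location),
                              month=pd.Period(str(r.month), freq="M"),
                              mean_no2=float(r.mean_no2_ugm3),
                              n_tubes=int(r.n_tubes), cv=float(r.cv),
                              precision_flag=bool(r.flag))
            for r in df.itertuples()]


def write_monthly_results_csv(results: Iterable[MonthlyTubeResult], path) -> None:
    rows = [{"location": r.location, "month": str(r.month),
             "mean_no2_ugm3": r.mean_no2, "n_tubes": r.n_tubes,
             "cv": r.cv, "flag": r.precision_flag} for r in results]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


# --------------------------------------------------------------------------
# validated hourly + reports
# --------------------------------------------------------------------------

def read_hourly_csv(path) -> dict[str, HourlySeries]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, {"hour_start", "site", "pm25_ugm3", "n_readings", "status"}, path)
    df["hour_start"] = _parse_timestamps(df["hour_start"], path, "hour_start")
    out = {}
    for site, sub in df.groupby("site", sort=True):
        sub = sub.sort_values("hour_start")
        frame = pd.DataFrame({"pm25": sub["pm25_ugm3"].to_numpy(),
                              "n_readings": sub["n_readings"].to_numpy(),
                              "status": sub["status"].to_numpy()},
                             index=pd.DatetimeIndex(sub["hour_start"], name="hour_start"))
        out[str(site)] = HourlySeries(str(site), frame)
    return out


def write_hourly_csv(validated: Mapping[str, HourlySeries], path) -> None:
    frames = []
    for site, h in sorted(validated.items()):
        df = h.frame
        frames.append(pd.DataFrame({
            "hour_start": df.index.strftime("%Y-%m-%dT%H:%M:%S"),
            "site": site, "pm25_ugm3": df["pm25"].to_numpy(),
            "n_readings": df["n_readings"].to_numpy(),
            "status": df["status"].to_numpy()}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def write_capture_reports_csv(reports: Iterable[CaptureReport], path) -> None:
    pd.DataFrame([r.to_dict() for r in reports]).to_csv(path, index=False)


def write_provenance(out_dir, config: object, seed: int | None = None, **extra) -> Path:
    """Write a machine-readable provenance record beside a run's outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if is_dataclass(config) and not isinstance(config, type):
        config = asdict(config)
    record = {"airqc_version": _version, "seed": seed,
              "config": _jsonable(config), **extra}
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(record, indent=2, default=str) + "\n")
    return path


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)
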