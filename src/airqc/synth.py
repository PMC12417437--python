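"""Synthetic sensor-network, meteorology, fault and tube-campaign generators.

The generators provide seeded, fully reproducible stand-ins for a campus
monitoring campaign with known ground truth:

* :func:`generate_network` — multi-site 15-minute PM2.5 series built from a
  shared regional process plus independent local processes (both AR(1)-smoothed
  lognormal-like, so concentrations stay positive and exhibit episodic peaks),
  additive diurnal/weekly cycles and Gaussian measurement noise.  A high
  regional weight reproduces the strong inter-site correlation of urban PM2.5.
* :func:`generate_meteorology` — hourly temperature with seasonal and diurnal
  cycles, and bounded relative humidity.
* :func:`inject_faults` — gap runs, stuck-sensor (static) runs and spike
  outliers, returning an exact fault mask for validation-recovery checks.
* :func:`generate_tube_study` — triplicate diffusion-tube deployments for a
  baseline and a follow-up period, with multiplicative lab noise and an
  optional step reduction at one intervention site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from airqc.series import MeteorologySeries, RawSensorSeries
from airqc.tubes import TubeDeployment

__all__ = [
    "NetworkConfig",
    "MeteorologyConfig",
    "FaultSpec",
    "TubeStudyConfig",
    "SyntheticNetwork",
    "TubeStudy",
    "calm_network_config",
    "generate_network",
    "generate_meteorology",
    "inject_faults",
    "generate_tube_study",
]


# --------------------------------------------------------------------------
# configuration types
# --------------------------------------------------------------------------

@dataclass
class NetworkConfig:
    """Parameters of the synthetic multi-site PM2.5 network.

    A site's latent signal is

        w * S(t) + (1 - w) * L_i(t) + offset_i + diurnal(t) + weekly(t)

    where ``w`` is ``regional_weight``, ``S`` is a shared regional process and
    ``L_i`` a site-specific process, both AR(1)-smoothed lognormal with mean
    ``regional_mean`` and relative standard deviation ``episodic_rel_sd``.
    Readings add Gaussian noise (``noise_sd``) and are floored at zero.
    """

    period_start: pd.Timestamp
    period_end: pd.Timestamp
    n_sites: int = 4
    cadence: str = "15min"
    regional_mean: float = 8.0
    regional_weight: float = 0.9
    site_offsets: Sequence[float] | None = None
    diurnal_amplitude: float = 3.0
    weekly_amplitude: float = 1.0
    episodic_rel_sd: float = 0.35
    ar_coeff: float = 0.98
    noise_sd: float = 0.5
    seed: int = 0
    site_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.period_start = pd.Timestamp(self.period_start)
        self.period_end = pd.Timestamp(self.period_end)
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.period_end <= self.period_start:
            raise ValueError("period_end must be after period_start")
        if not 0.0 <= self.regional_weight <= 1.0:
            raise ValueError("regional_weight must lie in [0, 1]")
        if self.noise_sd < 0 or self.episodic_rel_sd < 0:
            raise ValueError("noise_sd and episodic_rel_sd must be >= 0")
        if not 0.0 <= self.ar_coeff < 1.0:
            raise ValueError("ar_coeff must lie in [0, 1)")
        if self.regional_mean < 0:
            raise ValueError("regional_mean must be >= 0")
        if self.site_offsets is not None and len(self.site_offsets) != self.n_sites:
            raise ValueError("site_offsets must have one entry per site")
        if self.site_names is not None and len(self.site_names) != self.n_sites:
            raise ValueError("site_names must have one entry per site")

    @property
    def sites(self) -> list[str]:
        if self.site_names is not None:
            return list(self.site_names)
        return [f"S{i + 1:02d}" for i in range(self.n_sites)]

    @property
    def offsets(self) -> np.ndarray:
        if self.site_offsets is None:
            return np.zeros(self.n_sites)
        return np.asarray(self.site_offsets, dtype=float)


def calm_network_config(period_start, period_end, **overrides) -> NetworkConfig:
    """A low-volatility network preset whose clean output survives validation.

    Dispersion is dominated by the bounded diurnal cycle, so within any
    calendar month no clean value can stray beyond three (scaled) median
    absolute deviations of the monthly median; useful for clean-data identity
    checks and as an unambiguous background for fault-recovery studies.
    """
    params = dict(episodic_rel_sd=0.05, noise_sd=0.3, diurnal_amplitude=3.0,
                  weekly_amplitude=1.0)
    params.update(overrides)
    return NetworkConfig(period_start, period_end, **params)


@dataclass
class MeteorologyConfig:
    """Seasonal + diurnal temperature and AR(1) humidity parameters."""

    mean_temp_c: float = 10.0
    seasonal_amp_c: float = 7.0
    diurnal_amp_c: float = 3.0
    temp_noise_sd: float = 1.5
    rh_mean_pct: float = 75.0
    rh_noise_sd: float = 8.0
    ar_coeff: float = 0.95

    def __post_init__(self) -> None:
        if self.temp_noise_sd < 0 or self.rh_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not 0.0 <= self.ar_coeff < 1.0:
            raise ValueError("ar_coeff must lie in [0, 1)")


@dataclass
class FaultSpec:
    """Ground-truth fault injections.

    gap_runs: (site, start, duration) — readings deleted.
    static_runs: (site, start, duration, held_value) — readings overwritten.
    spike_events: (site, timestamp, magnitude) — magnitude added at one tick.
    """

    gap_runs: list[tuple] = field(default_factory=list)
    static_runs: list[tuple] = field(default_factory=list)
    spike_events: list[tuple] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not (self.gap_runs or self.static_runs or self.spike_events)


@dataclass
class TubeStudyConfig:
    """Triplicate diffusion-tube campaign with a baseline and follow-up period.

    ``monthly_truth`` maps location -> true NO2 (µg/m³); either a scalar
    (flat across months) or a mapping of calendar-month number -> truth.
    Follow-up truths at ``intervention_site`` are reduced by
    ``intervention_delta``.  Reported tube values are truth * (1 + eps) with
    eps ~ Normal(0, tube_noise_rel_sd²).
    """

    locations: Sequence[str]
    monthly_truth: Mapping[str, float | Mapping[int, float]]
    baseline_months: Sequence[tuple[int, int]] = ((2021, 4), (2021, 5), (2021, 6), (2021, 7))
    followup_months: Sequence[tuple[int, int]] = ((2023, 4), (2023, 5), (2023, 6), (2023, 7))
    intervention_site: str | None = None
    intervention_delta: float = 0.0
    tube_noise_rel_sd: float = 0.075
    n_tubes: int = 3
    deployment_days: int = 28
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tube_noise_rel_sd < 0:
            raise ValueError("tube_noise_rel_sd must be >= 0")
        if self.n_tubes < 1:
            raise ValueError("n_tubes must be >= 1")
        missing = set(self.locations) - set(self.monthly_truth)
        if missing:
            raise ValueError(f"monthly_truth missing locations: {sorted(missing)}")
        if self.intervention_site is not None and self.intervention_site not in self.locations:
            raise ValueError("intervention_site must be one of the locations")
        for loc in self.locations:
            for year, month in [*self.baseline_months, *self.followup_months]:
                if self.truth_for(loc, month, followup=(year, month) in set(self.followup_months)) <= 0:
                    raise ValueError(f"monthly truth must stay > 0 at {loc} month {month}")

    def truth_for(self, location: str, month: int, followup: bool) -> float:
        spec = self.monthly_truth[location]
        truth = float(spec[month]) if isinstance(spec, Mapping) else float(spec)
        if followup and location == self.intervention_site:
            truth -= self.intervention_delta
        return truth


@dataclass
class SyntheticNetwork:
    """Generated sensor series plus the latent (pre-noise) truth per site."""

    series: dict[str, RawSensorSeries]
    truth: pd.DataFrame = field(repr=False)
    config: NetworkConfig | None = None

    @property
    def sites(self) -> list[str]:
        return list(self.series)


@dataclass
class TubeStudy:
    """Generated deployments and the ground-truth table behind them."""

    deployments: list[TubeDeployment]
    truth: pd.DataFrame = field(repr=False)
    config: TubeStudyConfig | None = None


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------

def _ar1_unit(rng: np.random.Generator, n: int, rho: float) -> np.ndarray:
    """Stationary AR(1) path with unit marginal variance."""
    innov = rng.standard_normal(n) * math.sqrt(max(1.0 - rho * rho, 0.0))
    innov[0] = rng.standard_normal()
    return lfilter([1.0], [1.0, -rho], innov)


def _lognormal_process(rng, n, rho, mean, rel_sd) -> np.ndarray:
    """AR(1)-smoothed positive process with the given mean and relative SD."""
    z = _ar1_unit(rng, n, rho)
    if rel_sd == 0 or mean == 0:
        # still consume the draws above so seeding stays comparable
        return np.full(n, float(mean))
    sigma = math.sqrt(math.log1p(rel_sd * rel_sd))
    return mean * np.exp(sigma * z - 0.5 * sigma * sigma)


def _cycles(index: pd.DatetimeIndex, diurnal_amp: float, weekly_amp: float) -> np.ndarray:
    hour = index.hour.to_numpy() + index.minute.to_numpy() / 60.0
    # morning-peaked diurnal cycle (peak 08:00), Tuesday-peaked weekly cycle
    diurnal = diurnal_amp * np.cos(2 * np.pi * (hour - 8.0) / 24.0)
    dow = index.dayofweek.to_numpy()
    weekly = weekly_amp * np.cos(2 * np.pi * (dow - 1.0) / 7.0)
    return diurnal + weekly


def generate_network(config: NetworkConfig) -> SyntheticNetwork:
    """Generate the full multi-site 15-minute PM2.5 network.

    Returns a :class:`SyntheticNetwork` whose ``truth`` frame holds the latent
    pre-noise signal per site (not floored), alongside the noisy, floored
    readings in ``series``.  Identical configs (including seed) produce
    bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    ticks = pd.date_range(config.period_start, config.period_end,
                          freq=config.cadence, inclusive="left")
    n = len(ticks)
    if n == 0:
        raise ValueError("period too short for the requested cadence")

    shared = _lognormal_process(rng, n, config.ar_coeff,
                                config.regional_mean, config.episodic_rel_sd)
    cycles = _cycles(ticks, config.diurnal_amplitude, config.weekly_amplitude)

    w = config.regional_weight
    offsets = config.offsets
    series: dict[str, RawSensorSeries] = {}
    truth_cols: dict[str, np.ndarray] = {}
    for i, site in enumerate(config.sites):
        local = _lognormal_process(rng, n, config.ar_coeff,
                                   config.regional_mean, config.episodic_rel_sd)
        latent = w * shared + (1.0 - w) * local + offsets[i] + cycles
        noise = rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else 0.0
        values = np.maximum(latent + noise, 0.0)
        truth_cols[site] = latent
        series[site] = RawSensorSeries(site, pd.Series(values, index=ticks))

    truth = pd.DataFrame(truth_cols, index=ticks)
    truth.index.name = "timestamp"
    return SyntheticNetwork(series=series, truth=truth, config=config)


def generate_meteorology(period_start, period_end, seed: int = 0,
                         config: MeteorologyConfig | None = None) -> MeteorologySeries:
    """Hourly temperature and relative-humidity series for the period.

    Temperature = annual mean + seasonal cosine (peak mid-July) + afternoon
    diurnal cycle + AR(1) noise; RH = mean + AR(1) noise, clipped to [0, 100].
    """
    cfg = config or MeteorologyConfig()
    start, end = pd.Timestamp(period_start), pd.Timestamp(period_end)
    if end <= start:
        raise ValueError("period_end must be after period_start")
    rng = np.random.default_rng(seed)
    hours = pd.date_range(start, end, freq="h", inclusive="left")
    n = len(hours)

    doy = hours.dayofyear.to_numpy() + hours.hour.to_numpy() / 24.0
    seasonal = cfg.seasonal_amp_c * np.cos(2 * np.pi * (doy - 197.0) / 365.25)
    diurnal = cfg.diurnal_amp_c * np.cos(2 * np.pi * (hours.hour.to_numpy() - 14.0) / 24.0)
    temp = (cfg.mean_temp_c + seasonal + diurnal
            + cfg.temp_noise_sd * _ar1_unit(rng, n, cfg.ar_coeff))
    rh = np.clip(cfg.rh_mean_pct + cfg.rh_noise_sd * _ar1_unit(rng, n, cfg.ar_coeff),
                 0.0, 100.0)
    return MeteorologySeries(pd.DataFrame({"temp_c": temp, "rh_pct": rh}, index=hours))


def inject_faults(network: Mapping[str, RawSensorSeries] | SyntheticNetwork,
                  faults: FaultSpec) -> tuple[dict[str, RawSensorSeries], pd.DataFrame]:
    """Apply gap/static/spike faults and return the faulty network plus mask.

    The mask has one row per altered or deleted tick (columns: site,
    timestamp, fault in {gap, static, spike}) and is an exact ground-truth
    labelling.  A static run overlapping a gap run on the same tick is
    rejected: the ground truth there would be ambiguous.
    """
    series = network.series if isinstance(network, SyntheticNetwork) else dict(network)
    out: dict[str, pd.Series] = {s: r.data.copy() for s, r in series.items()}
    mask_rows: list[tuple[str, pd.Timestamp, str]] = []

    def _ticks_in(site: str, start, duration) -> pd.DatetimeIndex:
        start = pd.Timestamp(start)
        duration = pd.Timedelta(duration)
        if duration <= pd.Timedelta(0):
            raise ValueError("fault durations must be > 0")
        idx = series[site].data.index
        if start < idx[0] or start + duration > idx[-1] + (idx[1] - idx[0] if len(idx) > 1 else pd.Timedelta(0)):
            raise ValueError(f"fault interval outside series span for {site}")
        return idx[(idx >= start) & (idx < start + duration)]

    gap_ticks: dict[str, set] = {s: set() for s in series}
    for site, start, duration in faults.gap_runs:
        ticks = _ticks_in(site, start, duration)
        gap_ticks[site].update(ticks)
        mask_rows.extend((site, t, "gap") for t in ticks)

    for site, start, duration, held in faults.static_runs:
        ticks = _ticks_in(site, start, duration)
        clash = gap_ticks[site] & set(ticks)
        if clash:
            raise ValueError(f"static run overlaps gap run at {site} ({min(clash)})")
        out[site].loc[ticks] = float(held)
        mask_rows.extend((site, t, "static") for t in ticks)

    for site, ts, magnitude in faults.spike_events:
        ts = pd.Timestamp(ts)
        if ts not in out[site].index or ts in gap_ticks[site]:
            raise ValueError(f"spike timestamp {ts} not present in series for {site}")
        out[site].loc[ts] += float(magnitude)
        mask_rows.append((site, ts, "spike"))

    for site, ticks in gap_ticks.items():
        if ticks:
            out[site] = out[site].drop(index=sorted(ticks))

    faulty = {s: RawSensorSeries(s, v) for s, v in out.items()}
    mask = pd.DataFrame(mask_rows, columns=["site", "timestamp", "fault"])
    if len(mask):
        mask = mask.sort_values(["site", "timestamp"]).reset_index(drop=True)
    return faulty, mask


def generate_tube_study(config: TubeStudyConfig) -> TubeStudy:
    """Generate triplicate tube deployments for baseline and follow-up periods.

    Each location-month gets one 4-week deployment starting on the 1st of the
    month, with ``n_tubes`` reported values truth * (1 + eps),
    eps ~ Normal(0, tube_noise_rel_sd²).
    """
    rng = np.random.default_rng(config.seed)
    deployments: list[TubeDeployment] = []
    truth_rows = []
    for period_name, months in (("baseline", config.baseline_months),
                                ("followup", config.followup_months)):
        followup = period_name == "followup"
        for year, month in months:
            start = pd.Timestamp(year=year, month=month, day=1)
            end = start + pd.Timedelta(days=config.deployment_days)
            for loc in config.locations:
                truth = config.truth_for(loc, month, followup)
                eps = rng.normal(0.0, config.tube_noise_rel_sd, config.n_tubes)
                values = truth * (1.0 + eps)
                deployments.append(TubeDeployment(loc, start, end, tuple(values)))
                truth_rows.append({"location": loc, "period": period_name,
                                   "year": year, "month": month, "truth_no2": truth})
    truth = pd.DataFrame(truth_rows)
    return TubeStudy(deployments=deployments, truth=truth, config=config)
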