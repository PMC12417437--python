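"""Canonical synthetic study scenarios with known ground truth.

These builders pin down the study conditions used throughout the package's
verification material (tests, acceptance checks, analysis drivers): a
hospital-campus-like four-site sensor year, a fault-injection schedule whose
every corrupted tick is labelled, and a six-location diffusion-tube campaign
with a step reduction at one intervention site.  Everything is a pure
function of its seed.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from airqc.intervention import compare_periods
from airqc.qc import (REMOVED_STEP3, REMOVED_STEP4, ValidationConfig,
                      run_network)
from airqc.series import MeteorologySeries, RawSensorSeries
from airqc.synth import (FaultSpec, NetworkConfig, SyntheticNetwork,
                         TubeStudyConfig, calm_network_config,
                         generate_meteorology, generate_network,
                         generate_tube_study)
from airqc.tubes import triplicate_stats

__all__ = [
    "STUDY_START",
    "STUDY_END",
    "clean_study_year",
    "study_fault_spec",
    "fault_recovery_rates",
    "intervention_study_config",
    "intervention_recovery",
]

def _child_seeds(base_seed: int, n: int) -> list[int]:
    """Independent integer child seeds derived from one base seed."""
    ss = np.random.SeedSequence(base_seed)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n)]


#: One-year PM2.5 analysis window (September to September).
STUDY_START = pd.Timestamp("2021-09-01")
STUDY_END = pd.Timestamp("2022-09-01")

#: Diffusion-tube campaign: six roadside/background locations with flat
#: month-constant NO2 truths (µg/m³) over the matched April–July window.
TUBE_LOCATIONS = ("main_entrance", "ambulance_bay", "station", "crossing",
                  "womens_hospital", "background")
TUBE_TRUTHS: Mapping[str, float] = {"main_entrance": 34.0, "ambulance_bay": 26.0,
                                    "station": 25.0, "crossing": 24.0,
                                    "womens_hospital": 22.0, "background": 15.0}


def clean_study_year(seed: int = 0, n_sites: int = 4,
                     calm: bool = True) -> tuple[SyntheticNetwork, MeteorologySeries]:
    """A fault-free four-site study year with in-envelope meteorology.

    With ``calm=True`` the low-volatility network preset is used, whose clean
    output passes all four validation steps untouched; ``calm=False`` uses
    the default (episodic) configuration.
    """
    make = calm_network_config if calm else NetworkConfig
    cfg = make(STUDY_START, STUDY_END, n_sites=n_sites, seed=seed)
    met = generate_meteorology(STUDY_START, STUDY_END, seed=seed + 1_000_000)
    return generate_network(cfg), met


def study_fault_spec(network: SyntheticNetwork, seed: int = 0,
                     spikes_per_month: int = 5) -> FaultSpec:
    """Monthly fault schedule per site: one 24-h gap run, one 6-h hour-aligned
    static run and ``spikes_per_month`` spikes at +10x the site's monthly
    median, placed away from the gap and static windows."""
    rng = np.random.default_rng(seed)
    spec = FaultSpec()
    for site, raw in network.series.items():
        s = raw.data
        for month, sub in s.groupby(s.index.to_period("M")):
            start = month.start_time
            med = float(sub.median())
            gap_start = start + pd.Timedelta(days=9)                 # day 10
            static_start = start + pd.Timedelta(days=19, hours=12)   # day 20
            spec.gap_runs.append((site, gap_start, pd.Timedelta(hours=24)))
            spec.static_runs.append((site, static_start, pd.Timedelta(hours=6), med))
            blocked = ((sub.index >= gap_start) & (sub.index < gap_start + pd.Timedelta(hours=24))) | \
                      ((sub.index >= static_start) & (sub.index < static_start + pd.Timedelta(hours=6)))
            candidates = sub.index[~blocked]
            picks = rng.choice(len(candidates), size=spikes_per_month, replace=False)
            for t in candidates[np.sort(picks)]:
                spec.spike_events.append((site, t, 10.0 * med))
    return spec


def fault_recovery_rates(n_seeds: int = 20, base_seed: int = 0,
                         config: ValidationConfig | None = None) -> dict[str, float]:
    """Monte-Carlo fault-recovery study.

    For each seed, a clean study year is corrupted with :func:`study_fault_spec`
    and validated; returns the percentage of injected static-run hours flagged
    by Step 3 and of injected spike hours flagged by Step 4 (pooled over
    seeds and sites).
    """
    from airqc.synth import inject_faults

    static_flagged = static_total = 0
    spike_flagged = spike_total = 0
    seeds = _child_seeds(base_seed, 2 * n_seeds)
    for k in range(n_seeds):
        net, met = clean_study_year(seed=seeds[2 * k])
        faulty, mask = inject_faults(net, study_fault_spec(net, seed=seeds[2 * k + 1]))
        validated, _ = run_network(faulty, met, config, period=(STUDY_START, STUDY_END))
        for site, hourly in validated.items():
            status = hourly.frame["status"]
            m = mask[mask["site"] == site]
            static_hours = pd.DatetimeIndex(m.loc[m["fault"] == "static", "timestamp"]).floor("h").unique()
            spike_hours = pd.DatetimeIndex(m.loc[m["fault"] == "spike", "timestamp"]).floor("h").unique()
            static_total += len(static_hours)
            spike_total += len(spike_hours)
            static_flagged += int((status.reindex(static_hours) == REMOVED_STEP3).sum())
            spike_flagged += int((status.reindex(spike_hours) == REMOVED_STEP4).sum())
    return {"static_recovery_pct": 100.0 * static_flagged / static_total,
            "spike_recovery_pct": 100.0 * spike_flagged / spike_total,
            "n_static_hours": static_total, "n_spike_hours": spike_total}


def intervention_study_config(seed: int = 0, delta: float = 8.0,
                              tube_noise_rel_sd: float = 0.075) -> TubeStudyConfig:
    """Six-location tube campaign with a ``delta`` µg/m³ reduction at the
    main-entrance site in the follow-up period (four matched months)."""
    return TubeStudyConfig(locations=TUBE_LOCATIONS, monthly_truth=dict(TUBE_TRUTHS),
                           intervention_site="main_entrance",
                           intervention_delta=delta,
                           tube_noise_rel_sd=tube_noise_rel_sd, seed=seed)


def intervention_recovery(n_replicates: int = 1000, base_seed: int = 0,
                          delta: float = 8.0, alpha: float = 0.05) -> dict[str, float]:
    """Replicate the full tube-study -> monthly-means -> Welch pipeline.

    Returns the 95% CI coverage of ``delta`` and the detection rate at the
    intervention site, and the false-flag rate pooled over the null sites.
    """
    covered = detected = 0
    null_flags = null_tests = 0
    seeds = _child_seeds(base_seed, n_replicates)
    for k in range(n_replicates):
        cfg = intervention_study_config(seed=seeds[k], delta=delta)
        study = generate_tube_study(cfg)
        monthly = [triplicate_stats(d) for d in study.deployments]
        baseline = [r for r, d in zip(monthly, study.deployments)
                    if d.deploy_start.year == cfg.baseline_months[0][0]]
        followup = [r for r, d in zip(monthly, study.deployments)
                    if d.deploy_start.year == cfg.followup_months[0][0]]
        for res in compare_periods(baseline, followup, alpha=alpha):
            if res.location == cfg.intervention_site:
                covered += int(res.ci_low <= delta <= res.ci_high)
                detected += int(res.significant)
            else:
                null_tests += 1
                null_flags += int(res.significant)
    return {"ci_coverage_pct": 100.0 * covered / n_replicates,
            "detection_pct": 100.0 * detected / n_replicates,
            "null_flag_rate_pct": 100.0 * null_flags / null_tests,
            "n_replicates": n_replicates}
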