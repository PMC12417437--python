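# Methods

This note records the models, conventions and design choices behind airqc:
what each stage assumes, which parameters matter, what the synthetic
generator does and does not emulate, and the numerical details that make the
results reproducible.

## The validation pipeline

The pipeline targets data from small-form optical-particle-counter PM2.5
sensors, which are prone to gaps, stuck output, spurious spikes and
out-of-envelope operation. Raw 15-minute readings are averaged to hourly
means X_i (interval-start timestamps, timezone-naive; hour intervals are
half-open [h, h+1)). Four filters are then applied **once, in order**; a
removed hour keeps the first reason that applied, and filters never alter the
hourly value itself, only its status. Completeness is not re-evaluated after
the later steps — doing so would change what the capture report measures —
but a `reiterate_completeness` switch exists for sensitivity analysis.

**Step 1 — completeness (75% criteria).** An hour needs at least 3 of its 4
possible readings; a calendar day at least 18 such hours; a calendar month at
least 23 such days. All bounds are inclusive ("or more") and configurable
(`min_readings_per_hour`, `min_hours_per_day`, `min_days_per_month`). Hours
with no readings at all are *missing* rather than removed; both reduce
capture but are reported separately.

**Step 2 — meteorology mask.** The manufacturer operating envelope is applied
with strict bounds: keep −10 °C < t < 35 °C and RH > 35 %. The RH rule is
kept in this literal keep-low-humidity-out form as the default; since typical
OPC practice instead masks *high* humidity (hygroscopic particle growth), the
rule is configurable as `(rh_min, rh_max)` so e.g. `rh_max=85` reproduces the
more common convention. Hours with no meteorology record are retained: the
mask expresses evidence of envelope violation, and absent covariate data is
not such evidence. Retained-for-missing-met hours are counted and logged.

**Step 3 — static (stuck) data.** A window of `static_window = 5` consecutive
*retained* hourly samples (time order, gaps ignored) whose moving standard
deviation is zero — operationally, max−min ≤ 1e−12 — marks every member
removed. Overlapping zero-SD windows union, so a 7-hour stuck run is removed
in full.

**Step 4 — MAD outliers.** Per site and calendar month over the currently
valid values: X̃ = median(X_i), MAD = b · median(|X_i − X̃|) with
b = 1.4826 ≈ 1/Φ⁻¹(0.75), the constant that makes the MAD consistent with
the standard deviation under normality. Values outside X̃ ± m·MAD
(`mad_multiplier` m = 3) are removed, both tails, strict inequalities. Two
degenerate conventions: a month whose MAD is 0 (constant data) removes
nothing — a literal reading would delete every non-median value, and stuck
data is Step 3's job — and a month with no valid values is skipped. A
signed-deviation variant of the MAD (median of X_i − X̃ without the absolute
value, which is ≈ 0 and disables the filter) is available behind
`use_signed_deviation` purely for auditing; the standard absolute form is the
default and the tested behaviour.

**Capture accounting.** For an analysis period of P clock hours
(P = 8,760 for a 365-day year), the report satisfies the exact partition
valid + Σ removed-by-step + missing = P, and capture % = 100·valid/P.
Whether hours removed by the meteorology mask should count as "potential" is
a convention; we count all clock hours in the period.

## Diffusion tubes

A deployment is nominally a 4-week triplicate; durations outside 2–6 weeks
warn. It is assigned to the calendar month containing the most exposure
dates (deploy and collection dates inclusive), ties to the earlier month —
deterministic and aligned with deployment-start bookkeeping. The location's
monthly estimate is the triplicate mean; the coefficient of variation uses
the sample (n−1) SD, and a precision flag raises at cv > 0.20 (mirroring the
±20% accuracy generally expected of tubes used correctly) or when fewer than
two tubes survive. Accuracy against a co-located reference monitor is the
signed relative difference in percent; period summaries average monthly
means over a requested month set, reporting the months actually used.

## Exceedance statistics and profiles

Summary statistics are computed on validated hourly values; percentiles use
linear interpolation between order statistics (the numpy default and the
most common convention). Daily means include only days with ≥ 18 valid
hours, reusing the Step-1 day rule, and "% of days exceeding" uses a strict
`>` against the 24-h guideline over those recorded days. The WHO 2021
guideline constants ship as defaults (PM2.5: annual 5, daily 15 µg/m³; NO2:
annual 10, daily 25 µg/m³). Time-variation profiles are group means by
hour-of-day, day-of-week and calendar month; empty groups are absent, not
zero. Inter-site correlations are Pearson R on intersecting recorded daily
means (hourly correlation is a config option), requiring ≥ 3 common days.

## Intervention comparison

The unit of analysis is the monthly triplicate mean, so a location
contributes n = (number of matched calendar months) values per period;
month matching intersects the calendar months present in both campaigns.
Welch's unequal-variance t-test is the default — it reduces to the pooled
test under equal variances and is the safer choice when baseline and
follow-up spreads differ; the pooled Student form is available via
`pooled=True`. The 95% CI for the baseline−follow-up difference is
diff ± t_{1−α/2,ν}·SE with Welch–Satterthwaite ν. No multiple-testing
correction is applied across locations by default (screening reports
per-location tests); Bonferroni is available. Degenerate inputs: fewer than
2 values per group is an error; zero variance in both groups yields t = 0,
p = 1 at equal means.

Welch's test is conservative at these sample sizes: at n = 4 per group its
true size is measurably below the nominal α (the package's own replicate
studies, and an independent simulation of the identical design with scipy's
`ttest_ind`, both put it near 4%). The verification suite therefore checks
the null-site flag rate against the test's actual small-sample size rather
than against α exactly, while confirming it never exceeds α.

## The synthetic generator

`generate_network` builds each site's latent signal as
w·S(t) + (1−w)·L_i(t) + offset_i + diurnal(t) + weekly(t), where S (shared
regional) and L_i (site-local) are AR(1)-smoothed lognormal processes with
mean `regional_mean` (default 8 µg/m³) and relative SD `episodic_rel_sd`
(default 0.35, AR coefficient 0.98 per 15-min tick). This is deliberately a
statistical emulation, not a dispersion model: it reproduces the features
the pipeline must cope with — strongly correlated daily means across sites
(R ≈ 0.95–0.99 at w = 0.9), episodic multi-day peaks, positive skew — with
known ground truth. The diurnal term is a cosine peaking at 08:00 (amplitude
3 µg/m³ default, emulating morning traffic/carpark activity), the weekly
term a cosine peaking on Tuesday (amplitude 1); readings add Gaussian noise
(SD 0.5) and are floored at 0. Setting all variability parameters to zero
yields a constant series at `regional_mean`. What it does *not* emulate:
meteorology-driven sensor bias (hygroscopic growth), instrument drift,
manufacturer calibration, or real source chemistry — so passing tests show
the pipeline's filters behave as specified on data with these statistical
features, not that any particular physical scenario is reproduced.

A `calm_network_config` preset (episodic_rel_sd = 0.05, noise_sd = 0.3)
keeps dispersion dominated by the bounded diurnal cycle. For such data the
monthly 3·MAD band (≈ ±3.1·A around the median when the sinusoid dominates)
provably cannot be reached by clean values, so the preset serves the
clean-data-identity and fault-recovery studies where any removal must be
attributable to an injected fault. This margin was chosen by analysis of the
band width, not by tuning against test outcomes.

Meteorology is a seasonal + diurnal temperature cosine around a 10 °C annual
mean with AR(1) noise, and AR(1) humidity around 75% clipped to [0, 100] —
an in-envelope Midlands-like climate, so the Step-2 mask only fires on
constructed excursions. Fault injection deletes gap runs, overwrites static
runs, and adds spike magnitudes at single ticks, returning a mask that
labels exactly the altered ticks; a static run overlapping a gap is rejected
as ambiguous ground truth. Tube studies report truth·(1+ε), ε ~ N(0, 0.075²)
by default — at that noise ~95% of single tubes fall within ±15% of truth,
the middle of the ±10–20% accuracy range reported for tubes in the
literature — with a configurable step reduction at one intervention site in
the follow-up period.

## Study scenarios and problem sizes

`airqc.scenarios` pins the canonical conditions used by the verification
material: a September–September study year (8,760 potential hours), four
sites; a monthly fault schedule per site of one 24-h gap, one 6-h
hour-aligned static run and five spikes at +10× the site's monthly median
(hour alignment keeps the injected hourly ground truth exact); and a
six-location tube campaign (truths 15–34 µg/m³, flat across the four matched
April–July months) with an 8 µg/m³ reduction at the main-entrance site. The
flat monthly truths make the unpaired Welch CI exact for the design; strong
seasonal truth variation would render the unpaired comparison conservative.
Monte-Carlo sizes — 20 corrupted years for fault recovery, 1000 replicate
campaigns for CI coverage/detection, 10⁴ tube draws, 500/200 random arrays
for the brute-force oracle checks — were chosen so that binomial error is
small against the tolerances while the whole verification run stays fast.

## Known limitations

* The generator's parameters are statistical conveniences, not fitted to any
  real network; absolute exceedance rates it produces are illustrative.
* Step 2's literal RH > 35% default follows the manufacturer-envelope wording
  it implements; users wanting conventional high-RH masking must set
  `rh_max`.
* The intervention comparison is descriptive, not causal: traffic and
  meteorology covariates, trend adjustment and deweathering are out of scope.
* Monthly tube truths shared across years ignore inter-annual meteorology;
  month-matching mitigates but does not remove this in real campaigns.
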