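# Methods

This note documents the models and procedures behind `divetrace`, the
parameters that matter, the numerical choices, and what the synthetic-data
tests do and do not demonstrate about real tracking data.

## The measurement process

The target instrument is a continuous acoustic depth transmitter on a
free-swimming benthic diver, followed by a vessel with a directional
hydrophone. Each ~2 s pulse carries a depth reading quantized to the sensor
resolution (0.15 m or 0.2 m for the tag generations emulated here) and is
received with a signal strength that degrades with range and sea state.
The record therefore differs from an archival time–depth recorder in three
ways that drive the pipeline design: false detections (decoding errors
producing spurious depths), missing pulses (dropouts), and a vessel-side
position rather than an animal-side one.

## QC filtering (preprocess)

Four filters run in a fixed order — depth bounds, signal threshold, median
window, trimming — with removals attributed to the first filter that
rejects a record, so the retention report's counts always sum to
raw − retained. Cheap rejections run first.

* Depth bounds: a detection more than 0.5 m above sea level is physically
  impossible; one more than 1 m below the deepest vessel-sounder reading of
  the track is below the seafloor. Both are decoding artefacts.
* Signal threshold: per individual, from config (typically 43–65 dB). There
  is no automatic threshold selection: the field practice is to choose the
  lowest threshold that retains all surfacing events, by inspection.
* Median window: a record is removed iff its depth deviates by more than
  2 m from the median of a centred window of 10 consecutive detections
  (⌈w/2⌉−1 before, the rest after; truncated at the edges; even-length
  medians are the mean of the two central order statistics). The filter is
  a single pass over the input series — removals do not re-window, so
  re-running it on its own output may remove further points; this is
  documented rather than prevented, matching the one-pass reading of the
  procedure.
* Trimming: records within 20 min of release are dropped (post-release
  acclimation), as are records inside explicit exclusion intervals (e.g.
  around a mid-track recapture). A dive already in progress at a trim
  boundary surfaces downstream as a *truncated* dive — its submergence has
  no observed start or end crossing — and is excluded from analysis, which
  implements "dives recorded within the first 20 min are excluded" without
  inventing a boundary for them.

## Zero-offset correction

Surface episodes are maximal runs with depth < 1 m (widened to
accuracy + 0.5 m for coarse sensors) lasting ≥ 4 s. The offset at each
episode is the median of the episode's *surface plateau* — the samples
within two resolution steps of the episode minimum. The plateau restriction
matters: an episode also contains the ascent and descent tails that transit
the near-surface layer, and a plain episode median would be dragged
downward by them (by ~0.3 m at typical transit rates), manufacturing a
spurious offset on a perfectly calibrated sensor. Offsets are interpolated
linearly in time between episodes and held constant beyond the first and
last, which tracks both constant bias and slow drift.

## Dive detection

A dive is a maximal run of records deeper than 0.5 m. Boundaries are
linearly interpolated between the bracketing records, so durations are not
quantized to the pulse interval. Detection gaps longer than 60 s inside a
dive flag it but never split it: during active tracking a gap is almost
always acoustic dropout, and a surfacing is only inferred when the depth
record crosses the threshold. Dive durations derive from the boundary
timestamps (at nanosecond precision — `Timedelta.total_seconds()` truncates
to microseconds and would break the partition identity below).

## Phase segmentation

Phases are half-open `[start, end)` intervals with shared boundaries, so
phase durations always sum exactly to the dive duration.

**Core phases.** The bottom band is the deepest `bottom_frac` (default 0.2)
of the smoothed maximum depth. Descent runs from the dive start to the
first entry of the lightly smoothed profile (span `seg_window` = 15
samples) into the band; the terminal ascent from the last in-band sample to
the dive end; bottom is the remainder. A consequence of the band rule worth
stating: a symmetric V-shaped dive has a non-zero bottom phase equal to the
time its ramps spend inside the band (≈ 2·0.2·depth/rate), not zero; it is
short relative to any real bottom residence but not a single sample.
Dives with fewer than 5 records cannot be segmented and come back as a
single flagged `descent_ascent` phase.

**The S-dive phase set.** The gradual ascent — the slow mid-water phase
hypothesized to track neutral buoyancy — is identified by a vertical-rate
band on a smoothed profile. The original workflow classified these phases
by hand; this module makes the rule explicit and keeps a per-dive manual
override (`apply_phase_overrides`) so curated boundaries can reproduce a
hand classification exactly. The automatic rule:

1. *Eligibility.* A sample is eligible when the rate on a wide smooth
   (span `rate_window` = 45 samples ≈ 90 s) lies in
   `[-rate_slow, +rate_tol]` = [−0.03, +0.005] m/s, the light smooth is at
   least `clearance_min` = 1.5 m above the bottom band and ≥ 1 m below the
   surface threshold, and the sample is past the initial bottom residence.
   The rate band brackets observed gradual-ascent rates (~0.006–0.010 m/s)
   with generous headroom; both bounds are configurable because "rapid"
   versus "gradual" has no published quantitative criterion.
2. *Assembly.* Wiggles push the instantaneous rate out of band once per
   oscillation, so eligible fragments are bridged across gaps of up to
   `merge_gap_max` = 60 s that never *return to the seafloor* (within
   `seafloor_margin` = 1.2 m of the maximum dive depth). Mere re-entry into
   the 20 % bottom band does not interrupt: a gradual ascent that runs low
   over the seafloor dips its wiggle troughs into a band that is 2–4 m
   thick without ever touching bottom. The minimum-duration rule
   (`t_min` = 120 s) applies to the assembled total — an interruption
   splits one ascent into chunks — with each chunk ≥ 30 s and the longest
   ≥ 60 s so noise islands cannot qualify.
3. *Hysteresis.* Qualifying candidates extend outward under the rate and
   seafloor conditions alone (the clearance gates where a gradual ascent
   may *be*, not where its boundaries fall), then boundaries are refined
   on the light smooth, whose transition blur is ~15 s rather than ~45 s.
   Without this, gradual ascents that begin close to the seafloor — as the
   observed ones do, starting ~5.4 ± 2.5 m above it — would lose their
   onset to the clearance line.
4. *Interruptions.* A seafloor return between gradual chunks becomes a
   `secondary_descent`/`secondary_ascent` pair split at the deepest
   smoothed sample; a seafloor return after the last chunk still emits the
   pair (the returning slow chunk need not re-qualify), so the dive is
   classified interrupted either way.

If nothing qualifies, the dive keeps its core phases and classifies as U.

## Shape classification and bottom activity

`U` iff no gradual ascent; `S_interrupted` iff a secondary descent exists;
`S` otherwise; interrupted S-dives count as S in all downstream statistics.
Bottom-phase activity is the SD (n−1 denominator) of *raw* depths in the
bottom phase — raw so that the sensor resolution bounds the statistic's
floor, and the summary reports the sensor accuracy beside it because a
coarse sensor (±1.7 m) can exceed the biological signal. Outliers use an
upper-only fence `Q3 + 1.5·IQR` over the individual's U-dive SD set with
linear-interpolation quantiles (the fence depends on the quantile rule, so
it is fixed and documented); low SDs are physiologically meaningless as
outliers. Fences from fewer than 4 dives are computed but flagged
low-confidence. Bouts are maximal runs of ≥ 2 consecutive U-dives with no
other shape interleaved; per-bout SDs (n−1) of max depth (m) and duration
(min) measure stereotypy.

## Wiggle detection

Within each gradual-ascent phase (and bottom phases behind a flag), a
LOESS/LOWESS smooth with span `window_w` samples (per individual; default
30 ≈ 60 s) captures the slow trend. Robustness iterations are disabled:
wiggles are signal, and a robust fit would reject them from the trend and
distort the residual. The residual is despiked with a 5-sample (~10 s)
median filter — a wiggle is an oscillation sustained over tens of seconds,
while quantization/noise blips are 1–3 samples wide — and peaks are local
maxima of the (signed) residual with topographic prominence
≥ max(2 × resolution, 0.2 m), accepted greedily in decreasing order subject
to a minimum separation of `window_w // 2` samples. One counted peak per
oscillation: a k-period oscillation train yields k wiggles. An alternative
reading counts extrema of |residual| (two per period); the one-per-period
convention is used because a "wiggle" is one down-up event. Phases shorter
than 2·`window_w` records cannot support the smoother and return zero with
a flag.

The maximum amplitude is the 95th quantile of the *absolute* residuals of a
second, 3×-wider LOESS fit. Absolute residuals are an interpretation (a
signed-residual quantile would ignore downward excursions) and switchable
in principle; for a pure sinusoid of amplitude A the estimator returns
≈ 0.997·A. The window choice bounds the detectable period band: with
span w the smoother absorbs oscillations much longer than ~2.5·w·Δt and
the separation rule suppresses periods shorter than w·Δt/2 — which is why
the window is a per-individual parameter, matched to the animal's
oscillation pace.

## Behavioural metrics

The per-individual summary satisfies its identities exactly by
construction: submerged + surface time = total time (first dive start to
last dive end), the two proportions sum to 1, surfacing rate = dives /
hours. All means carry n−1 SDs. Mean gradual-ascent time is averaged over
*all* dives (U-dives contribute zero), the convention of the per-individual
summary table this mirrors; the per-S-dive mean is exposed separately.
Wiggle statistics: proportion of S-dives with ≥ 1 wiggle, mean wiggle count
over all S-dives, and mean maximum amplitude over the S-dives that have
wiggles.

Inter-dive distances are haversine great-circle distances (Earth radius
6371.0 km) between consecutive surfacing positions. Each gap is attributed
to the dive *enclosed* by the two surfacings — the dive whose travel it
reflects — with the alternative (preceding-dive) attribution switchable,
since the convention is not standardized. Surfacing positions come from
either the receiver GPS at the dive's last detection or the nearest 15-min
vessel log entry (≤ 7.5 min away, else missing), selected in config;
heights above the seafloor likewise use the nearest sounder reading and are
reported missing, never zero, when no reading is close enough.

The rank-sum comparison reports both U conventions and the rank-sum W,
because published W values depend on an unstated convention and group
order. Ties get midranks; the exact null distribution is used when
n₁+n₂ ≤ 12 without ties, otherwise the normal approximation with tie and
continuity corrections (delegated to `scipy.stats.mannwhitneyu`; the test
suite checks both branches against an exhaustive-enumeration oracle and a
10⁵-resample permutation oracle).

## The synthetic-data generator

`simulate_track` builds an ideal piecewise-linear depth profile (linear
descents/ascents, flat or gently wandering bottoms, sinusoidal wiggle
trains on the gradual-ascent ramp, seafloor excursions for interrupted
dives), records the ground truth *before* corruption, then
`apply_sensor_model` degrades it: Gaussian pulse noise, mid-tread
quantization to the resolution, a per-track constant bias drawn from
N(0, accuracy_bias_sd), independent dropouts, false-detection spikes of
3–8 m (either sign), and signal strengths with a configurable weak
fraction. The output depth is `quantize(depth + noise) + bias`: the sensor
quantizes what it measures, and the calibration bias rides on top.

The study-emulation sampler (`sample_study_specs`) draws dive geometry on
the observed scales: seafloor N(17.4, 3) m clipped to [10, 22]; gradual
ascents starting N(5.4, 2) m and ending N(10, 2.4) m above the seafloor
with implied rates kept within 0.001–0.03 m/s; wiggle counts uniform on
0–12 at amplitudes N(0.7, 0.25) clipped to [0.3, 1.3] m; one oscillation
period per track, U(45, 75) s, because the observed wiggles are
individually consistent in pace and the per-individual smoothing window
presupposes a per-individual timescale; surface intervals 10–120 s;
interruptions with probability 0.25 when the wiggle train leaves room
(truth labels always reflect what was actually built). Bottom and
gradual-ascent durations sit at the few-minutes scale — structure, not
absolute duration, is what the pipeline keys on — which keeps the
simulation-heavy test suite and the acceptance script at tens of seconds.
Dives whose gradual ascent would hug the seafloor or surface are nudged
into the mid-water band, since a gradual ascent is by definition a
water-column phase.

**What the generator does not emulate** — and hence what passing tests do
not show about field data: burst (non-independent) dropouts when the vessel
loses the bearing; tag depth error that correlates with range or sea state;
non-sinusoidal or irregular wiggle waveforms; behavioural states that blur
the rapid/gradual rate dichotomy; tidal advection of the surfacing
positions; and any feedback between behaviour and tracking (the GPS walk is
a labelled assumption, not a claim about travel during gradual ascents).
Recovery rates quoted by the acceptance script are therefore statements
about the pipeline's self-consistency under a faithful error model, not
field validation.

## Numerical choices and degenerate inputs

* LOWESS: `statsmodels` implementation, `it=0`, span expressed as
  fraction = window/n, `delta` interpolation enabled for phases longer
  than 500 samples.
* Quantiles: linear interpolation between order statistics, everywhere.
* Duplicate timestamps on ingest: keep the highest signal strength.
* Empty inputs: header-only logs give empty series; empty results still
  write header-only output tables; a track with zero dives yields a
  flagged all-zero summary.
* Timestamps parse to UTC; local time is presentation only.
* Seeds: every stochastic routine takes an explicit seed; identical seed
  and spec give bit-identical simulator output.

## Known limitations

* The segmentation rate band is a hard threshold; dives whose gradual
  ascent drifts near ±0.03 m/s will flicker between S and U under noise.
  The manual-override table is the escape hatch.
* The bottom band ties the bottom phase to 20 % of *maximum depth*, which
  overstates bottom time for V-shaped profiles (none observed in the
  emulated system) and for dives over steeply sloping seafloors.
* Wiggle counting assumes the oscillation period is resolvable by the
  configured window; a mis-set window silently under-counts long-period
  oscillations (absorbed into the trend) or merges short-period ones
  (separation rule).
* The replication of the source study's field numbers (dive counts, W
  statistic, distance medians) requires its deposited tracking data and
  per-individual thresholds; the acceptance script restricts itself to
  quantities computable from the published summary table and from
  synthetic ground truth.
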