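"""Ground-truthed synthetic dive tracks.

Generates detection and environment logs with the statistical structure
the analysis assumes -- 2-s acoustic pulse cadence, depths 0-25 m,
surface intervals of tens of seconds, U / S / interrupted-S dives with
sinusoidal "wiggles" superimposed on gradual ascents -- together with a
:class:`TrackTruth` holding the dive boundaries, shapes, phase intervals
and wiggle counts the pipeline should recover.  Truth is recorded from
the ideal (pre-corruption) profile.

The sensor model reproduces the acoustic-tag error budget: Gaussian
pulse noise, quantization to the sensor resolution (0.15 m or 0.2 m in
the emulated study), a per-track constant accuracy bias, pulse dropouts,
weak-signal detections, and false-detection depth spikes.

The study-emulation sampler draws dive parameters on the scales the
tracked animals showed: seafloors ~17 m, gradual ascents starting
~5.4 m and ending ~10 m above the seafloor at 0.001-0.03 m/s, wiggle
amplitudes 0.3-1.3 m, surface intervals 10-120 s.  Dive and bottom
durations are kept at the minutes scale so that simulation-heavy tests
stay cheap; the structure, not the absolute duration, is what the
pipeline keys on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PULSE_INTERVAL = 2.0  # s
DEFAULT_SITE = (-21.93, 114.12)  # lat, lon of the synthetic tracking area


@dataclass
class DiveSpec:
    """Blueprint of one simulated dive."""

    shape: str = "U"  # U | S  (S with n_interruptions > 0 -> interrupted)
    max_depth: float = 15.0  # m
    descent_rate: float = 0.12  # m/s
    ascent_rate: float = 0.12  # m/s, final ascent
    first_ascent_rate: float = 0.08  # m/s, off the bottom (S only)
    bottom_duration: float = 300.0  # s
    bottom_wander: float = 0.0  # m, sinusoidal bottom-depth amplitude
    bottom_wander_period: float = 90.0  # s
    ga_start_height: float = 5.4  # m above seafloor (S only)
    ga_span: float = 4.4  # m ascended during the gradual ascent
    ga_duration: float = 600.0  # s of gradual-ascent ramp time
    n_wiggles: int = 0
    wiggle_amplitude: float = 0.7  # m
    wiggle_period: float = 60.0  # s
    n_interruptions: int = 0
    interruption_dwell: float = 30.0  # s on the seafloor per interruption

    def __post_init__(self) -> None:
        if self.shape not in ("U", "S"):
            raise ValueError(f"unknown dive shape {self.shape!r}")
        for name in ("max_depth", "descent_rate", "ascent_rate", "ga_duration",
                     "bottom_duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def truth_shape(self) -> str:
        if self.shape == "U":
            return "U"
        return "S_interrupted" if self.n_interruptions > 0 else "S"


@dataclass
class SensorModel:
    """Acoustic depth-tag error model."""

    resolution: float = 0.15  # m, depth quantization step
    accuracy_bias_sd: float = 0.25  # m, SD of the per-track constant bias
    noise_sd: float = 0.05  # m, per-pulse Gaussian noise
    pulse_interval: float = PULSE_INTERVAL
    dropout_prob: float = 0.05  # per-pulse loss probability
    false_detection_rate: float = 0.01  # per-pulse spike probability
    false_detection_magnitude: tuple[float, float] = (3.0, 8.0)  # m
    signal_mean: float = 75.0  # dB of genuine detections
    signal_sd: float = 8.0
    weak_signal_fraction: float = 0.05  # fraction below the QC threshold
    weak_signal_range: tuple[float, float] = (20.0, 42.0)  # dB


#: Fine sensor: external tags of the emulated study (0.15 m / +-0.5 m).
FINE_SENSOR = SensorModel(resolution=0.15, accuracy_bias_sd=0.25)

#: Coarse sensor: internal tags of the emulated study (0.2 m / +-1.7 m).
COARSE_SENSOR = SensorModel(resolution=0.2, accuracy_bias_sd=0.85)

#: Ideal sensor: quantization only, no noise, bias, dropout or spikes.
NOISELESS_SENSOR = SensorModel(
    resolution=0.15, accuracy_bias_sd=0.0, noise_sd=0.0, dropout_prob=0.0,
    false_detection_rate=0.0, weak_signal_fraction=0.0,
)


@dataclass
class DiveTruth:
    """Ground truth for one simulated dive (pre-corruption)."""

    dive_index: int
    start_s: float  # 0.5-m threshold crossing, seconds from track start
    end_s: float
    shape: str  # U | S | S_interrupted
    max_depth: float
    n_wiggles: int
    wiggle_amplitude: float
    ga_duration_s: float  # total gradual-ascent ramp time (0 for U)
    phases: list[tuple[str, float, float]] = field(default_factory=list)

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class TrackTruth:
    seed: int | None
    specs: list[DiveSpec]
    dives: list[DiveTruth]


# ---------------------------------------------------------------------------
# ideal profile construction
# ---------------------------------------------------------------------------

class _Builder:
    """Accumulates piecewise-linear depth segments with wiggle overlays."""

    def __init__(self) -> None:
        self.cursor = 0.0
        self.segments: list[tuple[float, float, float, float]] = []
        self.overlays: list[tuple[float, float, float, float, float]] = []
        # overlays: (t0, t1, amplitude, period, phase_origin)

    def add(self, duration: float, z0: float, z1: float) -> tuple[float, float]:
        if duration <= 0:
            return (self.cursor, self.cursor)
        t0, t1 = self.cursor, self.cursor + duration
        self.segments.append((t0, t1, z0, z1))
        self.cursor = t1
        return (t0, t1)

    def add_overlay(self, t0: float, t1: float, amplitude: float,
                    period: float) -> None:
        self.overlays.append((t0, t1, amplitude, period, t0))

    def sample(self, t: np.ndarray) -> np.ndarray:
        depth = np.zeros_like(t)
        for t0, t1, z0, z1 in self.segments:
            mask = (t >= t0) & (t < t1)
            if mask.any():
                depth[mask] = z0 + (z1 - z0) * (t[mask] - t0) / (t1 - t0)
        for t0, t1, amp, period, origin in self.overlays:
            mask = (t >= t0) & (t < t1)
            if mask.any():
                depth[mask] += amp * np.sin(
                    2 * np.pi * (t[mask] - origin) / period
                )
        return depth


def _build_dive(builder: _Builder, spec: DiveSpec, index: int,
                rng: np.random.Generator) -> DiveTruth:
    """Append one dive to the builder; returns its truth record."""
    D = spec.max_depth
    phases: list[tuple[str, float, float]] = []

    t_desc0 = builder.cursor
    start_cross = t_desc0 + 0.5 / spec.descent_rate
    _, t_bottom0 = builder.add(D / spec.descent_rate, 0.0, D)
    phases.append(("descent", start_cross, t_bottom0))

    b0, b1 = builder.add(spec.bottom_duration, D, D)
    if spec.bottom_duration > 0:
        phases.append(("bottom", b0, b1))
        if spec.bottom_wander > 0:
            builder.add_overlay(b0, b1, spec.bottom_wander,
                                spec.bottom_wander_period)

    ga_total = 0.0
    if spec.shape == "S":
        z0 = D - spec.ga_start_height
        z1 = z0 - spec.ga_span
        fa0, fa1 = builder.add((D - z0) / spec.first_ascent_rate, D, z0)
        phases.append(("first_ascent", fa0, fa1))

        # split the gradual-ascent ramp at interruption points
        dur = spec.ga_duration
        rate = spec.ga_span / dur
        wiggle_len = spec.n_wiggles * spec.wiggle_period
        wg0_local = max(0.0, 0.5 * (dur - wiggle_len))
        cut_lo = wg0_local + wiggle_len + 20.0 if spec.n_wiggles else 60.0
        cuts = []
        if spec.n_interruptions > 0 and cut_lo < dur - 60.0:
            # interruptions must fit after the wiggle train; when they do
            # not, the dive is built (and labelled) as a plain S-dive
            cuts = sorted(
                rng.uniform(cut_lo, dur - 60.0, size=spec.n_interruptions)
            )
        local = 0.0
        for cut in cuts:
            g0, g1 = builder.add(cut - local, z0 - rate * local, z0 - rate * cut)
            phases.append(("gradual_ascent", g0, g1))
            ga_total += cut - local
            if spec.n_wiggles and local <= wg0_local < cut:
                builder.add_overlay(g0 + (wg0_local - local),
                                    g0 + (wg0_local - local) + wiggle_len,
                                    spec.wiggle_amplitude, spec.wiggle_period)
            z_here = z0 - rate * cut
            sd0, sd1 = builder.add((D - z_here) / spec.descent_rate, z_here, D)
            dw0, dw1 = builder.add(spec.interruption_dwell, D, D)
            sa0, sa1 = builder.add((D - z_here) / spec.first_ascent_rate,
                                   D, z_here)
            mid = 0.5 * (dw0 + dw1)
            phases.append(("secondary_descent", sd0, mid))
            phases.append(("secondary_ascent", mid, sa1))
            local = cut
        g0, g1 = builder.add(dur - local, z0 - rate * local, z1)
        phases.append(("gradual_ascent", g0, g1))
        ga_total += dur - local
        if spec.n_wiggles and local <= wg0_local:
            builder.add_overlay(g0 + (wg0_local - local),
                                g0 + (wg0_local - local) + wiggle_len,
                                spec.wiggle_amplitude, spec.wiggle_period)
        fin0, fin1 = builder.add(z1 / spec.ascent_rate, z1, 0.0)
    else:
        fin0, fin1 = builder.add(D / spec.ascent_rate, D, 0.0)
    end_cross = fin1 - 0.5 / spec.ascent_rate
    phases.append(("final_ascent" if spec.shape == "S" else "ascent",
                   fin0, end_cross))

    if spec.shape == "U":
        shape = "U"
    else:
        shape = "S_interrupted" if any(
            label == "secondary_descent" for label, _, _ in phases
        ) else "S"
    return DiveTruth(
        dive_index=index,
        start_s=start_cross,
        end_s=end_cross,
        shape=shape,
        max_depth=D,
        n_wiggles=spec.n_wiggles if spec.shape == "S" else 0,
        wiggle_amplitude=spec.wiggle_amplitude if spec.n_wiggles else 0.0,
        ga_duration_s=ga_total,
        phases=phases,
    )


# ---------------------------------------------------------------------------
# track simulation
# ---------------------------------------------------------------------------

def simulate_track(
    specs: list[DiveSpec],
    surface_intervals: list[float] | None = None,
    seed: int | None = None,
    start_time: str | pd.Timestamp = "2022-06-01T00:00:00Z",
    site: tuple[float, float] = DEFAULT_SITE,
    seafloor_depth: float | None = None,
    individual_id: str = "sim",
    lead_in: float = 60.0,
    lead_out: float = 60.0,
    speed_u: float = 0.03,  # m/s horizontal, U-dives and surface
    speed_s: float = 0.30,  # m/s horizontal, S-dives
) -> tuple[pd.DataFrame, pd.DataFrame, TrackTruth]:
    """Simulate one ideal (uncorrupted) track.

    Returns the detection series at 2-s pulse cadence (exact depths,
    uniformly strong signals), the 15-min vessel environment series, and
    the ground truth.  Corrupt with :func:`apply_sensor_model`.  GPS
    positions follow a correlated random walk whose speed is higher
    during S-shaped dives than U-shaped dives.  ``seafloor_depth``
    defaults to slightly below the deepest dive; a dive spec deeper than
    the stated seafloor is rejected.
    """
    rng = np.random.default_rng(seed)
    start_time = pd.Timestamp(start_time)
    if start_time.tzinfo is None:
        start_time = start_time.tz_localize("UTC")

    max_dive = max((s.max_depth for s in specs), default=0.0)
    if seafloor_depth is None:
        seafloor_depth = max_dive + 0.5 if specs else 10.0
    if specs and max_dive > seafloor_depth:
        raise ValueError(
            f"dive to {max_dive} m exceeds seafloor depth {seafloor_depth} m"
        )

    if surface_intervals is None:
        surface_intervals = [30.0] * max(0, len(specs) - 1)
    if specs and len(surface_intervals) < len(specs) - 1:
        raise ValueError("need a surface interval between each pair of dives")

    builder = _Builder()
    builder.add(lead_in, 0.0, 0.0)
    truths = []
    for k, spec in enumerate(specs):
        truths.append(_build_dive(builder, spec, k, rng))
        if k < len(specs) - 1:
            builder.add(surface_intervals[k], 0.0, 0.0)
    builder.add(lead_out, 0.0, 0.0)

    total = builder.cursor
    t = np.arange(0.0, total, PULSE_INTERVAL)
    depth = builder.sample(t)

    # correlated random walk, dive-shape-dependent speed
    speed = np.full(len(t), speed_u)
    for truth, spec in zip(truths, specs):
        if spec.shape == "S":
            speed[(t >= truth.start_s) & (t <= truth.end_s)] = speed_s
    heading = np.cumsum(rng.normal(0.0, 0.08, size=len(t)))
    step = speed * PULSE_INTERVAL
    dy = np.concatenate([[0.0], np.cumsum(step[:-1] * np.cos(heading[:-1]))])
    dx = np.concatenate([[0.0], np.cumsum(step[:-1] * np.sin(heading[:-1]))])
    lat = site[0] + dy / 111_320.0
    lon = site[1] + dx / (111_320.0 * np.cos(np.radians(site[0])))

    detections = pd.DataFrame(
        {
            "timestamp": start_time + pd.to_timedelta(t, unit="s"),
            "depth": depth,
            "signal_strength": np.full(len(t), 90.0),
            "latitude": lat,
            "longitude": lon,
            "individual_id": individual_id,
        }
    )

    env_t = np.arange(0.0, total + 900.0, 900.0)
    idx = np.minimum((env_t / PULSE_INTERVAL).astype(int), len(t) - 1)
    tide_phase = rng.uniform(0, 2 * np.pi)
    tide = 1.5 + 0.8 * np.sin(2 * np.pi * env_t / (12.42 * 3600) + tide_phase)
    dtide = np.gradient(tide, env_t) if len(env_t) > 1 else np.zeros(1)
    environment = pd.DataFrame(
        {
            "timestamp": start_time + pd.to_timedelta(env_t, unit="s"),
            "sounder_depth": seafloor_depth + rng.uniform(0.2, 0.8, len(env_t)),
            "water_temp": 26.0 + rng.normal(0.0, 0.2, len(env_t)),
            "tide_height": tide,
            "flow_direction": np.where(dtide >= 0, "rising", "falling"),
            "latitude": lat[idx],
            "longitude": lon[idx],
        }
    )

    truth = TrackTruth(seed=seed, specs=list(specs), dives=truths)
    return detections, environment, truth


def apply_sensor_model(
    series: pd.DataFrame, sensor: SensorModel, seed: int | None = None
) -> pd.DataFrame:
    """Corrupt an ideal detection series with the tag error model.

    Depth becomes ``quantize(depth + noise) + bias`` with mid-tread
    rounding to the sensor resolution and a per-track constant bias drawn
    from ``N(0, accuracy_bias_sd)``; pulses drop out independently; false
    detections appear as multi-metre depth spikes; signal strengths are
    drawn so that ``weak_signal_fraction`` of them falls in the
    sub-threshold band.  Timestamps of injected spikes are stored in
    ``out.attrs["spike_times"]`` so corruption-recovery tests can audit
    the QC filters.
    """
    rng = np.random.default_rng(seed)
    out = series.copy()
    depth = out["depth"].to_numpy(dtype=float)
    n = len(depth)

    bias = rng.normal(0.0, sensor.accuracy_bias_sd) if sensor.accuracy_bias_sd else 0.0
    noise = rng.normal(0.0, sensor.noise_sd, n) if sensor.noise_sd else 0.0
    depth = np.round((depth + noise) / sensor.resolution) * sensor.resolution + bias

    keep = rng.random(n) >= sensor.dropout_prob
    out = out.loc[keep].reset_index(drop=True)
    depth = depth[keep]

    m = len(depth)
    spikes = rng.random(m) < sensor.false_detection_rate
    lo, hi = sensor.false_detection_magnitude
    magnitude = rng.uniform(lo, hi, size=int(spikes.sum()))
    sign = rng.choice([-1.0, 1.0], size=int(spikes.sum()))
    depth[spikes] = depth[spikes] + sign * magnitude
    out["depth"] = depth

    signal = rng.normal(sensor.signal_mean, sensor.signal_sd, m)
    weak = rng.random(m) < sensor.weak_signal_fraction
    signal[weak] = rng.uniform(*sensor.weak_signal_range, size=int(weak.sum()))
    out["signal_strength"] = np.clip(signal, 0.0, None)

    out.attrs["spike_times"] = out.loc[spikes, "timestamp"].tolist()
    out.attrs["bias"] = float(bias)
    return out


# ---------------------------------------------------------------------------
# study-emulation sampler
# ---------------------------------------------------------------------------

def sample_study_specs(
    rng: np.random.Generator,
    n_dives: int,
    seafloor_depth: float | None = None,
    p_s: float = 0.5,
    p_interrupt: tuple[float, float] = (0.2, 0.05),  # P(1), P(2) interruptions
) -> tuple[list[DiveSpec], list[float], float]:
    """Draw study-scale dive specs for one track.

    Returns (specs, surface_intervals, seafloor_depth).  Geometry follows
    the emulated study: seafloor ~N(17.4, 3) m, gradual ascents starting
    ~5.4 m and ending ~10 m above the seafloor, implied rates within
    0.001-0.03 m/s, wiggle counts 0-12 at amplitudes drawn from
    N(0.7, 0.25) clipped to [0.3, 1.3] m, surface intervals 10-120 s.
    Dives whose gradual ascent would hug the seafloor or surface are
    nudged into the physically sensible mid-water band (a gradual ascent
    is, by definition, a water-column phase).  Bottom durations are kept
    at a few minutes so simulation suites stay fast.
    """
    if seafloor_depth is None:
        seafloor_depth = float(np.clip(rng.normal(17.4, 3.0), 10.0, 22.0))
    D_floor = seafloor_depth
    # wiggles are individually consistent in pace, so the oscillation
    # period is a per-track trait rather than a per-dive draw
    track_period = rng.uniform(45.0, 75.0)
    specs = []
    for _ in range(n_dives):
        D = float(np.clip(D_floor - abs(rng.normal(0.0, 0.3)), 5.0, D_floor))
        descent_rate = rng.uniform(0.08, 0.18)
        ascent_rate = rng.uniform(0.08, 0.15)
        if rng.random() < p_s:
            end_h = float(np.clip(rng.normal(10.0, 2.4), 0.2 * D + 3.5, D - 3.0))
            start_h = float(np.clip(rng.normal(5.4, 2.0), 2.0, end_h - 1.5))
            span = end_h - start_h
            k = int(rng.integers(0, 13))
            amp = float(np.clip(rng.normal(0.7, 0.25), 0.3, 1.3))
            dur = float(np.clip(rng.normal(600.0, 200.0), 300.0, 1200.0))
            dur = max(
                dur,
                span / 0.025,
                150.0 * span / max(end_h - 0.2 * D - 1.5, 0.5) + 60.0,
                k * 45.0 + 60.0,
            )
            period = float(min(track_period, 0.9 * dur / k)) if k else track_period
            u = rng.random()
            n_int = 2 if u < p_interrupt[1] else (1 if u < sum(p_interrupt) else 0)
            specs.append(
                DiveSpec(
                    shape="S",
                    max_depth=D,
                    descent_rate=descent_rate,
                    ascent_rate=ascent_rate,
                    first_ascent_rate=rng.uniform(0.06, 0.12),
                    bottom_duration=rng.uniform(30.0, 180.0),
                    ga_start_height=start_h,
                    ga_span=span,
                    ga_duration=dur,
                    n_wiggles=k,
                    wiggle_amplitude=amp,
                    wiggle_period=period,
                    n_interruptions=n_int,
                    interruption_dwell=rng.uniform(15.0, 45.0),
                )
            )
        else:
            active = rng.random() < 0.1
            specs.append(
                DiveSpec(
                    shape="U",
                    max_depth=D,
                    descent_rate=descent_rate,
                    ascent_rate=ascent_rate,
                    bottom_duration=rng.uniform(120.0, 480.0),
                    bottom_wander=(rng.uniform(0.5, 1.2) if active
                                   else rng.uniform(0.0, 0.2)),
                )
            )
    intervals = list(np.clip(rng.lognormal(np.log(30.0), 0.5, max(0, n_dives - 1)),
                             10.0, 120.0))
    return specs, intervals, seafloor_depth


def simulate_study_track(
    seed: int,
    n_dives: int = 4,
    sensor: SensorModel | None = FINE_SENSOR,
    individual_id: str = "sim",
) -> tuple[pd.DataFrame, pd.DataFrame, TrackTruth]:
    """Study-emulation preset: sample specs, simulate, optionally corrupt.

    ``sensor=None`` returns the ideal series; the default applies the
    fine (0.15 m) sensor model.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    specs, intervals, seafloor = sample_study_specs(rng, n_dives)
    sub_seed = int(rng.integers(0, 2**31 - 1))
    detections, environment, truth = simulate_track(
        specs, intervals, seed=sub_seed, seafloor_depth=seafloor,
        individual_id=individual_id,
    )
    if sensor is not None:
        detections = apply_sensor_model(
            detections, sensor, seed=int(rng.integers(0, 2**31 - 1))
        )
    return detections, environment, truth
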