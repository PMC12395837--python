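"""Zero-offset correction, dive detection, and phase segmentation.

A dive is a maximal excursion of the (zero-offset-corrected) depth record
beyond a 0.5 m surface threshold, bounded by surfacing events.  Each dive
is decomposed into labelled phases:

* U-shaped dives: rapid ``descent`` to maximum depth, extended ``bottom``
  residence, rapid terminal ``ascent``.
* S-shaped dives additionally contain a slow, prolonged ``gradual_ascent``
  in mid-water, bracketed by a rapid ``first_ascent`` off the bottom and a
  rapid ``final_ascent`` to the surface.  "Interrupted" S-dives return to
  the seafloor mid-gradual-ascent and back (``secondary_descent`` +
  ``secondary_ascent``).

The bottom phase is identified by residence in a depth band near the
maximum dive depth; the gradual ascent by a vertical-rate band on a
smoothed profile (slow ascent hypothesized to track neutral buoyancy),
held clear of both the bottom band and the surface.  The rate-band rule
algorithmizes what field workflows commonly do by eye, and a per-dive
manual-override table lets curated phase boundaries replace the automatic
ones.

Phase intervals are half-open ``[start, end)`` with shared boundaries, so
phase durations partition the dive duration exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .wiggle_detection import smooth_profile

logger = logging.getLogger(__name__)


def _td_seconds(delta: pd.Timedelta) -> float:
    """Timedelta to float seconds at nanosecond precision.

    ``Timedelta.total_seconds`` truncates to microseconds, which breaks
    the exact phase-partition identity; the nanosecond value does not.
    """
    return delta.value / 1e9

#: Depth threshold (m) separating surface from submergence.
DIVE_THRESHOLD = 0.5

#: Acoustic dropout gap (s) inside a dive above which the dive is flagged.
GAP_FLAG_SECONDS = 60.0

PHASE_LABELS = (
    "descent",
    "bottom",
    "first_ascent",
    "gradual_ascent",
    "secondary_descent",
    "secondary_ascent",
    "final_ascent",
    "ascent",
    "descent_ascent",  # degenerate dives too short to segment
)


@dataclass
class SegmentationParams:
    """Tunable thresholds of phase segmentation.

    The bottom band is the deepest ``bottom_frac`` of the dive's (smoothed)
    maximum depth.  A gradual ascent must hold a vertical rate between
    ``rate_slow`` m/s ascending and ``rate_tol`` m/s descending for at
    least ``t_min`` s, at least ``clearance_min`` m above the bottom band
    and ``surface_clearance`` m below the surface threshold; once such a
    core interval is found its boundaries extend outward while the rate
    stays in band and the depth stays out of the bottom band (hysteresis,
    so that gradual ascents beginning close to the seafloor keep their true
    onset).  ``seg_window``/``rate_window`` are smoothing spans in samples
    for the band test and the rate estimate; the rate span is wide so that
    wiggles do not fragment the gradual ascent.
    """

    surface_threshold: float = DIVE_THRESHOLD
    bottom_frac: float = 0.2
    clearance_min: float = 1.5  # m above the bottom band
    surface_clearance: float = 1.0  # m below the surface threshold
    rate_slow: float = 0.03  # m/s, fastest "gradual" ascent rate
    rate_tol: float = 0.005  # m/s, tolerated slow descent
    t_min: float = 120.0  # s, minimum gradual-ascent core duration
    seg_window: int = 15  # samples, band-test smoothing span
    rate_window: int = 45  # samples, rate-estimate smoothing span
    merge_gap_max: float = 60.0  # s, rate-violating gap bridged within an ascent
    seafloor_margin: float = 1.2  # m; within this of max depth = seafloor return


@dataclass
class Dive:
    """One submergence event."""

    dive_id: int
    start: pd.Timestamp
    end: pd.Timestamp
    duration: float  # s
    max_depth: float  # m
    start_idx: int  # first record of the dive in the cleaned series
    end_idx: int  # last record (inclusive)
    post_dive_surface_interval: float | None = None  # s; None for last dive
    truncated_start: bool = False
    truncated_end: bool = False
    has_gaps: bool = False


@dataclass
class DivePhase:
    """Labelled contiguous segment of a dive; [start, end) half-open."""

    dive_id: int
    label: str
    start: pd.Timestamp
    end: pd.Timestamp
    start_depth: float
    end_depth: float
    mean_depth: float
    vertical_rate: float  # m/s, signed; negative = ascending
    flagged: bool = False

    @property
    def duration(self) -> float:
        return _td_seconds(self.end - self.start)


# ---------------------------------------------------------------------------
# zero-offset correction
# ---------------------------------------------------------------------------

def zero_offset_correct(
    series: pd.DataFrame,
    surface_depth_limit: float = 1.0,
    min_duration: float = 4.0,
    resolution: float = 0.15,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Remove pressure-sensor offset using near-surface episodes.

    Surface episodes are maximal runs with ``depth < surface_depth_limit``
    sustained for at least ``min_duration`` s.  The offset during each
    episode is the median depth of the episode's surface plateau -- the
    samples within two resolution steps of the episode minimum -- so the
    ascent/descent tails that transit the near-surface layer cannot drag
    the offset downward in the water column.  Offsets are linearly
    interpolated in time between episodes (held constant beyond the
    first/last) and subtracted from the whole record.  With a well-behaved
    sensor the corrected surface medians sit within one resolution step of
    zero.

    Returns the corrected series and the per-record offset applied.
    """
    n = len(series)
    if n == 0:
        return series.copy(), np.zeros(0)
    t = (
        series["timestamp"] - series["timestamp"].iloc[0]
    ).dt.total_seconds().to_numpy()
    depth = series["depth"].to_numpy(dtype=float)

    near = depth < surface_depth_limit
    episodes = []  # (t_mid, median_depth)
    i = 0
    while i < n:
        if not near[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and near[j + 1]:
            j += 1
        if t[j] - t[i] >= min_duration - 1e-9:
            window = depth[i : j + 1]
            plateau = window[window <= window.min() + 2.0 * resolution]
            episodes.append((0.5 * (t[i] + t[j]), float(np.median(plateau))))
        i = j + 1

    if not episodes:
        logger.warning("no surface episodes found; zero-offset correction skipped")
        out = series.copy()
        return out, np.zeros(n)

    ep_t = np.array([e[0] for e in episodes])
    ep_off = np.array([e[1] for e in episodes])
    offsets = np.interp(t, ep_t, ep_off)
    out = series.copy()
    out["depth"] = depth - offsets
    logger.info(
        "zero-offset correction: %d surface episodes, offsets %.3f..%.3f m",
        len(episodes), ep_off.min(), ep_off.max(),
    )
    return out, offsets


# ---------------------------------------------------------------------------
# dive detection
# ---------------------------------------------------------------------------

def detect_dives(
    series: pd.DataFrame,
    threshold: float = DIVE_THRESHOLD,
    gap_flag_seconds: float = GAP_FLAG_SECONDS,
) -> list[Dive]:
    """Identify dives as maximal runs of records deeper than ``threshold``.

    Start and end instants are placed at the threshold crossings, linearly
    interpolated between the bracketing records; runs touching the series
    edge (no bracketing surface record) are flagged truncated.  Detection
    gaps longer than ``gap_flag_seconds`` inside a dive flag the dive but
    do not split it -- acoustic dropout is common in active tracking and a
    gap is only a surfacing if the depth record says so.
    """
    n = len(series)
    if n == 0:
        return []
    ts = series["timestamp"].reset_index(drop=True)
    depth = series["depth"].to_numpy(dtype=float)
    t = (ts - ts.iloc[0]).dt.total_seconds().to_numpy()
    sub = depth > threshold

    dives: list[Dive] = []
    i = 0
    while i < n:
        if not sub[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and sub[j + 1]:
            j += 1
        # interpolated start crossing
        if i > 0:
            frac = (threshold - depth[i - 1]) / (depth[i] - depth[i - 1])
            t_start = t[i - 1] + frac * (t[i] - t[i - 1])
            trunc_start = False
        else:
            t_start = t[i]
            trunc_start = True
        if j < n - 1:
            frac = (depth[j] - threshold) / (depth[j] - depth[j + 1])
            t_end = t[j] + frac * (t[j + 1] - t[j])
            trunc_end = False
        else:
            t_end = t[j]
            trunc_end = True
        gaps = np.diff(t[i : j + 1])
        # boundaries live on the timestamp axis; duration derives from them
        # so that phase partitions reproduce it exactly
        start_ts = ts.iloc[0] + pd.Timedelta(seconds=t_start)
        end_ts = ts.iloc[0] + pd.Timedelta(seconds=t_end)
        dives.append(
            Dive(
                dive_id=len(dives),
                start=start_ts,
                end=end_ts,
                duration=_td_seconds(end_ts - start_ts),
                max_depth=float(depth[i : j + 1].max()),
                start_idx=i,
                end_idx=j,
                truncated_start=trunc_start,
                truncated_end=trunc_end,
                has_gaps=bool(len(gaps) and gaps.max() > gap_flag_seconds),
            )
        )
        i = j + 1

    for a, b in zip(dives, dives[1:]):
        a.post_dive_surface_interval = (b.start - a.end).total_seconds()
    return dives


def drop_truncated_dives(dives: list[Dive]) -> list[Dive]:
    """Drop dives whose submergence began or ended outside the record.

    A dive already in progress at the first retained record (e.g. one that
    started inside the post-release acclimation window or an exclusion
    interval) cannot be characterised and is excluded, mirroring the
    trimming rule applied to the detection record itself.
    """
    kept = [d for d in dives if not (d.truncated_start or d.truncated_end)]
    for new_id, d in enumerate(kept):
        d.dive_id = new_id
    if kept:
        kept[-1].post_dive_surface_interval = None
    return kept


# ---------------------------------------------------------------------------
# phase segmentation
# ---------------------------------------------------------------------------

def _dive_arrays(dive: Dive, series: pd.DataFrame):
    ts0 = series["timestamp"].iloc[0]
    t_all = (series["timestamp"] - ts0).dt.total_seconds().to_numpy()
    d_all = series["depth"].to_numpy(dtype=float)
    sl = slice(dive.start_idx, dive.end_idx + 1)
    return ts0, t_all[sl], d_all[sl]


def _make_phase(
    dive: Dive,
    label: str,
    a: float,
    b: float,
    t: np.ndarray,
    d: np.ndarray,
    ts0: pd.Timestamp,
    flagged: bool = False,
) -> DivePhase:
    """Phase over seconds-interval [a, b) with stats from the raw samples."""
    start_depth = float(np.interp(a, t, d))
    end_depth = float(np.interp(b, t, d))
    mask = (t >= a) & (t < b)
    if mask.any():
        mean_depth = float(d[mask].mean())
    else:
        mean_depth = 0.5 * (start_depth + end_depth)
    duration = b - a
    rate = (end_depth - start_depth) / duration if duration > 0 else 0.0
    return DivePhase(
        dive_id=dive.dive_id,
        label=label,
        start=ts0 + pd.Timedelta(seconds=a),
        end=ts0 + pd.Timedelta(seconds=b),
        start_depth=start_depth,
        end_depth=end_depth,
        mean_depth=mean_depth,
        vertical_rate=rate,
        flagged=flagged,
    )


def _snap_to_dive(phases: list[DivePhase], dive: Dive) -> list[DivePhase]:
    """Pin the outer boundaries to the dive's exact timestamps.

    Interior boundaries are shared between adjacent phases, so with exact
    endpoints the phase durations telescope to the dive duration without
    float round-trip error.
    """
    if phases:
        phases[0].start = dive.start
        phases[-1].end = dive.end
    return phases


def segment_core_phases(
    dive: Dive,
    series: pd.DataFrame,
    params: SegmentationParams | None = None,
) -> list[DivePhase]:
    """Split a dive into descent / bottom / ascent.

    The bottom band is the deepest ``bottom_frac`` fraction of the smoothed
    maximum depth.  Descent runs from the dive start to the first entry of
    the smoothed profile into the band; the terminal ascent from the last
    band sample to the dive end; bottom is the remainder (duration ~0 when
    at most one sample sits in the band, e.g. a symmetric V-dive).

    Dives with fewer than 5 records cannot be segmented and come back as a
    single flagged ``descent_ascent`` phase.
    """
    params = params or SegmentationParams()
    ts0, t, d = _dive_arrays(dive, series)
    a0 = (dive.start - ts0).total_seconds()
    b0 = (dive.end - ts0).total_seconds()
    if len(t) < 5:
        return _snap_to_dive(
            [_make_phase(dive, "descent_ascent", a0, b0, t, d, ts0, flagged=True)],
            dive,
        )

    smooth = smooth_profile(t, d, params.seg_window)
    band_top = (1.0 - params.bottom_frac) * smooth.max()
    in_band = smooth >= band_top
    first_entry = int(np.argmax(in_band))
    last_in = len(t) - 1 - int(np.argmax(in_band[::-1]))

    bounds = [a0, t[first_entry], t[last_in], b0]
    labels = ["descent", "bottom", "ascent"]
    phases = []
    for lab, (a, b) in zip(labels, zip(bounds, bounds[1:])):
        a, b = max(a, a0), min(b, b0)
        if b < a:
            b = a
        phases.append(_make_phase(dive, lab, a, b, t, d, ts0))
    return _snap_to_dive(phases, dive)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (i0, i1) index runs of True."""
    runs = []
    i = 0
    n = len(mask)
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and mask[j + 1]:
            j += 1
        runs.append((i, j))
        i = j + 1
    return runs


def segment_s_phases(
    dive: Dive,
    series: pd.DataFrame,
    params: SegmentationParams | None = None,
) -> list[DivePhase]:
    """Refine core phases with the S-dive phase set, if one qualifies.

    After the initial bottom residence, a candidate gradual-ascent core is
    a maximal interval in which the smoothed depth stays at least
    ``clearance_min`` m above the bottom band and ``surface_clearance`` m
    below the surface threshold, the smoothed vertical rate lies within
    ``[-rate_slow, +rate_tol]``, and the (assembled) duration is at least
    ``t_min`` s.  Wiggles push the instantaneous rate out of band
    periodically and can dip a low-running gradual ascent into the bottom
    band, so fragments are bridged across short gaps and candidate
    boundaries extend outward (hysteresis) under the rate condition
    alone.  Only a *seafloor return* -- the smoothed depth coming back
    within ``seafloor_margin`` of the maximum dive depth -- interrupts
    the phase; it is emitted as a ``secondary_descent`` /
    ``secondary_ascent`` pair and marks the dive interrupted.  If no
    interval qualifies the core phases come back unchanged.
    """
    params = params or SegmentationParams()
    core = segment_core_phases(dive, series, params)
    if len(core) == 1:  # degenerate dive
        return core

    ts0, t, d = _dive_arrays(dive, series)
    n = len(t)
    a0 = (dive.start - ts0).total_seconds()
    b0 = (dive.end - ts0).total_seconds()

    smooth = smooth_profile(t, d, params.seg_window)
    band_top = (1.0 - params.bottom_frac) * smooth.max()
    in_band = smooth >= band_top
    seafloor = smooth >= smooth.max() - params.seafloor_margin
    first_entry = int(np.argmax(in_band))
    if not in_band.any():
        return core

    # first exit after the initial bottom residence
    after = np.nonzero(~in_band[first_entry:])[0]
    if len(after) == 0:
        return core
    first_exit = first_entry + int(after[0])

    smooth_wide = smooth_profile(t, d, params.rate_window)
    rate = np.gradient(smooth_wide, t)
    rate_ok = (rate >= -params.rate_slow) & (rate <= params.rate_tol)
    above_surface = smooth >= params.surface_threshold + params.surface_clearance
    clear = (smooth <= band_top - params.clearance_min) & above_surface
    elig = rate_ok & clear & ~in_band
    elig[:first_exit] = False

    def bridged(mask: np.ndarray, max_gap: float) -> list[tuple[int, int]]:
        """Runs of ``mask``, closing gaps up to ``max_gap`` seconds that
        never return to the seafloor."""
        out: list[tuple[int, int]] = []
        for i, j in _runs(mask):
            if (
                out
                and not seafloor[out[-1][1] + 1 : i].any()
                and t[i] - t[out[-1][1]] <= max_gap
            ):
                out[-1] = (out[-1][0], j)
            else:
                out.append((i, j))
        return out

    # an interruption splits one gradual ascent into chunks, so the
    # minimum-duration rule applies to their total; each chunk must still
    # be long enough not to be a noise island
    candidates = [
        (i, j)
        for i, j in bridged(elig, params.merge_gap_max)
        if t[j] - t[i] >= 30.0
    ]
    total = sum(t[j] - t[i] for i, j in candidates)
    longest = max((t[j] - t[i] for i, j in candidates), default=0.0)
    if total < params.t_min or longest < 60.0:
        return core

    def expand(intervals, runs):
        out: list[tuple[int, int]] = []
        for i, j in intervals:
            for r0, r1 in runs:
                if r0 <= j and i <= r1:  # overlapping run
                    i, j = min(i, r0), max(j, r1)
            j = min(j, n - 2)
            if out and i <= out[-1][1] + 1:
                out[-1] = (out[-1][0], max(out[-1][1], j))
            else:
                out.append((i, j))
        return out

    # hysteresis: expand each candidate through the bridged in-band-rate
    # runs it overlaps; the clearance condition gates where a gradual
    # ascent may *be*, not where its boundaries fall
    extend_ok = rate_ok & ~seafloor & above_surface
    extend_ok[: first_entry + 1] = False
    merged = expand(candidates, bridged(extend_ok, params.merge_gap_max))

    # refine boundaries on the lightly smoothed profile: the wide rate
    # estimate blurs the fast/slow transition by about half its span
    rate_fine = np.gradient(smooth, t)
    fine_ok = (
        (rate_fine >= -params.rate_slow)
        & (rate_fine <= params.rate_tol)
        & ~seafloor
        & above_surface
    )
    fine_ok[: first_entry + 1] = False
    merged = expand(merged, bridged(fine_ok, 0.75 * params.merge_gap_max))

    # gaps between candidate intervals that never return to the seafloor
    # are mid-water stalls: the gradual ascent continues through them
    joined: list[tuple[int, int]] = []
    for run in merged:
        if joined and not seafloor[joined[-1][1] + 1 : run[0]].any():
            joined[-1] = (joined[-1][0], run[1])
        else:
            joined.append(run)
    merged = joined

    bounds: list[tuple[str, float, float]] = []
    bounds.append(("descent", a0, t[first_entry]))
    g0_start = t[merged[0][0]]
    bottom_end = min(t[first_exit], g0_start)
    if bottom_end > t[first_entry]:
        bounds.append(("bottom", t[first_entry], bottom_end))
    if g0_start > bottom_end:
        bounds.append(("first_ascent", bottom_end, g0_start))
    for k, (i, j) in enumerate(merged):
        g_end = t[j + 1] if j + 1 <= n - 1 else b0
        bounds.append(("gradual_ascent", t[i], g_end))
        if k + 1 < len(merged):
            ni = merged[k + 1][0]
            peak = j + 1 + int(np.argmax(smooth[j + 1 : ni]))
            bounds.append(("secondary_descent", g_end, t[peak]))
            bounds.append(("secondary_ascent", t[peak], t[ni]))

    # any further seafloor return after the last gradual interval is an
    # interruption whose returning slow chunk did not qualify on its own:
    # still emit the secondary pair so the dive is marked interrupted
    cursor = merged[-1][1] + 1
    for r0, r1 in _runs(seafloor.copy()):
        if r0 <= cursor:
            continue
        peak = r0 + int(np.argmax(smooth[r0 : r1 + 1]))
        bounds.append(("secondary_descent", t[cursor], t[peak]))
        exit_idx = min(r1 + 1, n - 2)
        if exit_idx > peak:
            bounds.append(("secondary_ascent", t[peak], t[exit_idx]))
            cursor = exit_idx
        else:
            cursor = peak
    bounds.append(("final_ascent", t[cursor], b0))

    phases = []
    for lab, a, b in bounds:
        a, b = max(a, a0), min(b, b0)
        if b <= a:
            continue
        phases.append(_make_phase(dive, lab, a, b, t, d, ts0))
    return _snap_to_dive(phases, dive)


def segment_dive(
    dive: Dive,
    series: pd.DataFrame,
    params: SegmentationParams | None = None,
) -> list[DivePhase]:
    """Full segmentation: core phases refined with the S-dive phase set."""
    return segment_s_phases(dive, series, params)


def apply_phase_overrides(
    dive: Dive,
    series: pd.DataFrame,
    overrides: list[tuple[str, pd.Timestamp, pd.Timestamp]],
) -> list[DivePhase]:
    """Replace automatic phases of one dive with curated boundaries.

    ``overrides`` is an ordered list of ``(label, start, end)``; intervals
    must tile ``[dive.start, dive.end)`` contiguously.  This is the escape
    hatch for reproducing manually classified phase sets exactly.
    """
    ts0, t, d = _dive_arrays(dive, series)
    phases = []
    prev_end = None
    for label, start, end in overrides:
        if label not in PHASE_LABELS:
            raise ValueError(f"unknown phase label {label!r}")
        if prev_end is not None and start != prev_end:
            raise ValueError("override phases must be contiguous")
        a = (start - ts0).total_seconds()
        b = (end - ts0).total_seconds()
        phases.append(_make_phase(dive, label, a, b, t, d, ts0))
        prev_end = end
    return phases
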