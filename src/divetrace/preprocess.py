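"""Quality-control filters for actively tracked detection logs.

Acoustic depth telemetry collected by following an animal from a vessel is
contaminated by three kinds of artefact: physically impossible depths
(readings above sea level, or below the seafloor recorded by the vessel
sounder), weak-signal false detections, and isolated depth spikes.  This
module applies the corresponding filters in a fixed order -- depth bounds,
signal strength, moving-window median, acclimation/exclusion trimming --
and accounts for every removed record in a :class:`RetentionReport`.

All filters operate on a time-ordered detection ``DataFrame`` (columns
``timestamp``, ``depth``, ``signal_strength``, optionally positions) and
preserve the order and field values of retained records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Maximum height above sea level (m) a detection may report before it is
#: discarded as a surface artefact (depth is positive down, so the cut is
#: depth < -SURFACE_ARTIFACT_LIMIT).
SURFACE_ARTIFACT_LIMIT = 0.5

#: Margin (m) beyond the deepest vessel-sounder reading past which a
#: detection is discarded as a depth overrun.
SOUNDER_OVERRUN_MARGIN = 1.0

#: Default moving-window length (detections) of the median spike filter.
MEDIAN_WINDOW = 10

#: Default maximum deviation (m) from the window median before removal.
MEDIAN_MAX_DEVIATION = 2.0

#: Post-release acclimation period excluded from analysis.
ACCLIMATION_PERIOD = pd.Timedelta(minutes=20)


@dataclass
class RetentionReport:
    """Per-filter accounting of removed detections.

    ``removed`` maps a filter name to the number of records that filter
    removed; counts are attributed to the first filter that rejected a
    record, so they always sum to ``raw_count - retained_count``.
    """

    raw_count: int
    retained_count: int
    removed: dict[str, int] = field(default_factory=dict)

    @property
    def total_removed(self) -> int:
        return sum(self.removed.values())

    @property
    def fraction_removed(self) -> float:
        if self.raw_count == 0:
            return 0.0
        return self.total_removed / self.raw_count

    def merge(self, other: "RetentionReport") -> "RetentionReport":
        """Chain this report with one computed on this report's output."""
        removed = dict(self.removed)
        for key, n in other.removed.items():
            removed[key] = removed.get(key, 0) + n
        return RetentionReport(self.raw_count, other.retained_count, removed)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"filter": k, "removed": v} for k, v in self.removed.items()]
        rows.append({"filter": "retained", "removed": self.retained_count})
        return pd.DataFrame(rows)


def apply_static_filters(
    series: pd.DataFrame,
    signal_threshold: float | None,
    max_sounder_depth: float | None,
) -> tuple[pd.DataFrame, RetentionReport]:
    """Apply the record-wise depth-bound and signal-strength filters.

    A record is retained iff

    * ``depth >= -0.5`` m (not more than 0.5 m above sea level),
    * ``depth <= max_sounder_depth + 1`` m (not implausibly below the
      deepest seafloor seen by the vessel sounder), and
    * ``signal_strength >= signal_threshold`` dB (when a threshold is set).

    Records failing a filter are counted against the first filter that
    rejects them, in the order above.
    """
    n_raw = len(series)
    removed: dict[str, int] = {}
    keep = np.ones(n_raw, dtype=bool)

    depth = series["depth"].to_numpy(dtype=float)

    above = depth < -SURFACE_ARTIFACT_LIMIT
    removed["above_surface"] = int(above.sum())
    keep &= ~above

    if max_sounder_depth is not None:
        if max_sounder_depth <= 0:
            raise ValueError("max_sounder_depth must be positive")
        overrun = keep & (depth > max_sounder_depth + SOUNDER_OVERRUN_MARGIN)
        removed["sounder_overrun"] = int(overrun.sum())
        keep &= ~overrun

    if signal_threshold is not None:
        if "signal_strength" not in series.columns:
            raise ValueError(
                "signal threshold set but series has no 'signal_strength' column"
            )
        signal = series["signal_strength"].to_numpy(dtype=float)
        weak = keep & ~(signal >= signal_threshold)  # NaN counts as weak
        removed["weak_signal"] = int(weak.sum())
        keep &= ~weak

    out = series.loc[keep].reset_index(drop=True)
    report = RetentionReport(n_raw, len(out), removed)
    logger.info(
        "static filters: %d/%d retained (%s)", len(out), n_raw, removed
    )
    return out, report


def _centered_window_bounds(n: int, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Half-open [lo, hi) index bounds of a centered window, truncated at edges.

    ``ceil(window/2) - 1`` records fall before the centre, the rest after.
    """
    before = int(np.ceil(window / 2)) - 1
    after = window - before  # centre sample + (window - before - 1) trailing
    idx = np.arange(n)
    lo = np.maximum(0, idx - before)
    hi = np.minimum(n, idx + after)
    return lo, hi


def median_window_filter(
    series: pd.DataFrame,
    window: int = MEDIAN_WINDOW,
    max_deviation: float = MEDIAN_MAX_DEVIATION,
) -> tuple[pd.DataFrame, RetentionReport]:
    """Remove detections deviating from a moving-window median depth.

    A single pass over the input series: record *i* is removed iff
    ``|depth_i - median(depth over the centered window of `window`
    records)| > max_deviation``.  Windows are truncated at the series
    edges; removals do not re-window.  Even-length window medians are the
    mean of the two central order statistics (numpy convention).
    """
    if window < 3:
        raise ValueError("median filter window must be >= 3")
    n = len(series)
    if n == 0:
        return series.copy(), RetentionReport(0, 0, {"median_spike": 0})

    depth = series["depth"].to_numpy(dtype=float)
    lo, hi = _centered_window_bounds(n, window)
    medians = np.empty(n)
    for i in range(n):
        medians[i] = np.median(depth[lo[i] : hi[i]])
    keep = np.abs(depth - medians) <= max_deviation

    out = series.loc[keep].reset_index(drop=True)
    report = RetentionReport(n, len(out), {"median_spike": int((~keep).sum())})
    logger.info("median filter: removed %d of %d", int((~keep).sum()), n)
    return out, report


def trim_track(
    series: pd.DataFrame,
    release_time: pd.Timestamp | None = None,
    exclusion_intervals: list[tuple[pd.Timestamp, pd.Timestamp]] | None = None,
    acclimation: pd.Timedelta = ACCLIMATION_PERIOD,
) -> tuple[pd.DataFrame, RetentionReport]:
    """Drop the post-release acclimation window and explicit exclusions.

    Records within ``acclimation`` of ``release_time`` (default: the first
    detection) are removed, as are records inside each closed exclusion
    interval (used e.g. around a mid-track recapture).  Dives that were in
    progress at a trim boundary surface downstream as truncated dives and
    are dropped there (see :func:`divetrace.dive_segmentation.detect_dives`).
    """
    n = len(series)
    if n == 0:
        return series.copy(), RetentionReport(0, 0, {"trim": 0})
    ts = series["timestamp"]
    if release_time is None:
        release_time = ts.iloc[0]
    keep = (ts >= release_time + acclimation).to_numpy()
    for interval in exclusion_intervals or []:
        start, end = interval
        if end < start:
            raise ValueError(f"exclusion interval end {end} before start {start}")
        keep &= ~((ts >= start) & (ts <= end)).to_numpy()
    out = series.loc[keep].reset_index(drop=True)
    report = RetentionReport(n, len(out), {"trim": int((~keep).sum())})
    logger.info("trim: removed %d of %d", int((~keep).sum()), n)
    return out, report


def preprocess_series(
    series: pd.DataFrame,
    signal_threshold: float | None = None,
    max_sounder_depth: float | None = None,
    window: int = MEDIAN_WINDOW,
    max_deviation: float = MEDIAN_MAX_DEVIATION,
    release_time: pd.Timestamp | None = None,
    exclusion_intervals: list[tuple[pd.Timestamp, pd.Timestamp]] | None = None,
) -> tuple[pd.DataFrame, RetentionReport]:
    """Run the full filter chain: depth/signal bounds, median filter, trim."""
    out, report = apply_static_filters(series, signal_threshold, max_sounder_depth)
    out, rep2 = median_window_filter(out, window=window, max_deviation=max_deviation)
    report = report.merge(rep2)
    out, rep3 = trim_track(out, release_time, exclusion_intervals)
    return out, report.merge(rep3)
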