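"""Depth "wiggle" detection and amplitude estimation.

A wiggle is a rapid vertical oscillation in depth during the gradual-ascent
(or, optionally, bottom) phase of a dive.  Wiggles are detected against a
local-regression (LOESS/LOWESS) smooth of the phase profile: the smooth
captures the slow trend of the ascent, the residual carries the
oscillations, and the peaks of the residual are counted as discrete wiggle
events.  The maximum wiggle amplitude is estimated as the 95th quantile of
the absolute residuals from a second, wider-span local-regression fit.

The smoothing window ``window_w`` is expressed as a number of detections
(the study cadence is one detection every 2 s) and is configured per
individual because movement styles differ between animals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.signal import find_peaks
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

#: Default smoothing window, in detections (~60 s at 2-s cadence).
DEFAULT_WINDOW_W = 30

#: Quantile of |residual| used for the maximum-amplitude estimate.
AMPLITUDE_QUANTILE = 0.95

#: The second (amplitude) fit uses this multiple of the detection window.
SECOND_FIT_FACTOR = 3


@dataclass
class WiggleSet:
    """Detected oscillation peaks for one dive phase."""

    dive_id: int
    phase_label: str
    n_wiggles: int
    peak_times: np.ndarray  # seconds, strictly increasing
    peak_deviations: np.ndarray  # residual magnitude at each peak (m)
    max_amplitude: float  # m, 95th quantile of |second-fit residuals|
    window_w: int
    short_phase: bool = False

    def __post_init__(self) -> None:
        assert self.n_wiggles == len(self.peak_times)


def smooth_profile(t: np.ndarray, depth: np.ndarray, window: int) -> np.ndarray:
    """LOESS-family smooth of a depth profile.

    ``window`` is a span in samples; it is converted to the fraction of the
    series the local regressions use.  Robustness iterations are disabled:
    wiggles are signal here, not outliers to be rejected, and the residuals
    must retain them.
    """
    n = len(t)
    if n < 3:
        return depth.astype(float).copy()
    frac = min(1.0, max(window, 3) / n)
    delta = 0.01 * (t[-1] - t[0]) if n > 500 else 0.0
    sm = lowess(depth, t, frac=frac, it=0, delta=delta, return_sorted=False)
    return np.asarray(sm, dtype=float)


def detect_wiggles(
    t: np.ndarray,
    depth: np.ndarray,
    window_w: int = DEFAULT_WINDOW_W,
    min_prominence: float | None = None,
    min_separation: int | None = None,
    sensor_resolution: float = 0.15,
    dive_id: int = -1,
    phase_label: str = "gradual_ascent",
) -> WiggleSet:
    """Count wiggle peaks in one phase profile.

    The profile is smoothed with span ``window_w``; the residual
    ``depth - smooth`` oscillates about zero, one positive excursion per
    wiggle.  Peaks are local maxima of the residual with topographic
    prominence of at least ``min_prominence`` (default
    ``max(2 * sensor_resolution, 0.2)`` m, so quantization steps never
    register), accepted greedily in decreasing order of magnitude subject
    to a minimum separation of ``window_w // 2`` samples.

    A wiggle is an oscillation sustained over tens of seconds, not a
    single pulse, so the residual is despiked with a short (5-sample,
    ~10 s) median filter before peak finding; isolated
    quantization/noise blips vanish while sinusoid-scale peaks pass
    essentially unchanged.

    Phases shorter than ``2 * window_w`` records cannot support the
    smoother and return zero wiggles with ``short_phase`` set.
    """
    if min_prominence is None:
        min_prominence = max(2.0 * sensor_resolution, 0.2)
    if min_separation is None:
        min_separation = max(1, window_w // 2)

    n = len(t)
    empty = np.array([], dtype=float)
    if n < 2 * window_w:
        return WiggleSet(
            dive_id, phase_label, 0, empty, empty,
            wiggle_amplitude(t, depth) if n >= 10 else 0.0,
            window_w, short_phase=True,
        )

    residual = depth - smooth_profile(t, depth, window_w)
    residual = median_filter(residual, size=5, mode="nearest")
    peaks, props = find_peaks(
        residual, prominence=min_prominence, distance=min_separation
    )
    order = np.argsort(peaks)
    peaks = peaks[order]
    amplitude = wiggle_amplitude(t, depth, SECOND_FIT_FACTOR * window_w)
    return WiggleSet(
        dive_id,
        phase_label,
        int(len(peaks)),
        t[peaks].astype(float),
        np.abs(residual[peaks]),
        amplitude,
        window_w,
    )


def wiggle_amplitude(
    t: np.ndarray, depth: np.ndarray, second_fit_span: int | None = None
) -> float:
    """Maximum wiggle amplitude of a phase profile.

    A second, wider-span local regression (default span
    ``SECOND_FIT_FACTOR * DEFAULT_WINDOW_W`` samples) is fit to the phase
    and the 95th quantile of the absolute residuals is returned.  The
    absolute value is deliberate: downward and upward excursions both
    carry amplitude.  Degenerate (constant) profiles return 0.
    """
    n = len(t)
    if n < 10:
        return 0.0
    if second_fit_span is None:
        second_fit_span = SECOND_FIT_FACTOR * DEFAULT_WINDOW_W
    if np.ptp(depth) == 0.0:
        return 0.0
    residual = depth - smooth_profile(t, depth, second_fit_span)
    return float(np.quantile(np.abs(residual), AMPLITUDE_QUANTILE))


def wiggles_for_dive(
    dive_id: int,
    phases: list,
    series: pd.DataFrame,
    window_w: int = DEFAULT_WINDOW_W,
    sensor_resolution: float = 0.15,
    include_bottom: bool = False,
    min_prominence: float | None = None,
) -> list[WiggleSet]:
    """Run wiggle detection over the gradual-ascent phases of one dive.

    Bottom phases are included behind ``include_bottom`` (the definition of
    a wiggle covers them, but gradual-ascent counts are the headline
    metric).  Returns one :class:`WiggleSet` per analysed phase.
    """
    labels = {"gradual_ascent"} | ({"bottom"} if include_bottom else set())
    t_all = (
        series["timestamp"] - series["timestamp"].iloc[0]
    ).dt.total_seconds().to_numpy()
    depth_all = series["depth"].to_numpy(dtype=float)
    t0 = series["timestamp"].iloc[0]
    out = []
    for phase in phases:
        if phase.label not in labels:
            continue
        a = (phase.start - t0).total_seconds()
        b = (phase.end - t0).total_seconds()
        mask = (t_all >= a) & (t_all < b)
        ws = detect_wiggles(
            t_all[mask],
            depth_all[mask],
            window_w=window_w,
            sensor_resolution=sensor_resolution,
            min_prominence=min_prominence,
            dive_id=dive_id,
            phase_label=phase.label,
        )
        out.append(ws)
    return out
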