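"""Dive-shape classification, bottom-phase activity, and U-dive bouts.

Shapes follow directly from the phase decomposition: a dive with a
gradual-ascent phase is S-shaped (interrupted if it also contains a
secondary descent), otherwise U-shaped.  Interrupted S-dives are grouped
with S-dives in downstream statistics.

Bottom-phase activity is summarised as the standard deviation of raw
depth during the bottom phase of each U-dive -- a proxy separating
stationary (resting) dives from active (possibly foraging) ones -- with
outliers flagged by an upper 1.5 x IQR fence over the individual's SD
set.  Runs of two or more consecutive U-dives form bouts, whose internal
spread of maximum depth and duration measures behavioural stereotypy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dive_segmentation import Dive, DivePhase

logger = logging.getLogger(__name__)

SHAPES = ("U", "S", "S_interrupted")


@dataclass
class DiveShape:
    dive_id: int
    shape: str  # U | S | S_interrupted
    bottom_depth_sd: float | None = None  # m; U-dives only
    outlier_flag: bool = False
    low_confidence: bool = False  # fence computed from < 4 dives

    @property
    def is_s(self) -> bool:
        """Interrupted S-dives count as S in all statistics."""
        return self.shape in ("S", "S_interrupted")


@dataclass
class Bout:
    bout_id: int
    dive_ids: list[int]
    sd_max_depth: float  # m, n-1 denominator
    sd_duration: float  # minutes, n-1 denominator

    @property
    def n_dives(self) -> int:
        return len(self.dive_ids)


def classify_shape(dive: Dive, phases: list[DivePhase]) -> DiveShape:
    """U if no gradual ascent; S if one exists; interrupted-S if the
    gradual ascent was broken by a secondary descent to the seafloor."""
    labels = {p.label for p in phases}
    if "gradual_ascent" not in labels:
        shape = "U"
    elif "secondary_descent" in labels:
        shape = "S_interrupted"
    else:
        shape = "S"
    return DiveShape(dive_id=dive.dive_id, shape=shape)


def bottom_depth_sd(phases: list[DivePhase], series: pd.DataFrame) -> float | None:
    """SD (n-1) of raw depths within the bottom phase of a dive.

    Raw, not smoothed, depths are used so the sensor resolution bounds the
    floor of the statistic.  Returns 0 for a constant bottom, None when
    the bottom phase holds fewer than 2 records.
    """
    bottoms = [p for p in phases if p.label == "bottom"]
    if not bottoms:
        return None
    ts = series["timestamp"]
    depths = []
    for p in bottoms:
        mask = (ts >= p.start) & (ts < p.end)
        depths.append(series.loc[mask, "depth"].to_numpy(dtype=float))
    d = np.concatenate(depths)
    if len(d) < 2:
        return None
    return float(np.std(d, ddof=1))


def bottom_activity_stats(
    dives: list[Dive],
    phases_by_dive: dict[int, list[DivePhase]],
    series: pd.DataFrame,
    shapes: list[DiveShape],
) -> list[DiveShape]:
    """Attach bottom-phase SDs and IQR outlier flags to U-dive shapes.

    The fence is upper-only, ``Q3 + 1.5 * IQR`` over the individual's
    U-dive SD set with linear-interpolation quantiles: a high SD means
    activity, a low one only a still sensor.  With fewer than 4 U-dives
    the fence is still computed but flagged low-confidence.
    """
    by_id = {s.dive_id: s for s in shapes}
    sds = {}
    for dive in dives:
        shape = by_id[dive.dive_id]
        if shape.shape != "U":
            continue
        sd = bottom_depth_sd(phases_by_dive[dive.dive_id], series)
        shape.bottom_depth_sd = sd
        if sd is not None:
            sds[dive.dive_id] = sd
    if sds:
        values = np.array(list(sds.values()))
        q1, q3 = np.quantile(values, [0.25, 0.75])  # linear interpolation
        fence = q3 + 1.5 * (q3 - q1)
        low_conf = len(values) < 4
        for dive_id, sd in sds.items():
            by_id[dive_id].outlier_flag = bool(sd > fence)
            by_id[dive_id].low_confidence = low_conf
        if low_conf:
            logger.warning(
                "IQR fence computed from only %d U-dives; low confidence",
                len(values),
            )
    return shapes


def find_u_bouts(dives: list[Dive], shapes: list[DiveShape]) -> list[Bout]:
    """Maximal runs of >= 2 consecutive U-dives, with intra-bout spreads.

    Dives must be consecutive in time with no other shape interleaved; a
    lone U-dive is not a bout.  Per-bout SDs (n-1) are of maximum depth in
    metres and dive duration in minutes; a bout of identical dives scores
    zero on both.
    """
    by_id = {s.dive_id: s for s in shapes}
    order = sorted(dives, key=lambda d: d.start)
    bouts: list[Bout] = []
    run: list[Dive] = []

    def close_run() -> None:
        if len(run) >= 2:
            depths = np.array([d.max_depth for d in run])
            durations = np.array([d.duration / 60.0 for d in run])
            bouts.append(
                Bout(
                    bout_id=len(bouts),
                    dive_ids=[d.dive_id for d in run],
                    sd_max_depth=float(np.std(depths, ddof=1)),
                    sd_duration=float(np.std(durations, ddof=1)),
                )
            )

    for dive in order:
        if by_id[dive.dive_id].shape == "U":
            run.append(dive)
        else:
            close_run()
            run = []
    close_run()
    return bouts


def shape_counts(shapes: list[DiveShape]) -> dict[str, int]:
    counts = {s: 0 for s in SHAPES}
    for s in shapes:
        counts[s.shape] += 1
    return counts
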