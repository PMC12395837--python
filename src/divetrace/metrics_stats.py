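"""Per-dive and per-individual behavioural metrics, distances, rank-sum test.

The per-individual summary mirrors the standard dive-behaviour table:
total dives, surfacing rate, shape counts, total/submerged/surface time,
means +/- SD of dive duration, surface interval, gradual-ascent time,
bottom time and maximum depth, and the wiggle metrics of S-shaped dives.
Gradual-ascent time is averaged over *all* dives (U-dives contribute
zero), which is the convention of the per-individual table; the
per-S-dive mean is exposed separately.

Horizontal movement is summarised as the great-circle distance between
consecutive surfacing positions, attributed by dive shape and compared
between shapes with a Wilcoxon rank-sum (Mann-Whitney U) test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .dive_segmentation import Dive, DivePhase
from .shape_classification import DiveShape
from .wiggle_detection import WiggleSet

logger = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_000.0

#: Maximum |Delta t| for a nearest-in-time environment-record join; half
#: the nominal 15-min logging cadence.
ENV_MATCH_MAX_S = 7.5 * 60.0


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def haversine_m(lat1, lon1, lat2, lon2, radius_m: float = EARTH_RADIUS_M):
    """Great-circle distance in metres on a sphere of ``radius_m``."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return radius_m * 2 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def inter_dive_distances(
    dives: list[Dive],
    shapes: list[DiveShape],
    positions: dict[int, tuple[float, float]],
    attribute_to: str = "enclosed",
) -> pd.DataFrame:
    """Distances between consecutive surfacing events, labelled by shape.

    ``positions`` maps dive_id -> (lat, lon) of the surfacing at the dive
    end.  The gap between the surfacings ending dive *k-1* and dive *k*
    reflects travel during dive *k*; by default (``attribute_to=
    "enclosed"``) it is attributed to dive *k*'s shape.  The alternative
    ``"previous"`` attributes it to dive *k-1*.  Interrupted S-dives count
    as S.  Gaps with a missing position are omitted (and counted in the
    log).
    """
    if attribute_to not in ("enclosed", "previous"):
        raise ValueError("attribute_to must be 'enclosed' or 'previous'")
    by_id = {s.dive_id: s for s in shapes}
    order = sorted(dives, key=lambda d: d.start)
    rows = []
    missing = 0
    for prev, cur in zip(order, order[1:]):
        p1 = positions.get(prev.dive_id)
        p2 = positions.get(cur.dive_id)
        if p1 is None or p2 is None or any(pd.isna(v) for v in (*p1, *p2)):
            missing += 1
            continue
        owner = cur if attribute_to == "enclosed" else prev
        shape = "S" if by_id[owner.dive_id].is_s else "U"
        rows.append(
            {
                "dive_id": owner.dive_id,
                "shape": shape,
                "distance_m": float(haversine_m(p1[0], p1[1], p2[0], p2[1])),
            }
        )
    if missing:
        logger.info("inter-dive distances: %d gaps omitted (missing position)", missing)
    return pd.DataFrame(rows, columns=["dive_id", "shape", "distance_m"])


def distance_summary(distances: pd.DataFrame) -> pd.DataFrame:
    """Median and IQR of inter-dive distance by dive shape."""
    rows = []
    for shape, grp in distances.groupby("shape"):
        d = grp["distance_m"].to_numpy()
        q1, q3 = np.quantile(d, [0.25, 0.75])
        rows.append(
            {"shape": shape, "n": len(d), "median_m": float(np.median(d)),
             "iqr_m": float(q3 - q1)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------

@dataclass
class RankSumResult:
    """Mann-Whitney/Wilcoxon rank-sum result, both statistic conventions.

    ``u_first`` is the U statistic of the first sample, ``u_second`` its
    complement (``u_first + u_second = n1 * n2``), and ``w_first`` the
    rank-sum (W) of the first sample.  Printed W values in the literature
    depend on an often unstated convention, so all three are reported.
    """

    u_first: float
    u_second: float
    w_first: float
    n1: int
    n2: int
    p_two_sided: float
    method: str  # exact_enumeration | normal_approximation


def rank_sum_test(x, y, method: str | None = None) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Ties receive midranks.  The exact null distribution is used when
    ``n1 + n2 <= 12`` and the pooled data are tie-free; otherwise the
    normal approximation with tie correction and continuity correction.
    ``method`` forces ``"exact_enumeration"`` or
    ``"normal_approximation"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("rank_sum_test requires non-empty samples")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if method is None:
        method = (
            "exact_enumeration"
            if (n1 + n2 <= 12 and not has_ties)
            else "normal_approximation"
        )
    if method == "exact_enumeration":
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    elif method == "normal_approximation":
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    u1 = float(res.statistic)
    return RankSumResult(
        u_first=u1,
        u_second=n1 * n2 - u1,
        w_first=u1 + n1 * (n1 + 1) / 2.0,
        n1=n1,
        n2=n2,
        p_two_sided=float(res.pvalue),
        method=method,
    )


# ---------------------------------------------------------------------------
# per-dive metrics
# ---------------------------------------------------------------------------

def nearest_environment(
    environment: pd.DataFrame,
    when: pd.Timestamp,
    max_gap_s: float = ENV_MATCH_MAX_S,
) -> pd.Series | None:
    """Environment record nearest in time to ``when``, or None beyond the gap."""
    if environment is None or len(environment) == 0:
        return None
    dt = (environment["timestamp"] - when).dt.total_seconds().abs()
    i = int(dt.idxmin())
    if dt.loc[i] > max_gap_s:
        return None
    return environment.loc[i]


def dive_metrics(
    dive: Dive,
    phases: list[DivePhase],
    environment: pd.DataFrame | None = None,
) -> dict:
    """Tidy per-dive record: durations, rates, phase makeup, heights.

    Descent rate is the descent vertical distance (m) over the descent
    time (s).  Gradual-ascent start/end heights above the seafloor use the
    nearest-in-time vessel sounder depth; when no environment record falls
    within the matching window the heights are reported missing, never
    zero.
    """
    by_label: dict[str, float] = {}
    for p in phases:
        by_label[p.label] = by_label.get(p.label, 0.0) + p.duration
    duration = dive.duration

    descent = next((p for p in phases if p.label == "descent"), None)
    descent_rate = np.nan
    if descent is not None and descent.duration > 0:
        descent_rate = (descent.end_depth - descent.start_depth) / descent.duration

    ga_phases = [p for p in phases if p.label == "gradual_ascent"]
    ga_time = sum(p.duration for p in ga_phases)
    ga_start_height = ga_end_height = np.nan
    if ga_phases and environment is not None:
        env = nearest_environment(environment, dive.start)
        if env is not None and not pd.isna(env.get("sounder_depth", np.nan)):
            seafloor = float(env["sounder_depth"])
            ga_start_height = seafloor - ga_phases[0].start_depth
            ga_end_height = seafloor - ga_phases[-1].end_depth

    record = {
        "dive_id": dive.dive_id,
        "start": dive.start,
        "end": dive.end,
        "duration_min": duration / 60.0,
        "max_depth_m": dive.max_depth,
        "post_dive_surface_interval_s": dive.post_dive_surface_interval,
        "descent_rate_m_s": descent_rate,
        "bottom_time_min": by_label.get("bottom", 0.0) / 60.0,
        "gradual_ascent_min": ga_time / 60.0,
        "ga_start_height_m": ga_start_height,
        "ga_end_height_m": ga_end_height,
    }
    for label, secs in sorted(by_label.items()):
        record[f"prop_{label}"] = secs / duration if duration > 0 else np.nan
    return record


# ---------------------------------------------------------------------------
# per-individual summary
# ---------------------------------------------------------------------------

def _mean_sd(values) -> tuple[float, float]:
    v = np.asarray([x for x in values if x is not None and np.isfinite(x)], dtype=float)
    if len(v) == 0:
        return (np.nan, np.nan)
    return float(v.mean()), (float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)


def surfacing_rate(total_dives: int, total_time_min: float) -> float:
    """Dives per hour over the span from first dive start to last dive end."""
    if total_time_min <= 0:
        return np.nan
    return total_dives / (total_time_min / 60.0)


def pooled_species_mean(means, counts) -> float:
    """Dive-count-weighted pooled mean of per-individual means."""
    means = np.asarray(means, dtype=float)
    counts = np.asarray(counts, dtype=float)
    return float(np.sum(means * counts) / np.sum(counts))


@dataclass
class IndividualSummary:
    """One row of the per-individual dive-behaviour table."""

    individual_id: str
    total_dives: int = 0
    surfacing_rate_per_hr: float = np.nan
    n_s_dives: int = 0
    n_u_dives: int = 0
    total_time_min: float = np.nan
    time_at_depth_min: float = np.nan
    time_at_surface_min: float = np.nan
    prop_time_at_depth: float = np.nan
    prop_time_at_surface: float = np.nan
    mean_dive_duration_min: float = np.nan
    sd_dive_duration_min: float = np.nan
    mean_surface_interval_min: float = np.nan
    sd_surface_interval_min: float = np.nan
    mean_gradual_ascent_min: float = np.nan
    sd_gradual_ascent_min: float = np.nan
    mean_gradual_ascent_per_s_dive_min: float = np.nan
    mean_bottom_time_min: float = np.nan
    sd_bottom_time_min: float = np.nan
    mean_max_depth_m: float = np.nan
    sd_max_depth_m: float = np.nan
    prop_s_dives_with_wiggles: float = np.nan
    mean_wiggles_per_s_dive: float = np.nan
    mean_max_wiggle_amplitude_m: float = np.nan
    sd_max_wiggle_amplitude_m: float = np.nan
    sensor_accuracy_m: float = np.nan
    zero_dives: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def individual_summary(
    individual_id: str,
    dives: list[Dive],
    phases_by_dive: dict[int, list[DivePhase]],
    shapes: list[DiveShape],
    wigglesets: list[WiggleSet] | None = None,
    sensor_accuracy: float = np.nan,
) -> IndividualSummary:
    """All per-individual summary fields.

    Invariants hold exactly by construction: submerged + surface time
    equals total time (first dive start to last dive end), the two
    proportions sum to 1, and the surfacing rate is the dive count over
    the total time in hours.  Means use n-1 SDs.  A track with zero dives
    comes back as a flagged all-zero summary.
    """
    if not dives:
        return IndividualSummary(individual_id, zero_dives=True, total_dives=0,
                                 sensor_accuracy_m=sensor_accuracy)

    order = sorted(dives, key=lambda d: d.start)
    by_id = {s.dive_id: s for s in shapes}
    total_time_min = (order[-1].end - order[0].start).total_seconds() / 60.0
    time_at_depth = sum(d.duration for d in order) / 60.0
    time_at_surface = total_time_min - time_at_depth

    durations = [d.duration / 60.0 for d in order]
    intervals = [
        d.post_dive_surface_interval / 60.0
        for d in order
        if d.post_dive_surface_interval is not None
    ]
    ga_all, bottoms, ga_s = [], [], []
    for d in order:
        phases = phases_by_dive[d.dive_id]
        ga = sum(p.duration for p in phases if p.label == "gradual_ascent") / 60.0
        bottom = sum(p.duration for p in phases if p.label == "bottom") / 60.0
        ga_all.append(ga)
        bottoms.append(bottom)
        if by_id[d.dive_id].is_s:
            ga_s.append(ga)
    max_depths = [d.max_depth for d in order]

    n_s = sum(1 for s in shapes if s.is_s)
    n_u = sum(1 for s in shapes if s.shape == "U")

    prop_wiggles = mean_wiggles = np.nan
    amp_mean = amp_sd = np.nan
    if wigglesets is not None and n_s > 0:
        per_dive: dict[int, dict] = {}
        for ws in wigglesets:
            rec = per_dive.setdefault(ws.dive_id, {"n": 0, "amp": 0.0})
            rec["n"] += ws.n_wiggles
            rec["amp"] = max(rec["amp"], ws.max_amplitude)
        s_ids = [s.dive_id for s in shapes if s.is_s]
        counts = [per_dive.get(i, {"n": 0})["n"] for i in s_ids]
        prop_wiggles = float(np.mean([c >= 1 for c in counts]))
        mean_wiggles = float(np.mean(counts))
        amps = [per_dive[i]["amp"] for i in s_ids if per_dive.get(i, {"n": 0})["n"] >= 1]
        amp_mean, amp_sd = _mean_sd(amps)

    mean_dur, sd_dur = _mean_sd(durations)
    mean_int, sd_int = _mean_sd(intervals)
    mean_ga, sd_ga = _mean_sd(ga_all)
    mean_bot, sd_bot = _mean_sd(bottoms)
    mean_dep, sd_dep = _mean_sd(max_depths)

    return IndividualSummary(
        individual_id=individual_id,
        total_dives=len(order),
        surfacing_rate_per_hr=surfacing_rate(len(order), total_time_min),
        n_s_dives=n_s,
        n_u_dives=n_u,
        total_time_min=total_time_min,
        time_at_depth_min=time_at_depth,
        time_at_surface_min=time_at_surface,
        prop_time_at_depth=time_at_depth / total_time_min,
        prop_time_at_surface=time_at_surface / total_time_min,
        mean_dive_duration_min=mean_dur,
        sd_dive_duration_min=sd_dur,
        mean_surface_interval_min=mean_int,
        sd_surface_interval_min=sd_int,
        mean_gradual_ascent_min=mean_ga,
        sd_gradual_ascent_min=sd_ga,
        mean_gradual_ascent_per_s_dive_min=_mean_sd(ga_s)[0] if ga_s else np.nan,
        mean_bottom_time_min=mean_bot,
        sd_bottom_time_min=sd_bot,
        mean_max_depth_m=mean_dep,
        sd_max_depth_m=sd_dep,
        prop_s_dives_with_wiggles=prop_wiggles,
        mean_wiggles_per_s_dive=mean_wiggles,
        mean_max_wiggle_amplitude_m=amp_mean,
        sd_max_wiggle_amplitude_m=amp_sd,
        sensor_accuracy_m=sensor_accuracy,
    )
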