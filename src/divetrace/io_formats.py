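"""Reading, configuration, and output tables for the dive pipeline.

Detection and environment logs are delimited text with ISO-8601
timestamps; receiver exports differ in column naming, so a
:class:`LogDialect` maps the standard field names onto whatever the file
uses.  Timestamps are parsed to UTC -- ordering must be unambiguous even
where local time is what a report would show.

Configuration is a single YAML file with global defaults, optional
segmentation overrides, and per-individual entries (signal threshold,
smoothing window, sensor resolution/accuracy, release time, exclusion
intervals).  :func:`run_pipeline` chains all stages for one individual
and :func:`write_outputs` writes the result as a set of delimited tables
plus a run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dive_segmentation import (
    Dive, DivePhase, SegmentationParams, detect_dives, drop_truncated_dives,
    segment_dive, zero_offset_correct,
)
from .metrics_stats import (
    dive_metrics, distance_summary, individual_summary, inter_dive_distances,
    nearest_environment,
)
from .preprocess import RetentionReport, preprocess_series
from .shape_classification import (
    Bout, DiveShape, bottom_activity_stats, classify_shape, find_u_bouts,
)
from .wiggle_detection import WiggleSet, wiggles_for_dive

logger = logging.getLogger(__name__)

DETECTION_COLUMNS = ("timestamp", "depth", "signal_strength",
                     "latitude", "longitude", "individual_id")
MANDATORY_DETECTION = ("timestamp", "depth", "signal_strength")
ENVIRONMENT_COLUMNS = ("timestamp", "sounder_depth", "water_temp",
                       "tide_height", "flow_direction", "latitude", "longitude")

ISO_FORMAT = "%Y-%m-%dT%H:%M:%S.%f%z"


@dataclass
class LogDialect:
    """Column mapping and delimiter of a particular log export."""

    delimiter: str = ","
    columns: dict[str, str] = field(default_factory=dict)
    # columns maps standard name -> column name in the file

    def resolve(self, standard: str) -> str:
        return self.columns.get(standard, standard)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_detection_log(
    path, dialect: LogDialect | None = None, individual_id: str | None = None
) -> pd.DataFrame:
    """Read a detection log into a time-ordered series.

    Rows with unparseable timestamps are rejected with a warning; records
    sharing a timestamp collapse to the one with the highest signal
    strength (the strongest signal is the least error-prone detection).
    A missing mandatory column is a hard error naming the column.
    """
    dialect = dialect or LogDialect()
    raw = pd.read_csv(path, sep=dialect.delimiter)
    for standard in MANDATORY_DETECTION:
        if dialect.resolve(standard) not in raw.columns:
            raise ValueError(f"detection log missing mandatory column "
                             f"{dialect.resolve(standard)!r}")
    out = pd.DataFrame()
    for standard in DETECTION_COLUMNS:
        col = dialect.resolve(standard)
        if col in raw.columns:
            out[standard] = raw[col]
    n_raw = len(out)
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True, errors="coerce")
    bad = out["timestamp"].isna()
    if bad.any():
        logger.warning("rejected %d rows with unparseable timestamps",
                       int(bad.sum()))
        out = out.loc[~bad]
    out["depth"] = pd.to_numeric(out["depth"], errors="coerce")
    out = out.loc[np.isfinite(out["depth"])]
    if individual_id is not None:
        out["individual_id"] = individual_id
    out = out.sort_values("timestamp", kind="mergesort")
    if len(out):
        # duplicate-timestamp tie-break: keep the strongest signal
        out = (
            out.sort_values(["timestamp", "signal_strength"], kind="mergesort")
            .drop_duplicates("timestamp", keep="last")
        )
    out = out.reset_index(drop=True)
    logger.info("read %d detections (%d rows dropped) from %s",
                len(out), n_raw - len(out), path)
    return out


def read_environment_log(path, dialect: LogDialect | None = None) -> pd.DataFrame:
    """Read the 15-min vessel environment log; missing values tolerated."""
    dialect = dialect or LogDialect()
    try:
        raw = pd.read_csv(path, sep=dialect.delimiter)
    except pd.errors.EmptyDataError:
        logger.warning("environment log %s is empty", path)
        return pd.DataFrame(columns=list(ENVIRONMENT_COLUMNS))
    out = pd.DataFrame()
    for standard in ENVIRONMENT_COLUMNS:
        col = dialect.resolve(standard)
        if col in raw.columns:
            out[standard] = raw[col]
    if len(out) == 0 or "timestamp" not in out.columns:
        logger.warning("environment log %s is empty", path)
        return pd.DataFrame(columns=list(ENVIRONMENT_COLUMNS))
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True, errors="coerce")
    out = out.loc[~out["timestamp"].isna()]
    out = out.sort_values("timestamp", kind="mergesort").reset_index(drop=True)
    return out


def max_sounder_depth(environment: pd.DataFrame) -> float | None:
    """Deepest vessel-sounder reading of a track, for the overrun filter."""
    if environment is None or len(environment) == 0:
        return None
    if "sounder_depth" not in environment.columns:
        return None
    value = pd.to_numeric(environment["sounder_depth"], errors="coerce").max()
    return None if pd.isna(value) else float(value)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class IndividualConfig:
    individual_id: str = "default"
    signal_threshold: float = 50.0  # dB
    smoothing_window_w: int = 30  # detections
    sensor_resolution: float = 0.15  # m
    sensor_accuracy: float = 0.5  # m
    position_source: str = "detection"  # detection | environment
    release_time: pd.Timestamp | None = None
    exclusion_intervals: list[tuple[pd.Timestamp, pd.Timestamp]] = field(
        default_factory=list
    )

    def validate(self) -> None:
        if not (0.0 <= self.signal_threshold <= 100.0):
            raise ValueError(
                f"signal_threshold {self.signal_threshold} dB outside [0, 100]"
            )
        if not (43.0 <= self.signal_threshold <= 65.0):
            logger.warning(
                "signal_threshold %.1f dB outside the typical 43-65 dB range",
                self.signal_threshold,
            )
        if self.smoothing_window_w < 3:
            raise ValueError("smoothing_window_w must be >= 3")
        if self.sensor_resolution <= 0:
            raise ValueError("sensor_resolution must be positive")
        if self.position_source not in ("detection", "environment"):
            raise ValueError("position_source must be 'detection' or 'environment'")


@dataclass
class PipelineConfig:
    defaults: IndividualConfig = field(default_factory=IndividualConfig)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    individuals: dict[str, IndividualConfig] = field(default_factory=dict)

    def for_individual(self, individual_id: str) -> IndividualConfig:
        if individual_id in self.individuals:
            return self.individuals[individual_id]
        cfg = dataclasses.replace(self.defaults, individual_id=individual_id)
        return cfg


_IND_KEYS = {f.name for f in dataclasses.fields(IndividualConfig)}
_SEG_KEYS = {f.name for f in dataclasses.fields(SegmentationParams)}


def _parse_individual(individual_id: str, entry: dict,
                      defaults: IndividualConfig) -> IndividualConfig:
    unknown = set(entry) - _IND_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} "
                         f"for individual {individual_id!r}")
    merged = {**asdict(defaults), **entry, "individual_id": individual_id}
    if merged.get("release_time") is not None:
        merged["release_time"] = pd.Timestamp(merged["release_time"])
        if merged["release_time"].tzinfo is None:
            merged["release_time"] = merged["release_time"].tz_localize("UTC")
    intervals = []
    for pair in merged.get("exclusion_intervals") or []:
        a, b = (pd.Timestamp(x) for x in pair)
        a = a.tz_localize("UTC") if a.tzinfo is None else a
        b = b.tz_localize("UTC") if b.tzinfo is None else b
        intervals.append((a, b))
    merged["exclusion_intervals"] = intervals
    cfg = IndividualConfig(**merged)
    cfg.validate()
    return cfg


def load_config(path) -> PipelineConfig:
    """Load and fully resolve a pipeline configuration file.

    Unknown keys are hard errors; defaults applied to omitted keys are
    echoed to the log so every run records its effective parameters.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    unknown = set(data) - {"defaults", "segmentation", "individuals"}
    if unknown:
        raise ValueError(f"unknown top-level config key(s) {sorted(unknown)}")

    base = IndividualConfig()
    defaults_entry = data.get("defaults") or {}
    defaults = _parse_individual(
        defaults_entry.get("individual_id", "default"),
        {k: v for k, v in defaults_entry.items() if k != "individual_id"},
        base,
    )
    for key in sorted(_IND_KEYS - set(defaults_entry) - {"individual_id"}):
        logger.info("config default applied: %s = %r", key,
                    getattr(defaults, key))

    seg_entry = data.get("segmentation") or {}
    unknown = set(seg_entry) - _SEG_KEYS
    if unknown:
        raise ValueError(f"unknown segmentation key(s) {sorted(unknown)}")
    segmentation = SegmentationParams(**seg_entry)

    individuals = {}
    for individual_id, entry in (data.get("individuals") or {}).items():
        individuals[individual_id] = _parse_individual(
            individual_id, entry or {}, defaults
        )
    return PipelineConfig(defaults, segmentation, individuals)


def save_config(config: PipelineConfig, path) -> None:
    """Write a config so that load_config reproduces it exactly."""

    def ind_dict(cfg: IndividualConfig) -> dict:
        d = asdict(cfg)
        d.pop("individual_id")
        if d["release_time"] is not None:
            d["release_time"] = str(d["release_time"])
        d["exclusion_intervals"] = [
            [str(a), str(b)] for a, b in d["exclusion_intervals"]
        ]
        return d

    data = {
        "defaults": ind_dict(config.defaults),
        "segmentation": asdict(config.segmentation),
        "individuals": {k: ind_dict(v) for k, v in config.individuals.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(
        {
            "defaults": {k: str(v) for k, v in asdict(config.defaults).items()},
            "segmentation": asdict(config.segmentation),
            "individuals": {
                k: {kk: str(vv) for kk, vv in asdict(v).items()}
                for k, v in config.individuals.items()
            },
        },
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    individual_id: str
    detections_clean: pd.DataFrame
    retention: RetentionReport
    dives: list[Dive]
    phases: dict[int, list[DivePhase]]
    shapes: list[DiveShape]
    bouts: list[Bout]
    wigglesets: list[WiggleSet]
    dive_table: pd.DataFrame
    summary: "pd.Series | None"
    positions: dict[int, tuple[float, float]]


def surfacing_positions(
    dives: list[Dive],
    series: pd.DataFrame,
    environment: pd.DataFrame | None,
    source: str = "detection",
) -> dict[int, tuple[float, float]]:
    """Position of the surfacing at each dive end.

    ``detection`` takes the receiver GPS of the last detection of the
    dive; ``environment`` the nearest 15-min vessel log entry.  Which one
    anchors surfacing locations is a study choice, so both are supported.
    """
    positions: dict[int, tuple[float, float]] = {}
    for dive in dives:
        if source == "detection":
            if {"latitude", "longitude"} <= set(series.columns):
                row = series.iloc[dive.end_idx]
                positions[dive.dive_id] = (row["latitude"], row["longitude"])
        elif source == "environment":
            env = nearest_environment(environment, dive.end)
            if env is not None:
                positions[dive.dive_id] = (env["latitude"], env["longitude"])
        else:
            raise ValueError(f"unknown position source {source!r}")
    return positions


def run_pipeline(
    detections: pd.DataFrame,
    environment: pd.DataFrame | None,
    config: IndividualConfig,
    segmentation: SegmentationParams | None = None,
) -> PipelineResult:
    """Chain every stage for one individual's track."""
    segmentation = segmentation or SegmentationParams()
    clean, retention = preprocess_series(
        detections,
        signal_threshold=config.signal_threshold,
        max_sounder_depth=max_sounder_depth(environment),
        release_time=config.release_time,
        exclusion_intervals=config.exclusion_intervals,
    )
    clean, _ = zero_offset_correct(
        clean,
        surface_depth_limit=max(1.0, config.sensor_accuracy + 0.5),
        resolution=config.sensor_resolution,
    )
    dives = drop_truncated_dives(
        detect_dives(clean, threshold=segmentation.surface_threshold)
    )
    phases = {d.dive_id: segment_dive(d, clean, segmentation) for d in dives}
    shapes = [classify_shape(d, phases[d.dive_id]) for d in dives]
    shapes = bottom_activity_stats(dives, phases, clean, shapes)
    bouts = find_u_bouts(dives, shapes)
    wigglesets = []
    for dive in dives:
        wigglesets.extend(
            wiggles_for_dive(
                dive.dive_id, phases[dive.dive_id], clean,
                window_w=config.smoothing_window_w,
                sensor_resolution=config.sensor_resolution,
            )
        )
    dive_table = pd.DataFrame(
        [dive_metrics(d, phases[d.dive_id], environment) for d in dives]
    )
    if len(dive_table):
        shape_map = {s.dive_id: s.shape for s in shapes}
        dive_table["shape"] = dive_table["dive_id"].map(shape_map)
    summary = individual_summary(
        config.individual_id, dives, phases, shapes, wigglesets,
        sensor_accuracy=config.sensor_accuracy,
    )
    positions = surfacing_positions(dives, clean, environment,
                                    config.position_source)
    return PipelineResult(
        individual_id=config.individual_id,
        detections_clean=clean,
        retention=retention,
        dives=dives,
        phases=phases,
        shapes=shapes,
        bouts=bouts,
        wigglesets=wigglesets,
        dive_table=dive_table,
        summary=pd.Series(summary.to_dict()),
        positions=positions,
    )


# ---------------------------------------------------------------------------
# output tables
# ---------------------------------------------------------------------------

def dives_table(dives: list[Dive]) -> pd.DataFrame:
    cols = ["dive_id", "start", "end", "duration", "max_depth",
            "post_dive_surface_interval", "has_gaps"]
    return pd.DataFrame(
        [{c: getattr(d, c) for c in cols} for d in dives], columns=cols
    )


def phases_table(phases: dict[int, list[DivePhase]]) -> pd.DataFrame:
    cols = ["dive_id", "label", "start", "end", "start_depth", "end_depth",
            "mean_depth", "vertical_rate"]
    rows = []
    for plist in phases.values():
        for p in plist:
            rows.append({c: getattr(p, c) for c in cols})
    return pd.DataFrame(rows, columns=cols)


def wiggles_table(wigglesets: list[WiggleSet]) -> pd.DataFrame:
    cols = ["dive_id", "phase_label", "n_wiggles", "max_amplitude", "window_w"]
    return pd.DataFrame(
        [{c: getattr(w, c) for c in cols} for w in wigglesets], columns=cols
    )


def shapes_table(shapes: list[DiveShape]) -> pd.DataFrame:
    cols = ["dive_id", "shape", "bottom_depth_sd", "outlier_flag"]
    return pd.DataFrame(
        [{c: getattr(s, c) for c in cols} for s in shapes], columns=cols
    )


def bouts_table(bouts: list[Bout]) -> pd.DataFrame:
    cols = ["bout_id", "n_dives", "sd_max_depth", "sd_duration"]
    frame = pd.DataFrame(
        [{c: getattr(b, c) for c in cols} for b in bouts], columns=cols
    )
    return frame


def write_outputs(
    results: list[PipelineResult] | PipelineResult,
    directory,
    config: PipelineConfig | None = None,
) -> dict[str, Path]:
    """Write all output tables and the run manifest.

    Empty results still produce header-only tables, so downstream tooling
    always finds the same file set.
    """
    if isinstance(results, PipelineResult):
        results = [results]
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {directory}: {exc}")

    def concat(frames: list[pd.DataFrame], columns) -> pd.DataFrame:
        frames = [f for f in frames if len(f)]
        if not frames:
            return pd.DataFrame(columns=list(columns))
        return pd.concat(frames, ignore_index=True)

    def with_id(frame: pd.DataFrame, individual_id: str) -> pd.DataFrame:
        frame = frame.copy()
        frame.insert(0, "individual_id", individual_id)
        return frame

    tables = {
        "detections_clean": concat(
            [r.detections_clean for r in results], DETECTION_COLUMNS
        ),
        "dives": concat(
            [with_id(dives_table(r.dives), r.individual_id) for r in results],
            ["individual_id"],
        ),
        "phases": concat(
            [with_id(phases_table(r.phases), r.individual_id) for r in results],
            ["individual_id"],
        ),
        "wiggles": concat(
            [with_id(wiggles_table(r.wigglesets), r.individual_id)
             for r in results],
            ["individual_id"],
        ),
        "bouts": concat(
            [with_id(bouts_table(r.bouts), r.individual_id) for r in results],
            ["individual_id"],
        ),
        "summary": concat(
            [pd.DataFrame([r.summary]) for r in results if r.summary is not None],
            ["individual_id"],
        ),
        "shapes": concat(
            [with_id(shapes_table(r.shapes), r.individual_id) for r in results],
            ["individual_id"],
        ),
        "retention": concat(
            [with_id(r.retention.to_frame(), r.individual_id) for r in results],
            ["individual_id", "filter", "removed"],
        ),
    }
    written = {}
    for name, frame in tables.items():
        path = directory / f"{name}.csv"
        frame.to_csv(path, index=False, date_format=ISO_FORMAT)
        written[name] = path

    manifest = {
        "software": "divetrace",
        "version": __version__,
        "config_hash": config_hash(config) if config is not None else None,
        "individuals": [r.individual_id for r in results],
        "tables": {k: str(v) for k, v in written.items()},
    }
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    written["manifest"] = path
    return written
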