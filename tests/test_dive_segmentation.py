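"""Zero-offset correction, dive detection, and phase segmentation."""

import numpy as np
import pandas as pd
import pytest

import divetrace as dt
from divetrace.dive_segmentation import (
    detect_dives,
    drop_truncated_dives,
    segment_core_phases,
    segment_dive,
    zero_offset_correct,
)

from conftest import T0, series_from, trapezoid_depth


class TestZeroOffsetCorrection:
    def test_true_zero_surfaces_leave_series_unchanged(self):
        t = np.arange(0, 840, 2.0)
        s = series_from(t, trapezoid_depth(t, 60, 780, 10.0, 60))
        out, offsets = zero_offset_correct(s)
        assert np.allclose(offsets, 0.0)
        assert np.allclose(out["depth"], s["depth"])

    def test_constant_bias_removed_within_resolution(self):
        det, _, _ = dt.simulate_track(
            [dt.DiveSpec(shape="U", max_depth=10, bottom_duration=200)] * 3,
            surface_intervals=[40, 40], seed=1,
        )
        surface = det["depth"].to_numpy() == 0.0
        biased = det.copy()
        biased["depth"] = biased["depth"] + 0.3
        out, _ = zero_offset_correct(biased, resolution=0.15)
        assert abs(np.median(out.loc[surface, "depth"])) <= 0.15

    def test_linear_drift_tracked(self):
        det, _, _ = dt.simulate_track(
            [dt.DiveSpec(shape="U", max_depth=10, bottom_duration=200)] * 3,
            surface_intervals=[40, 40], seed=1,
        )
        t = (det["timestamp"] - det["timestamp"].iloc[0]).dt.total_seconds()
        drift = 0.4 * t.to_numpy() / t.iloc[-1]
        surface = det["depth"].to_numpy() == 0.0
        drifted = det.copy()
        drifted["depth"] = drifted["depth"] + drift
        out, _ = zero_offset_correct(drifted)
        assert np.abs(out.loc[surface, "depth"]).max() < 0.2

    def test_no_surface_episode_warns_and_passes_through(self, caplog):
        s = series_from(np.arange(0, 100, 2.0), np.full(50, 8.0))
        with caplog.at_level("WARNING"):
            out, offsets = zero_offset_correct(s)
        assert np.allclose(offsets, 0.0)
        assert "no surface episodes" in caplog.text


class TestDetectDives:
    def test_trapezoid_boundaries_interpolated(self):
        # depth crosses 0.5 m at t = 100 s and t = 400 s by construction
        t = np.arange(0, 500, 2.0)
        d = np.interp(t, [0, 95, 100, 150, 350, 400, 405, 498],
                      [0, 0, 0.5, 10, 10, 0.5, 0, 0])
        dives = detect_dives(series_from(t, d))
        assert len(dives) == 1
        assert dives[0].duration == pytest.approx(300.0, abs=1e-6)

    def test_never_submerged_yields_no_dives(self):
        s = series_from(np.arange(0, 200, 2.0), np.full(100, 0.4))
        assert detect_dives(s) == []

    def test_post_dive_surface_interval(self):
        t = np.arange(0, 1000, 2.0)
        d = trapezoid_depth(t, 60, 400, 10, 40) + trapezoid_depth(t, 430, 800, 10, 40)
        dives = detect_dives(series_from(t, d))
        assert len(dives) == 2
        gap = dives[1].start - dives[0].end
        assert dives[0].post_dive_surface_interval == pytest.approx(
            gap.total_seconds()
        )
        assert dives[0].post_dive_surface_interval == pytest.approx(30.0, abs=4.0)
        assert dives[1].post_dive_surface_interval is None

    def test_time_translation_invariance(self, u_dive_series):
        base = detect_dives(u_dive_series)
        shifted = u_dive_series.copy()
        shifted["timestamp"] = shifted["timestamp"] + pd.Timedelta(hours=7)
        moved = detect_dives(shifted)
        assert len(base) == len(moved)
        assert moved[0].duration == pytest.approx(base[0].duration)
        assert (moved[0].start - base[0].start) == pd.Timedelta(hours=7)

    def test_truncated_dives_dropped(self):
        t = np.arange(0, 400, 2.0)
        d = np.full_like(t, 8.0)  # submerged for the whole record
        dives = detect_dives(series_from(t, d))
        assert dives[0].truncated_start and dives[0].truncated_end
        assert drop_truncated_dives(dives) == []


class TestCorePhases:
    def test_u_dive_phases_within_one_sample(self, u_dive_series):
        dive = detect_dives(u_dive_series)[0]
        phases = segment_core_phases(dive, u_dive_series)
        assert [p.label for p in phases] == ["descent", "bottom", "ascent"]
        by = {p.label: p for p in phases}
        # smoothed profile enters the 8 m band at t=108, leaves at t=732
        t0 = u_dive_series["timestamp"].iloc[0]
        assert abs((by["descent"].end - t0).total_seconds() - 108) <= 2
        assert abs((by["ascent"].start - t0).total_seconds() - 732) <= 2
        assert by["bottom"].vertical_rate == pytest.approx(0.0, abs=0.01)

    def test_v_dive_bottom_limited_to_band_transit(self):
        # a symmetric V has no plateau: its bottom phase is only the time
        # the ramps spend inside the 20% depth band (~0.2*10/0.5 m/s per
        # side here), far short of a real bottom residence
        t = np.arange(0, 200, 2.0)
        d = trapezoid_depth(t, 60, 100, 10.0, 20)
        s = series_from(t, d)
        dive = detect_dives(s)[0]
        by = {p.label: p for p in segment_core_phases(dive, s)}
        transit = 2 * (0.2 * 10.0) / 0.5
        assert by["bottom"].duration <= transit + 2 * 2.0
        assert by["bottom"].duration < 0.4 * dive.duration

    def test_flat_bottom_has_zero_depth_sd(self):
        # step profile: every bottom-phase record sits at exactly 10 m
        from divetrace.shape_classification import bottom_depth_sd
        t = np.arange(0, 400, 2.0)
        d = np.where((t >= 60) & (t < 340), 10.0, 0.0)
        s = series_from(t, d)
        dive = detect_dives(s)[0]
        phases = segment_core_phases(dive, s)
        assert bottom_depth_sd(phases, s) == pytest.approx(0.0)

    def test_degenerate_dive_single_flagged_phase(self):
        t = np.arange(0, 20, 2.0)
        d = np.array([0, 0, 2, 5, 2, 0, 0, 0, 0, 0.0])
        dive = detect_dives(series_from(t, d))[0]
        phases = segment_core_phases(dive, series_from(t, d))
        assert len(phases) == 1
        assert phases[0].label == "descent_ascent" and phases[0].flagged


def _s_dive_series(ga_rate=0.006, ga_duration=900.0, **kw):
    spec = dt.DiveSpec(
        shape="S", max_depth=18, descent_rate=0.1, ascent_rate=0.1,
        first_ascent_rate=0.1, bottom_duration=120, ga_start_height=5.5,
        ga_span=ga_rate * ga_duration, ga_duration=ga_duration, **kw,
    )
    return dt.simulate_track([spec], seed=0)


class TestSPhases:
    def test_s_dive_gradual_ascent_recovered_within_two_samples(self):
        # 15-min gradual ascent at 0.006 m/s, the observed mean rate scale
        det, _, truth = _s_dive_series()
        dive = drop_truncated_dives(detect_dives(det))[0]
        phases = segment_dive(dive, det)
        labels = [p.label for p in phases]
        assert labels == ["descent", "bottom", "first_ascent",
                          "gradual_ascent", "final_ascent"]
        ga = next(p for p in phases if p.label == "gradual_ascent")
        truth_ga = next(p for p in truth.dives[0].phases
                        if p[0] == "gradual_ascent")
        t0 = det["timestamp"].iloc[0]
        assert abs((ga.start - t0).total_seconds() - truth_ga[1]) <= 4.0
        assert abs((ga.end - t0).total_seconds() - truth_ga[2]) <= 4.0
        assert -0.03 <= ga.vertical_rate <= 0.0

    def test_interrupted_s_dive_emits_secondary_phases(self):
        det, _, truth = _s_dive_series(n_wiggles=0, n_interruptions=1)
        assert truth.dives[0].shape == "S_interrupted"
        dive = drop_truncated_dives(detect_dives(det))[0]
        labels = [p.label for p in segment_dive(dive, det)]
        assert "secondary_descent" in labels and "secondary_ascent" in labels

    def test_u_dive_is_left_with_core_phases(self, u_dive_series):
        dive = detect_dives(u_dive_series)[0]
        phases = segment_dive(dive, u_dive_series)
        assert [p.label for p in phases] == ["descent", "bottom", "ascent"]

    def test_gradual_ascent_mean_depth_strictly_midwater(self):
        det, _, _ = _s_dive_series()
        dive = drop_truncated_dives(detect_dives(det))[0]
        for p in segment_dive(dive, det):
            if p.label == "gradual_ascent":
                assert 0.5 < p.mean_depth < dive.max_depth


class TestPartitionInvariant:
    @pytest.mark.parametrize("sensor", ["ideal", "fine"])
    def test_phase_durations_partition_dive_duration(self, sensor):
        model = dt.NOISELESS_SENSOR if sensor == "ideal" else dt.FINE_SENSOR
        for seed in range(5):
            det, env, _ = dt.simulate_study_track(seed, n_dives=4, sensor=model)
            cfg = dt.IndividualConfig(
                individual_id="sim", signal_threshold=43,
                release_time=det["timestamp"].iloc[0] - pd.Timedelta(minutes=20),
            )
            res = dt.run_pipeline(det, env, cfg)
            assert res.dives, "simulated track must contain dives"
            for dive in res.dives:
                phases = res.phases[dive.dive_id]
                total = sum(p.duration for p in phases)
                assert total == pytest.approx(dive.duration, abs=1e-6)
                # shared boundaries, no overlap
                for a, b in zip(phases, phases[1:]):
                    assert a.end == b.start


def test_manual_phase_override_roundtrip(u_dive_series):
    dive = detect_dives(u_dive_series)[0]
    mid = dive.start + pd.Timedelta(seconds=dive.duration / 2)
    phases = dt.apply_phase_overrides(
        dive, u_dive_series,
        [("descent", dive.start, mid), ("ascent", mid, dive.end)],
    )
    assert [p.label for p in phases] == ["descent", "ascent"]
    assert sum(p.duration for p in phases) == pytest.approx(dive.duration)
    with pytest.raises(ValueError, match="contiguous"):
        dt.apply_phase_overrides(
            dive, u_dive_series,
            [("descent", dive.start, mid),
             ("ascent", mid + pd.Timedelta(seconds=2), dive.end)],
        )
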