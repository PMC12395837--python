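"""Behavioural metrics, distances, and the rank-sum comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import divetrace as dt
from divetrace.dive_segmentation import Dive, DivePhase
from divetrace.metrics_stats import (
    dive_metrics,
    distance_summary,
    haversine_m,
    individual_summary,
    inter_dive_distances,
    nearest_environment,
    pooled_species_mean,
    rank_sum_test,
    surfacing_rate,
)
from divetrace.shape_classification import classify_shape

from conftest import T0


def _dive(dive_id, start_s, duration, max_depth=10.0, psi=None):
    start = T0 + pd.Timedelta(seconds=start_s)
    return Dive(dive_id=dive_id, start=start,
                end=start + pd.Timedelta(seconds=duration),
                duration=duration, max_depth=max_depth, start_idx=0, end_idx=0,
                post_dive_surface_interval=psi)


def _phase(dive_id, label, start_s, duration, d0, d1):
    start = T0 + pd.Timedelta(seconds=start_s)
    rate = (d1 - d0) / duration
    return DivePhase(dive_id=dive_id, label=label, start=start,
                     end=start + pd.Timedelta(seconds=duration),
                     start_depth=d0, end_depth=d1,
                     mean_depth=(d0 + d1) / 2, vertical_rate=rate)


class TestDiveMetrics:
    def test_descent_rate_definition(self):
        dive = _dive(0, 100, 300, max_depth=12.0)
        phases = [
            _phase(0, "descent", 100, 120, 0.5, 12.0 + 0.5),
            _phase(0, "bottom", 220, 120, 12.5, 12.5),
            _phase(0, "ascent", 340, 60, 12.5, 0.5),
        ]
        rec = dive_metrics(dive, phases)
        assert rec["descent_rate_m_s"] == pytest.approx(12.0 / 120.0)
        assert rec["duration_min"] == pytest.approx(5.0)
        assert rec["max_depth_m"] == 12.0

    def test_missing_sounder_depth_reports_missing_heights(self):
        dive = _dive(0, 0, 600)
        phases = [_phase(0, "gradual_ascent", 0, 600, 12.0, 8.0)]
        rec = dive_metrics(dive, phases, environment=None)
        assert np.isnan(rec["ga_start_height_m"])
        assert np.isnan(rec["ga_end_height_m"])


class TestEnvironmentJoin:
    def test_nearest_matches_exhaustive_search(self, rng):
        times = T0 + pd.to_timedelta(np.sort(rng.uniform(0, 36000, 40)), unit="s")
        env = pd.DataFrame({"timestamp": times,
                            "sounder_depth": rng.uniform(10, 20, 40)})
        for _ in range(25):
            when = T0 + pd.Timedelta(seconds=float(rng.uniform(0, 36000)))
            got = nearest_environment(env, when, max_gap_s=1e12)
            # brute-force minimum |dt| oracle
            deltas = [abs((ts - when).total_seconds()) for ts in env["timestamp"]]
            assert got["timestamp"] == env["timestamp"].iloc[int(np.argmin(deltas))]

    def test_gap_limit_returns_none(self):
        env = pd.DataFrame({"timestamp": [T0], "sounder_depth": [15.0]})
        assert nearest_environment(env, T0 + pd.Timedelta(minutes=10)) is None


class TestSummary:
    def _results(self):
        # 15 dives over 978.7 min total, matching the headline individual
        n = 15
        total_min = 978.7
        dive_min = 963.9 / n
        gap_min = (total_min - 963.9) / (n - 1)
        dives, phases, shapes = [], {}, []
        cursor = 0.0
        for i in range(n):
            d = _dive(i, cursor * 60, dive_min * 60, max_depth=17.0,
                      psi=gap_min * 60 if i < n - 1 else None)
            dives.append(d)
            phases[i] = [
                _phase(i, "descent", cursor * 60, 120, 0.5, 17.0),
                _phase(i, "bottom", cursor * 60 + 120, dive_min * 60 - 240,
                       17.0, 17.0),
                _phase(i, "ascent", cursor * 60 + dive_min * 60 - 120, 120,
                       17.0, 0.5),
            ]
            shapes.append(classify_shape(d, phases[i]))
            cursor += dive_min + gap_min
        return dives, phases, shapes

    def test_surfacing_rate_and_proportions(self):
        dives, phases, shapes = self._results()
        s = individual_summary("dora-like", dives, phases, shapes)
        assert s.total_time_min == pytest.approx(978.7, abs=1e-6)
        assert s.surfacing_rate_per_hr == pytest.approx(0.92, abs=0.005)
        assert s.prop_time_at_depth == pytest.approx(963.9 / 978.7, abs=1e-9)
        # internal consistency invariants
        assert s.time_at_depth_min + s.time_at_surface_min == pytest.approx(
            s.total_time_min
        )
        assert s.prop_time_at_depth + s.prop_time_at_surface == pytest.approx(1.0)
        assert s.surfacing_rate_per_hr == pytest.approx(
            s.total_dives / (s.total_time_min / 60.0)
        )

    def test_zero_dives_flagged(self):
        s = individual_summary("empty", [], {}, [])
        assert s.zero_dives and s.total_dives == 0

    def test_pooled_species_mean(self):
        assert pooled_species_mean([64.3, 36.2, 16.2], [15, 25, 28]) == (
            pytest.approx((15 * 64.3 + 25 * 36.2 + 28 * 16.2) / 68)
        )
        assert surfacing_rate(15, 978.7) == pytest.approx(0.9196, abs=1e-4)


class TestDistances:
    def test_small_latitude_offset_matches_closed_form(self):
        # 0.001 deg of latitude = R * pi/180 * 0.001 ~ 111.2 m
        d = haversine_m(-21.0, 114.0, -21.001, 114.0)
        assert d == pytest.approx(111.2, abs=0.1)

    def test_symmetry_and_identity(self, rng):
        p = rng.uniform(-60, 60, size=(10, 4))
        fwd = haversine_m(p[:, 0], p[:, 1], p[:, 2], p[:, 3])
        rev = haversine_m(p[:, 2], p[:, 3], p[:, 0], p[:, 1])
        assert np.allclose(fwd, rev)
        assert haversine_m(12.0, 44.0, 12.0, 44.0) == 0.0

    def test_matches_law_of_cosines_within_point1_percent(self, rng):
        for _ in range(50):
            lat1, lat2 = rng.uniform(-65, 65, 2)
            lon1 = rng.uniform(-180, 180)
            lon2 = lon1 + rng.uniform(-0.1, 0.1)
            lat2 = lat1 + rng.uniform(-0.1, 0.1)
            hav = haversine_m(lat1, lon1, lat2, lon2)
            f1, f2 = np.radians([lat1, lat2])
            dl = np.radians(lon2 - lon1)
            loc = 6_371_000.0 * np.arccos(
                np.clip(np.sin(f1) * np.sin(f2)
                        + np.cos(f1) * np.cos(f2) * np.cos(dl), -1, 1)
            )
            if hav > 100:  # law of cosines is ill-conditioned at tiny angles
                assert abs(hav - loc) / hav < 1e-3

    def test_gap_attribution_by_shape(self):
        dives = [_dive(i, i * 700, 600) for i in range(3)]
        shapes = []
        for i, shp in enumerate("USU"):
            ph = [_phase(i, "descent", i * 700, 100, 0.5, 10)]
            if shp == "S":
                ph.append(_phase(i, "gradual_ascent", i * 700 + 100, 300, 8, 5))
            shapes.append(classify_shape(dives[i], ph))
        positions = {0: (-21.0, 114.0), 1: (-21.002, 114.0), 2: (-21.0025, 114.0)}
        table = inter_dive_distances(dives, shapes, positions)
        # gap 0->1 encloses dive 1 (S); gap 1->2 encloses dive 2 (U)
        assert list(table["shape"]) == ["S", "U"]
        assert table["distance_m"].iloc[0] == pytest.approx(222.4, abs=0.5)
        summary = distance_summary(table)
        assert set(summary["shape"]) == {"S", "U"}


def _exact_enumeration_p(x, y):
    """Independent oracle: two-sided p over all C(n1+n2, n1) labelings."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = pd.Series(pooled).rank().to_numpy()

    def u_of(idx):
        r = ranks[list(idx)].sum()
        return r - n1 * (n1 + 1) / 2

    observed = u_of(range(n1))
    n = len(pooled)
    mean = len(x) * len(y) / 2
    us = [u_of(c) for c in itertools.combinations(range(n), n1)]
    extreme = sum(abs(u - mean) >= abs(observed - mean) - 1e-12 for u in us)
    return extreme / len(us)


class TestRankSum:
    def test_separated_samples_exact(self):
        res = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res.method == "exact_enumeration"
        assert res.u_first == 0
        assert res.p_two_sided == pytest.approx(0.1)
        assert res.p_two_sided == pytest.approx(
            _exact_enumeration_p(np.array([1., 2, 3]), np.array([4., 5, 6]))
        )

    @settings(max_examples=20, deadline=None)
    @given(
        st.lists(st.floats(-50, 50), min_size=1, max_size=8),
        st.lists(st.floats(-50, 50), min_size=1, max_size=8),
    )
    def test_u_complementarity(self, x, y):
        res = rank_sum_test(x, y)
        assert res.u_first + res.u_second == pytest.approx(len(x) * len(y))
        assert 0.0 <= res.p_two_sided <= 1.0
        assert res.w_first == pytest.approx(
            res.u_first + len(x) * (len(x) + 1) / 2
        )

    def test_exact_agrees_with_enumeration_oracle(self, rng):
        for _ in range(5):
            x = rng.uniform(0, 100, 4)
            y = rng.uniform(0, 100, 5)
            res = rank_sum_test(x, y)
            assert res.method == "exact_enumeration"
            assert res.p_two_sided == pytest.approx(
                _exact_enumeration_p(x, y), abs=1e-9
            )

    def test_normal_approximation_close_to_exact_at_n20(self, rng):
        for _ in range(10):
            x = rng.normal(0, 1, 20)
            y = rng.normal(0.3, 1, 20)
            exact = rank_sum_test(x, y, method="exact_enumeration")
            approx = rank_sum_test(x, y, method="normal_approximation")
            assert abs(exact.p_two_sided - approx.p_two_sided) < 0.01

    def test_empty_group_is_hard_error(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])
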