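"""Shared fixtures: synthetic series builders used across the suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

T0 = pd.Timestamp("2022-06-01T00:00:00Z")


def series_from(t_seconds, depths, signal=90.0, **extra) -> pd.DataFrame:
    """Detection DataFrame from seconds-offset and depth arrays."""
    t_seconds = np.asarray(t_seconds, dtype=float)
    frame = pd.DataFrame(
        {
            "timestamp": T0 + pd.to_timedelta(t_seconds, unit="s"),
            "depth": np.asarray(depths, dtype=float),
            "signal_strength": np.broadcast_to(
                np.asarray(signal, dtype=float), t_seconds.shape
            ).copy(),
        }
    )
    for key, value in extra.items():
        frame[key] = value
    return frame


def trapezoid_depth(t, start, end, max_depth, ramp):
    """Trapezoidal dive profile: linear descent/ascent, flat top."""
    t = np.asarray(t, dtype=float)
    d = np.zeros_like(t)
    m = (t >= start) & (t < start + ramp)
    d[m] = (t[m] - start) / ramp * max_depth
    m = (t >= start + ramp) & (t < end - ramp)
    d[m] = max_depth
    m = (t >= end - ramp) & (t < end)
    d[m] = (end - t[m]) / ramp * max_depth
    return d


@pytest.fixture
def rng():
    return np.random.default_rng(20220601)


@pytest.fixture
def u_dive_series():
    """U-dive: 60 s descent to 10 m, 600 s bottom, 60 s ascent, surface pads."""
    t = np.arange(0, 840, 2.0)
    return series_from(t, trapezoid_depth(t, 60, 780, 10.0, 60))
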