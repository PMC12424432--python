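"""Shared fixtures: hand-built minute streams and small daily-record tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from somnalr.markers import MinuteStream


def build_stream(
    segments,
    start="2021-08-17 23:00",
    stress=None,
    subject_id="S001",
    activity=None,
):
    """Assemble a MinuteStream from (stage, n_minutes) segments.

    ``stress`` may be None (all minutes at 30), a scalar, or a full array
    with NaN for missing minutes.
    """
    stages = np.concatenate(
        [np.full(n, stage, dtype=object) for stage, n in segments]
    )
    n = len(stages)
    times = pd.date_range(start, periods=n, freq="min")
    if stress is None:
        stress = np.full(n, 30.0)
    elif np.isscalar(stress):
        stress = np.full(n, float(stress))
    else:
        stress = np.asarray(stress, dtype=float)
    if activity is None:
        activity = np.full(n // 15, "sedentary", dtype=object)
    return MinuteStream(
        subject_id=subject_id,
        date=pd.Timestamp(start).normalize(),
        times=times,
        stages=stages,
        stress=stress,
        activity=np.asarray(activity, dtype=object),
    )


@pytest.fixture
def stream_builder():
    return build_stream


@pytest.fixture
def daily_records():
    """Ten days of complete records for two subjects, with valid sleep and
    stress compositions."""
    rng = np.random.default_rng(99)
    rows = []
    for sid, age in (("A", 28), ("B", 40)):
        for j in range(5):
            day = pd.Timestamp("2021-08-16") + pd.Timedelta(days=j)
            sleep = rng.dirichlet([2, 30, 10, 8])
            stress = rng.dirichlet([30, 5, 2, 1])
            rows.append(
                {
                    "subject_id": sid,
                    "date": day,
                    "age": age,
                    "alcohol": ["none", "low", "moderate", "high", "none"][j],
                    "hours_worked": float(rng.uniform(4, 10)),
                    "subjective_evening_stress": int(rng.integers(1, 11)),
                    "subjective_evening_energy": int(rng.integers(1, 11)),
                    "active_hours": float(rng.uniform(0, 4)),
                    "average_daily_stress": float(rng.uniform(15, 60)),
                    "prop_awake": sleep[0],
                    "prop_light": sleep[1],
                    "prop_deep": sleep[2],
                    "prop_rem": sleep[3],
                    "stress_low": stress[0],
                    "stress_medium": stress[1],
                    "stress_high": stress[2],
                    "stress_highest": stress[3],
                }
            )
    return pd.DataFrame(rows)
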