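"""Daily wearable markers from minute-level streams.

Reduces one subject-night of minute-resolution wearable data (sleep-stage
hypnogram, 0-100 stress level, 15-min activity-class epochs) to the daily
features used downstream: the sleep-stage composition over the sleep-wake
cycle, stress summary statistics separately for awake and asleep periods,
proportions of time in four equidistant stress bands, and active hours.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .compositional import Composition

__all__ = [
    "MinuteStream",
    "SleepCycle",
    "SleepComposition",
    "StressSummary",
    "NoSleepDetected",
    "EmptyPeriod",
    "SLEEP_STAGES",
    "STRESS_CLASS_LABELS",
    "STRESS_MERGE_MAP",
    "identify_sleep_cycle",
    "stage_proportions",
    "stress_summary",
    "stress_category_proportions",
    "merge_components",
    "active_hours",
    "derive_daily_markers",
]

#: stage labels counted as asleep
SLEEP_STAGES = ("light", "deep", "rem")
STAGE_LABELS = ("awake", "light", "deep", "rem")

#: four equidistant stress bands on the integer 0-100 scale:
#: low [0, 25], medium [26, 50], high [51, 75], highest [76, 100]
STRESS_CLASS_LABELS = ("low", "medium", "high", "highest")
_STRESS_EDGES = np.array([25, 50, 75])

#: merge of the two upper bands -> three classes, as used for the
#: nocturnal-stress outcome (high = [51, 100])
STRESS_MERGE_MAP: Mapping[str, tuple[str, ...]] = {
    "low": ("low",),
    "medium": ("medium",),
    "high": ("high", "highest"),
}

ACTIVE_CLASSES = ("active", "highly_active")
EPOCH_MINUTES = 15


class NoSleepDetected(ValueError):
    """The stream contains no minute labeled light/deep/REM."""


class EmptyPeriod(ValueError):
    """The requested period contains no valid stress minute."""


@dataclass(frozen=True)
class MinuteStream:
    """One subject-night of minute-level wearable data.

    ``times`` must be contiguous at 1-minute resolution and strictly
    increasing.  ``stress`` is on the 0-100 scale with NaN for missing
    minutes.  ``activity`` holds one class per complete 15-minute epoch
    (``len(times) // 15`` entries).
    """

    subject_id: str
    date: pd.Timestamp
    times: pd.DatetimeIndex
    stages: np.ndarray
    stress: np.ndarray
    activity: np.ndarray

    def __post_init__(self) -> None:
        times = pd.DatetimeIndex(self.times)
        stages = np.asarray(self.stages, dtype=object)
        stress = np.asarray(self.stress, dtype=float)
        activity = np.asarray(self.activity, dtype=object)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "stages", stages)
        object.__setattr__(self, "stress", stress)
        object.__setattr__(self, "activity", activity)
        n = len(times)
        if n == 0:
            raise ValueError("empty stream")
        deltas = np.diff(times.asi8)
        if len(deltas) and not np.all(deltas == 60_000_000_000):
            raise ValueError("minutes must be contiguous and strictly increasing")
        if stages.shape != (n,) or stress.shape != (n,):
            raise ValueError("stages and stress must have one entry per minute")
        valid = np.isfinite(stress)
        if np.any((stress[valid] < 0) | (stress[valid] > 100)):
            raise ValueError("stress values must lie in [0, 100]")
        if len(activity) != n // EPOCH_MINUTES:
            raise ValueError(
                f"expected {n // EPOCH_MINUTES} activity epochs, got {len(activity)}"
            )

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class SleepCycle:
    """Sleep-wake cycle: first-asleep to final wake-up.

    ``onset`` is the first minute labeled light/deep/REM; ``offset`` is the
    minute *after* the last such minute, so the cycle window is the
    half-open interval [onset, offset).
    """

    subject_id: str
    date: pd.Timestamp
    onset: pd.Timestamp
    offset: pd.Timestamp

    def __post_init__(self) -> None:
        if not self.onset < self.offset:
            raise ValueError("cycle onset must precede offset")


@dataclass(frozen=True)
class SleepComposition:
    proportions: Composition  # over (awake, light, deep, rem)
    total_sleep_minutes: int


@dataclass(frozen=True)
class StressSummary:
    period: str  # "awake" | "asleep"
    n_minutes: int
    mean: float
    sd: float
    min: float
    max: float
    median: float
    category_proportions: Composition


def identify_sleep_cycle(stream: MinuteStream) -> SleepCycle:
    """Locate the sleep-wake cycle from the first asleep to the final wake-up."""
    asleep = np.isin(stream.stages, SLEEP_STAGES)
    if not asleep.any():
        raise NoSleepDetected(f"no sleep-stage minutes in stream {stream.subject_id}")
    idx = np.flatnonzero(asleep)
    onset = stream.times[idx[0]]
    offset = stream.times[idx[-1]] + pd.Timedelta(minutes=1)
    return SleepCycle(stream.subject_id, stream.date, onset, offset)


def _cycle_mask(stream: MinuteStream, cycle: SleepCycle) -> np.ndarray:
    return (stream.times >= cycle.onset) & (stream.times < cycle.offset)


def stage_proportions(stream: MinuteStream, cycle: SleepCycle) -> SleepComposition:
    """Proportions of time per sleep stage over the cycle window.

    Awake minutes outside [onset, offset) — e.g. before going to bed or
    after the final wake-up — are excluded, so the awake component measures
    intra-night fragmentation only.
    """
    in_cycle = _cycle_mask(stream, cycle)
    if not in_cycle.any():
        raise ValueError("cycle window contains no minutes of the stream")
    stages = stream.stages[in_cycle]
    counts = np.array([np.sum(stages == lab) for lab in STAGE_LABELS], dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("cycle window contains no staged minutes")
    comp = Composition(STAGE_LABELS, counts / total, baseline="light")
    sleep_minutes = int(counts[1:].sum())
    return SleepComposition(comp, sleep_minutes)


def _period_mask(stream: MinuteStream, cycle: SleepCycle, period: str) -> np.ndarray:
    """Asleep = sleep-stage minutes within the cycle; awake = everything else."""
    if period not in ("awake", "asleep"):
        raise ValueError(f"period must be 'awake' or 'asleep', got {period!r}")
    asleep = _cycle_mask(stream, cycle) & np.isin(stream.stages, SLEEP_STAGES)
    return asleep if period == "asleep" else ~asleep


def _period_stress(stream: MinuteStream, cycle: SleepCycle, period: str) -> np.ndarray:
    mask = _period_mask(stream, cycle, period) & np.isfinite(stream.stress)
    values = stream.stress[mask]
    if len(values) == 0:
        raise EmptyPeriod(f"no valid stress minutes in {period} period")
    return values


def stress_category_proportions(
    stream: MinuteStream, cycle: SleepCycle, period: str
) -> Composition:
    """Share of period minutes in each of the four equidistant stress bands.

    Bands are closed on integer stress: [0,25], [26,50], [51,75], [76,100];
    real-valued stress is floored before classification.
    """
    values = np.floor(_period_stress(stream, cycle, period))
    classes = np.searchsorted(_STRESS_EDGES, values, side="left")
    counts = np.bincount(classes, minlength=4).astype(float)
    return Composition(STRESS_CLASS_LABELS, counts / counts.sum(), baseline="low")


def stress_summary(stream: MinuteStream, cycle: SleepCycle, period: str) -> StressSummary:
    """Summary statistics of the stress level over one period of the day.

    Missing stress minutes are excluded from every statistic.  The standard
    deviation is the sample SD (ddof=1), defined as 0 for a single minute.
    """
    values = _period_stress(stream, cycle, period)
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return StressSummary(
        period=period,
        n_minutes=len(values),
        mean=float(np.mean(values)),
        sd=sd,
        min=float(np.min(values)),
        max=float(np.max(values)),
        median=float(np.median(values)),
        category_proportions=stress_category_proportions(stream, cycle, period),
    )


def merge_components(comp: Composition, merge_map: Mapping[str, Sequence[str]]) -> Composition:
    """Aggregate composition parts according to a partition of the labels."""
    return comp.merge(merge_map)


def active_hours(stream: MinuteStream) -> float:
    """Sum of active and highly-active time in hours (15-min epochs x 0.25)."""
    n = int(np.sum(np.isin(stream.activity, ACTIVE_CLASSES)))
    return n * EPOCH_MINUTES / 60.0


def derive_daily_markers(streams: Iterable[MinuteStream]) -> pd.DataFrame:
    """One row of daily features per subject-night.

    Nights without any detected sleep yield NaN sleep/stress columns so the
    preprocessing exclusion step can drop them.  ``average_daily_stress`` is
    the awake-period mean stress.
    """
    rows = []
    for stream in streams:
        row: dict = {"subject_id": stream.subject_id, "date": stream.date}
        try:
            cycle = identify_sleep_cycle(stream)
        except NoSleepDetected:
            rows.append(row)
            continue
        sc = stage_proportions(stream, cycle)
        for lab in STAGE_LABELS:
            row[f"prop_{lab}"] = sc.proportions[lab]
        row["total_sleep_minutes"] = sc.total_sleep_minutes
        for period in ("asleep", "awake"):
            try:
                summ = stress_summary(stream, cycle, period)
            except EmptyPeriod:
                continue
            for stat in ("mean", "sd", "min", "max", "median"):
                row[f"{period}_stress_{stat}"] = getattr(summ, stat)
            if period == "asleep":
                for lab in STRESS_CLASS_LABELS:
                    row[f"stress_{lab}"] = summ.category_proportions[lab]
            else:
                row["average_daily_stress"] = summ.mean
        row["active_hours"] = active_hours(stream)
        rows.append(row)
    return pd.DataFrame(rows)
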