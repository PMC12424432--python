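"""From daily records to a clean model frame.

Implements the data-preparation rules of the analysis: exclusion of subjects
with incomplete sleep data, conditional mean imputation of questionnaire
answers (by subject and weekend indicator), correlation-based predictor
pruning, alcohol-category merging with one-hot encoding, centering of age
and average daily stress at 30, Laplace smoothing and the ALR transform of
the compositional outcomes.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .compositional import alr_matrix

__all__ = [
    "ModelFrame",
    "ImputationImpossible",
    "QUESTIONNAIRE_COLUMNS",
    "COEF_LABELS",
    "SLEEP_OUTCOME_LABELS",
    "STRESS_OUTCOME_LABELS",
    "derive_weekend_flag",
    "exclude_incomplete_subjects",
    "impute_missing",
    "prune_correlated",
    "encode_predictors",
    "build_model_frame",
]

#: questionnaire-sourced numeric fields eligible for imputation
QUESTIONNAIRE_COLUMNS = (
    "hours_worked",
    "subjective_evening_stress",
    "subjective_evening_energy",
)

#: fixed-effect design columns, in reporting order
COEF_LABELS = (
    "(Intercept)",
    "Age-30",
    "Low alcohol intake",
    "Moderate alcohol intake",
    "Hours worked",
    "Subjective evening stress",
    "Subjective evening energy",
    "Active hours",
    "Average daily stress-30",
)

SLEEP_COMPONENTS = ("awake", "light", "deep", "rem")
SLEEP_OUTCOME_LABELS = ("Deep/Light", "REM/Light", "Awake/Light")
STRESS_COMPONENTS = ("low", "medium", "high", "highest")
STRESS_OUTCOME_LABELS = ("Medium/Low", "High/Low")

ALCOHOL_CATEGORIES = ("none", "low", "moderate", "high")


class ImputationImpossible(ValueError):
    """A questionnaire field is missing for every record."""


@dataclass(frozen=True)
class ModelFrame:
    """Assembled outcome / design / grouping matrices for the mixed model.

    Attributes
    ----------
    Y : (n_obs, D-1) ALR-transformed outcomes.
    X : (n_obs, p) fixed-effect design with a leading intercept column.
    subject_codes : (n_obs,) integer codes 0..n_subjects-1 in first-appearance
        order; the implicit random-intercept design Z.
    """

    Y: np.ndarray
    X: np.ndarray
    subject_codes: np.ndarray
    subject_ids: tuple[str, ...]
    coef_labels: tuple[str, ...]
    outcome_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        Y = np.asarray(self.Y, dtype=float)
        X = np.asarray(self.X, dtype=float)
        codes = np.asarray(self.subject_codes, dtype=int)
        object.__setattr__(self, "Y", Y)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "subject_codes", codes)
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        object.__setattr__(self, "coef_labels", tuple(self.coef_labels))
        object.__setattr__(self, "outcome_labels", tuple(self.outcome_labels))
        if not (np.all(np.isfinite(Y)) and np.all(np.isfinite(X))):
            raise ValueError("model frame must not contain missing values")
        n = Y.shape[0]
        if X.shape[0] != n or codes.shape != (n,):
            raise ValueError("Y, X and subject_codes must align row-wise")
        if X.shape[1] != len(self.coef_labels):
            raise ValueError("coef_labels must match X columns")
        if Y.shape[1] != len(self.outcome_labels):
            raise ValueError("outcome_labels must match Y columns")
        uniq = np.unique(codes)
        if len(uniq) and not np.array_equal(uniq, np.arange(len(self.subject_ids))):
            raise ValueError("subject codes must be contiguous 0..n_subjects-1")

    @property
    def n_obs(self) -> int:
        return self.Y.shape[0]

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_outcomes(self) -> int:
        return self.Y.shape[1]

    @property
    def n_coef(self) -> int:
        return self.X.shape[1]


def derive_weekend_flag(date) -> bool:
    """True iff the date falls on a Saturday or Sunday."""
    if isinstance(date, str):
        date = pd.Timestamp(date)
    if isinstance(date, (pd.Timestamp, _dt.date)):
        return pd.Timestamp(date).dayofweek >= 5
    raise TypeError(f"cannot interpret {date!r} as a calendar date")


def exclude_incomplete_subjects(records: pd.DataFrame, min_nights: int) -> pd.DataFrame:
    """Drop subjects with fewer than ``min_nights`` valid sleep compositions."""
    if min_nights < 0:
        raise ValueError("min_nights must be >= 0")
    if min_nights == 0:
        return records.copy()
    sleep_cols = [f"prop_{c}" for c in SLEEP_COMPONENTS]
    valid = records[sleep_cols].notna().all(axis=1)
    nights = valid.groupby(records["subject_id"]).sum()
    keep = nights[nights >= min_nights].index
    return records[records["subject_id"].isin(keep)].copy()


def impute_missing(
    records: pd.DataFrame, columns: Sequence[str] = QUESTIONNAIRE_COLUMNS
) -> pd.DataFrame:
    """Conditional mean imputation of questionnaire fields.

    Each missing cell is replaced by the mean of the same field over the
    same subject's records with the same weekend flag; if that stratum is
    empty the fallback chain is: same-subject mean (any flag), global
    same-flag mean, global mean.  Idempotent.
    """
    out = records.copy()
    if "weekend" not in out.columns:
        out["weekend"] = out["date"].map(derive_weekend_flag)
    for col in columns:
        if col not in out.columns:
            continue
        if out[col].isna().all():
            raise ImputationImpossible(f"field {col!r} is missing for every record")
        by_subj_flag = out.groupby(["subject_id", "weekend"])[col].transform("mean")
        by_subj = out.groupby("subject_id")[col].transform("mean")
        by_flag = out.groupby("weekend")[col].transform("mean")
        out[col] = (
            out[col].fillna(by_subj_flag).fillna(by_subj).fillna(by_flag)
        ).fillna(out[col].mean())
    return out


def prune_correlated(
    records: pd.DataFrame,
    threshold: float = 0.75,
    priority: Sequence[str] | None = None,
) -> tuple[list[str], list[dict]]:
    """Greedy correlation pruning of numeric predictors.

    For every pair with \\|Pearson r\\| >= ``threshold`` the lower-priority
    member is dropped (``priority`` is ordered highest first and defaults to
    column order).  Returns the retained list and a report of dropped pairs.
    Constant columns are excluded from the correlation computation with a
    warning and retained.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    if priority is None:
        priority = [
            c for c in records.columns if pd.api.types.is_numeric_dtype(records[c])
        ]
    priority = list(priority)
    data = records[priority]
    constant = [c for c in priority if data[c].nunique(dropna=True) <= 1]
    if constant:
        warnings.warn(
            f"constant columns excluded from correlation pruning: {constant}",
            stacklevel=2,
        )
    active = [c for c in priority if c not in constant]
    corr = data[active].corr()
    retained = list(active)
    report: list[dict] = []
    for i, hi in enumerate(active):
        if hi not in retained:
            continue
        for lo in active[i + 1 :]:
            if lo not in retained:
                continue
            r = corr.loc[hi, lo]
            if np.isfinite(r) and abs(r) >= threshold:
                retained.remove(lo)
                report.append({"kept": hi, "dropped": lo, "r": float(r)})
    return retained + constant, report


def encode_predictors(records: pd.DataFrame) -> tuple[np.ndarray, tuple[str, ...]]:
    """Fixed-effect design matrix in reporting order.

    Columns: intercept; age centered at 30; low / moderate alcohol
    indicators (the rare 'high' answers are recoded to 'moderate'; 'none' is
    the reference); hours worked; subjective evening stress and energy;
    active hours; average daily stress centered at 30.
    """
    alcohol = records["alcohol"].astype(str)
    bad = set(alcohol.unique()) - set(ALCOHOL_CATEGORIES)
    if bad:
        raise ValueError(f"unknown alcohol categories: {sorted(bad)}")
    numeric_cols = [
        "age",
        "hours_worked",
        "subjective_evening_stress",
        "subjective_evening_energy",
        "active_hours",
        "average_daily_stress",
    ]
    if records[numeric_cols].isna().any().any():
        raise ValueError("predictors contain missing values; impute first")
    alcohol = alcohol.replace({"high": "moderate"})
    X = np.column_stack(
        [
            np.ones(len(records)),
            records["age"].to_numpy(float) - 30.0,
            (alcohol == "low").to_numpy(float),
            (alcohol == "moderate").to_numpy(float),
            records["hours_worked"].to_numpy(float),
            records["subjective_evening_stress"].to_numpy(float),
            records["subjective_evening_energy"].to_numpy(float),
            records["active_hours"].to_numpy(float),
            records["average_daily_stress"].to_numpy(float) - 30.0,
        ]
    )
    return X, COEF_LABELS


def _laplace_smooth_rows(values: np.ndarray, lam: float) -> np.ndarray:
    if lam < 0:
        raise ValueError("smoothing constant must be >= 0")
    D = values.shape[1]
    return (values + lam) / (1.0 + D * lam)


def build_model_frame(
    records: pd.DataFrame,
    outcome: str = "sleep",
    baseline: str | None = None,
    lam: float = 0.01,
    merge_stress: bool = True,
) -> ModelFrame:
    """Assemble Y (smoothed + ALR outcomes), X and the subject index.

    For the sleep outcome the 4-part stage composition against the light
    baseline yields 3 ALR columns (deep, REM, awake vs light).  For the
    stress outcome the two upper bands are merged first (low/medium/high
    against the low baseline), yielding 2 ALR columns.
    """
    def _pretty(c: str) -> str:
        return "REM" if c == "rem" else c.capitalize()

    if outcome == "sleep":
        components = list(SLEEP_COMPONENTS)
        cols = [f"prop_{c}" for c in components]
        values = records[cols].to_numpy(float)
        baseline = baseline or "light"
        order = [c for c in ("deep", "rem", "awake", "light") if c != baseline]
        labels = tuple(f"{_pretty(c)}/{_pretty(baseline)}" for c in order)
    elif outcome == "stress":
        components = [
            c for c in STRESS_COMPONENTS if f"stress_{c}" in records.columns
        ]
        cols = [f"stress_{c}" for c in components]
        values = records[cols].to_numpy(float)
        if "highest" not in components:
            # already-merged 3-part input: nothing to fold into 'high'
            merge_stress = False
        if merge_stress:
            values = np.column_stack(
                [values[:, 0], values[:, 1], values[:, 2] + values[:, 3]]
            )
            components = ["low", "medium", "high"]
        baseline = baseline or "low"
        order = [
            c
            for c in ("medium", "high", "highest", "low")
            if c in components and c != baseline
        ]
        labels = tuple(
            f"{c.capitalize()}/{baseline.capitalize()}" for c in order
        )
    else:
        raise ValueError(f"outcome must be 'sleep' or 'stress', got {outcome!r}")
    if baseline not in components:
        raise ValueError(f"baseline {baseline!r} not a component of {components}")
    if np.isnan(values).any():
        raise ValueError("outcome compositions contain missing values")

    smoothed = _laplace_smooth_rows(values, lam)
    smoothed /= smoothed.sum(axis=1, keepdims=True)
    y_raw = alr_matrix(smoothed, components.index(baseline))
    nonbase = [c for c in components if c != baseline]
    y = y_raw[:, [nonbase.index(c) for c in order if c != baseline]]

    X, coef_labels = encode_predictors(records)
    subject_ids = list(dict.fromkeys(records["subject_id"]))
    code_of = {s: i for i, s in enumerate(subject_ids)}
    codes = records["subject_id"].map(code_of).to_numpy(int)
    return ModelFrame(
        Y=y,
        X=X,
        subject_codes=codes,
        subject_ids=tuple(str(s) for s in subject_ids),
        coef_labels=coef_labels,
        outcome_labels=labels,
    )
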