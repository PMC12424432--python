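"""Synthetic study generator with known ground truth.

Emulates the structure of a one-week wearable study of academic workers:
~16 subjects x ~7 nights, daily questionnaire covariates (alcohol intake,
hours worked, subjective evening stress/energy, active hours, average daily
stress), 4-part sleep-stage compositions and zero-inflatable nocturnal
stress-category compositions, plus minute-level wearable streams.  Outcomes
are drawn from the random-intercept model run in the generative direction
(Y = X beta + Z u + eps on the ALR scale, mapped back to the simplex), so
every downstream stage — marker derivation, preprocessing, model fitting,
recovery scoring — is testable without any real data.

Default effect sizes, intercepts and random-intercept SDs mirror the
magnitudes reported for the sleep and nocturnal-stress outcomes of the
motivating study; the residual SD, not reported there, defaults to 0.5 per
ALR dimension (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date as _date, timedelta


import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .compositional import alr_inverse_matrix
from .markers import MinuteStream
from .preprocess import (
    COEF_LABELS,
    QUESTIONNAIRE_COLUMNS,
    SLEEP_OUTCOME_LABELS,
    STRESS_OUTCOME_LABELS,
    derive_weekend_flag,
    encode_predictors,
)

__all__ = [
    "ConfigError",
    "CovariateSpec",
    "GeneratorConfig",
    "SyntheticTruth",
    "DEFAULT_BETA_SLEEP",
    "DEFAULT_BETA_STRESS",
    "sleep_config",
    "stress_config",
    "generate_covariates",
    "generate_compositions",
    "generate_minute_streams",
    "inject_missingness",
    "generate_dataset",
]


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


ALCOHOL_LEVELS = ("none", "low", "moderate", "high")

#: generating fixed effects for the sleep outcome, rows in COEF_LABELS order,
#: columns (Deep/Light, REM/Light, Awake/Light)
DEFAULT_BETA_SLEEP = np.array(
    [
        [-1.97, -1.39, -4.44],
        [-0.03, 0.02, 0.00],
        [0.37, -0.19, 0.04],
        [0.29, -0.55, -0.16],
        [0.01, 0.02, 0.00],
        [0.00, 0.04, 0.00],
        [-0.02, -0.01, 0.04],
        [0.12, 0.03, 0.00],
        [-0.03, 0.01, 0.00],
    ]
)

#: generating fixed effects for the merged nocturnal-stress outcome,
#: columns (Medium/Low, High/Low)
DEFAULT_BETA_STRESS = np.array(
    [
        [-6.18, -9.06],
        [0.03, 0.00],
        [0.58, -0.80],
        [1.28, 1.73],
        [0.11, 0.07],
        [-0.37, -0.21],
        [0.19, 0.15],
        [0.09, 0.14],
        [0.06, 0.05],
    ]
)


@dataclass(frozen=True)
class CovariateSpec:
    """Distribution parameters for the daily covariates.

    Ranges bracket the study population: working adults aged 24-44 with a
    roughly one-hour daily activity budget and mid-scale daytime stress.
    """

    age_range: tuple[int, int] = (24, 44)
    alcohol_probs: tuple[float, float, float, float] = (0.5, 0.25, 0.2, 0.05)
    hours_worked_mean: float = 8.0
    hours_worked_sd: float = 2.5
    hours_worked_range: tuple[float, float] = (0.0, 14.0)
    scale_range: tuple[int, int] = (1, 10)
    active_hours_mean: float = 1.5
    active_hours_sd: float = 1.0
    active_hours_range: tuple[float, float] = (0.0, 6.0)
    daily_stress_mean: float = 35.0
    daily_stress_sd: float = 15.0
    daily_stress_range: tuple[float, float] = (0.0, 100.0)

    def __post_init__(self) -> None:
        if abs(sum(self.alcohol_probs) - 1.0) > 1e-9:
            raise ConfigError("alcohol_probs must sum to 1")
        if any(p < 0 for p in self.alcohol_probs):
            raise ConfigError("alcohol_probs must be non-negative")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of one synthetic study.

    ``beta_true`` is on the ALR scale with rows in the encoded-predictor
    order and one column per ALR outcome dimension (``alr_order`` names the
    non-baseline components, ``outcome_components`` and ``baseline`` define
    the simplex the inverse transform maps onto).
    """

    n_subjects: int = 16
    days_per_subject: int = 7
    beta_true: np.ndarray = field(default_factory=lambda: DEFAULT_BETA_SLEEP.copy())
    sigma_u_true: tuple[float, ...] = (0.88, 0.68, 0.65)
    sigma_e_true: tuple[float, ...] = (0.5, 0.5, 0.5)
    covariate_spec: CovariateSpec = field(default_factory=CovariateSpec)
    zero_inflation_prob: float = 0.0
    max_missing_per_subject: int = 3
    seed: int = 0
    outcome_components: tuple[str, ...] = ("awake", "light", "deep", "rem")
    baseline: str = "light"
    alr_order: tuple[str, ...] = ("deep", "rem", "awake")
    outcome_labels: tuple[str, ...] = SLEEP_OUTCOME_LABELS
    column_prefix: str = "prop_"
    start_date: _date = _date(2021, 8, 16)
    night_minutes: int = 480
    evening_awake_minutes: int = 30
    morning_awake_minutes: int = 30
    stress_missing_prob: float = 0.02
    activity_probs: tuple[float, float, float] = (0.70, 0.22, 0.08)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be >= 2")
        if self.days_per_subject < 1:
            raise ConfigError("days_per_subject must be >= 1")
        beta = np.asarray(self.beta_true, dtype=float)
        object.__setattr__(self, "beta_true", beta)
        K = len(self.alr_order)
        if beta.ndim != 2 or beta.shape[1] != K:
            raise ConfigError(
                f"beta_true must have {K} columns (one per ALR dimension)"
            )
        for name in ("sigma_u_true", "sigma_e_true"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (K,):
                raise ConfigError(f"{name} must have length {K}")
            if np.any(v < 0):
                raise ConfigError(f"{name} must be non-negative")
        if not 0.0 <= self.zero_inflation_prob <= 1.0:
            raise ConfigError("zero_inflation_prob must lie in [0, 1]")
        if self.max_missing_per_subject < 0:
            raise ConfigError("max_missing_per_subject must be >= 0")
        if self.baseline not in self.outcome_components:
            raise ConfigError("baseline must be one of outcome_components")
        if sorted(self.alr_order) != sorted(
            c for c in self.outcome_components if c != self.baseline
        ):
            raise ConfigError("alr_order must list the non-baseline components")


def sleep_config(**overrides) -> GeneratorConfig:
    """Study-default configuration for the sleep-stage outcome."""
    return GeneratorConfig(**overrides)


def stress_config(**overrides) -> GeneratorConfig:
    """Study-default configuration for the merged nocturnal-stress outcome.

    Generates 3-part (low/medium/high) compositions with occasional exact
    zeros in the minor components, emulating the zero-inflated time in the
    upper nocturnal stress bands.
    """
    defaults = dict(
        beta_true=DEFAULT_BETA_STRESS.copy(),
        sigma_u_true=(2.64, 2.29),
        sigma_e_true=(1.0, 1.0),
        zero_inflation_prob=0.15,
        outcome_components=("low", "medium", "high"),
        baseline="low",
        alr_order=("medium", "high"),
        outcome_labels=STRESS_OUTCOME_LABELS,
        column_prefix="stress_",
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one generated dataset, for recovery scoring."""

    beta_true: np.ndarray
    u_true: np.ndarray
    sigma_u_true: np.ndarray
    sigma_e_true: np.ndarray
    seed: int
    coef_labels: tuple[str, ...] = COEF_LABELS
    outcome_labels: tuple[str, ...] = SLEEP_OUTCOME_LABELS


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _truncated_normal(rng, mean, sd, lo, hi, size) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_covariates(config: GeneratorConfig) -> pd.DataFrame:
    """Daily covariate table: one row per subject-day, age constant within
    subject, all numeric covariates within their configured ranges."""
    rng = _rng(config, 0)
    spec = config.covariate_spec
    n_days = config.days_per_subject
    rows = []
    for i in range(config.n_subjects):
        sid = f"S{i + 1:03d}"
        age = int(rng.integers(spec.age_range[0], spec.age_range[1] + 1))
        alcohol = rng.choice(ALCOHOL_LEVELS, size=n_days, p=spec.alcohol_probs)
        hours = _truncated_normal(
            rng, spec.hours_worked_mean, spec.hours_worked_sd, *spec.hours_worked_range,
            size=n_days,
        )
        stress_scale = rng.integers(
            spec.scale_range[0], spec.scale_range[1] + 1, size=n_days
        )
        energy_scale = rng.integers(
            spec.scale_range[0], spec.scale_range[1] + 1, size=n_days
        )
        active = _truncated_normal(
            rng, spec.active_hours_mean, spec.active_hours_sd,
            *spec.active_hours_range, size=n_days,
        )
        daily_stress = _truncated_normal(
            rng, spec.daily_stress_mean, spec.daily_stress_sd,
            *spec.daily_stress_range, size=n_days,
        )
        for j in range(n_days):
            day = config.start_date + timedelta(days=j)
            rows.append(
                {
                    "subject_id": sid,
                    "date": pd.Timestamp(day),
                    "weekend": derive_weekend_flag(day),
                    "age": age,
                    "alcohol": str(alcohol[j]),
                    "hours_worked": float(hours[j]),
                    "subjective_evening_stress": int(stress_scale[j]),
                    "subjective_evening_energy": int(energy_scale[j]),
                    "active_hours": float(active[j]),
                    "average_daily_stress": float(daily_stress[j]),
                }
            )
    return pd.DataFrame(rows)


def generate_compositions(
    covariates: pd.DataFrame, config: GeneratorConfig
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Model-based compositional outcomes with known ground truth.

    Runs the mixed model in the generative direction — ALR outcome
    Y = X beta + u[subject] + eps — then maps each row onto the simplex by
    the inverse ALR.  With ``zero_inflation_prob`` > 0 a random subset of
    rows has its smallest non-baseline component forced to an exact zero
    (then renormalised), exercising the Laplace-smoothing path downstream.
    """
    rng = _rng(config, 1)
    X, _ = encode_predictors(covariates)
    beta = config.beta_true
    if X.shape[1] != beta.shape[0]:
        raise ConfigError(
            f"beta_true has {beta.shape[0]} rows but the encoded design has "
            f"{X.shape[1]} columns"
        )
    K = beta.shape[1]
    subject_ids = list(dict.fromkeys(covariates["subject_id"]))
    codes = covariates["subject_id"].map(
        {s: i for i, s in enumerate(subject_ids)}
    ).to_numpy(int)
    J = len(subject_ids)
    sigma_u = np.asarray(config.sigma_u_true, dtype=float)
    sigma_e = np.asarray(config.sigma_e_true, dtype=float)
    u = rng.standard_normal((J, K)) * sigma_u
    eps = rng.standard_normal((len(covariates), K)) * sigma_e
    Y = X @ beta + u[codes] + eps

    # reorder ALR columns from alr_order to label order (baseline skipped)
    components = list(config.outcome_components)
    nonbase = [c for c in components if c != config.baseline]
    Y_labelorder = Y[:, [list(config.alr_order).index(c) for c in nonbase]]
    values = alr_inverse_matrix(Y_labelorder, components.index(config.baseline))

    if config.zero_inflation_prob > 0:
        inflate = rng.random(len(values)) < config.zero_inflation_prob
        nonbase_idx = [k for k, c in enumerate(components) if c != config.baseline]
        for r in np.flatnonzero(inflate):
            k = nonbase_idx[int(np.argmin(values[r, nonbase_idx]))]
            values[r, k] = 0.0
            values[r] /= values[r].sum()

    out = covariates[["subject_id", "date"]].copy()
    for k, c in enumerate(components):
        out[f"{config.column_prefix}{c}"] = values[:, k]
    truth = SyntheticTruth(
        beta_true=beta.copy(),
        u_true=u,
        sigma_u_true=sigma_u,
        sigma_e_true=sigma_e,
        seed=config.seed,
        coef_labels=COEF_LABELS,
        outcome_labels=tuple(config.outcome_labels),
    )
    return out, truth


def _largest_remainder_counts(proportions: np.ndarray, total: int) -> np.ndarray:
    scaled = proportions * total
    counts = np.floor(scaled).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(scaled - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def generate_minute_streams(
    config: GeneratorConfig, target_profiles: pd.DataFrame
) -> list[MinuteStream]:
    """Minute-level streams whose per-night stage counts match the target
    sleep compositions to within rounding.

    Each night is ``night_minutes`` long with stages laid out as contiguous
    blocks (light, deep, REM) and the awake allocation inserted as a single
    mid-night awakening, flanked by awake lead-in/out periods outside the
    sleep-wake cycle.  Asleep stress is drawn low, awake stress higher, a
    small fraction of stress minutes is missing, and activity classes are
    sampled per 15-minute epoch.
    """
    if config.night_minutes < 60:
        raise ConfigError("night_minutes must be >= 60")
    rng = _rng(config, 2)
    streams = []
    for _, row in target_profiles.iterrows():
        props = np.array([row[f"prop_{c}"] for c in ("awake", "light", "deep", "rem")])
        counts = _largest_remainder_counts(props / props.sum(), config.night_minutes)
        n_awake, n_light, n_deep, n_rem = counts
        sleep_seq = ["light"] * n_light + ["deep"] * n_deep + ["rem"] * n_rem
        if not sleep_seq:
            raise ConfigError(
                "target profile has no sleep minutes; cannot build a night"
            )
        mid = min(max(len(sleep_seq) // 2, 1), len(sleep_seq) - 1) if len(sleep_seq) > 1 else 1
        night = sleep_seq[:mid] + ["awake"] * n_awake + sleep_seq[mid:]
        stages = (
            ["awake"] * config.evening_awake_minutes
            + night
            + ["awake"] * config.morning_awake_minutes
        )
        n = len(stages)
        start = pd.Timestamp(row["date"]) + pd.Timedelta(hours=23, minutes=30) - pd.Timedelta(
            minutes=config.evening_awake_minutes
        )
        times = pd.date_range(start, periods=n, freq="min")
        asleep = np.isin(stages, ("light", "deep", "rem"))
        stress = np.where(
            asleep,
            rng.normal(20.0, 8.0, size=n),
            rng.normal(45.0, 12.0, size=n),
        )
        stress = np.clip(np.round(stress), 0, 100)
        missing = rng.random(n) < config.stress_missing_prob
        stress = stress.astype(float)
        stress[missing] = np.nan
        activity = rng.choice(
            ["sedentary", "active", "highly_active"],
            size=n // 15,
            p=config.activity_probs,
        )
        streams.append(
            MinuteStream(
                subject_id=str(row["subject_id"]),
                date=pd.Timestamp(row["date"]),
                times=times,
                stages=np.array(stages, dtype=object),
                stress=stress,
                activity=activity,
            )
        )
    return streams


def inject_missingness(records: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Blank up to ``max_missing_per_subject`` questionnaire cells per subject.

    Only the numeric questionnaire fields are affected (a mean-imputation
    target must have a mean).  Deterministic given the config seed.
    """
    rng = _rng(config, 3)
    out = records.copy()
    cols = [c for c in QUESTIONNAIRE_COLUMNS if c in out.columns]
    if not cols or config.max_missing_per_subject == 0:
        return out
    out[cols] = out[cols].astype(float)
    for sid, idx in out.groupby("subject_id").groups.items():
        cells = [(i, c) for i in idx for c in cols]
        if config.max_missing_per_subject > len(cells):
            raise ConfigError(
                "max_missing_per_subject exceeds available questionnaire cells "
                f"for subject {sid}"
            )
        k = int(rng.integers(0, config.max_missing_per_subject + 1))
        for pick in rng.choice(len(cells), size=k, replace=False):
            i, c = cells[int(pick)]
            out.loc[i, c] = np.nan
    return out


def generate_dataset(
    config: GeneratorConfig, with_missingness: bool = True
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Covariates + model-based compositions merged into one daily table."""
    cov = generate_covariates(config)
    comps, truth = generate_compositions(cov, config)
    records = cov.merge(comps, on=["subject_id", "date"])
    if with_missingness and config.max_missing_per_subject > 0:
        records = inject_missingness(records, config)
    return records, truth
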