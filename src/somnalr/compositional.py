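"""Simplex machinery: compositions, Laplace (additive) smoothing, and the
additive log-ratio (ALR) transform with a configurable baseline component.

A *composition* is a point on the D-part simplex: a vector of non-negative
proportions that sum to one.  Sleep-stage profiles (awake/light/deep/REM)
and nocturnal stress-category profiles are compositions.  The ALR transform
maps a strictly positive D-part composition to D-1 unconstrained log-ratios
against a designated baseline component,

    alr(p)_i = ln(p_i / p_baseline),

which is the coordinate system in which the regression model operates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "Composition",
    "CompositionError",
    "DomainError",
    "laplace_smooth",
    "alr_transform",
    "alr_inverse",
    "alr_matrix",
    "alr_inverse_matrix",
]

_SUM_ATOL = 1e-8


class CompositionError(ValueError):
    """Invalid composition (negative parts, bad sum, unknown baseline...)."""


class DomainError(CompositionError):
    """Operation applied outside its domain (e.g. ALR of a zero part)."""


@dataclass(frozen=True)
class Composition:
    """A labeled point on the D-simplex with a designated baseline part.

    Parameters
    ----------
    labels : ordered component names, length D >= 2.
    values : non-negative proportions summing to 1 (within 1e-8 on input;
        internally renormalised exactly).
    baseline : the component used as the ALR denominator.
    """

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=True)
    baseline: str

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", values)
        if len(labels) < 2:
            raise CompositionError("a composition needs at least 2 parts")
        if len(labels) != len(set(labels)):
            raise CompositionError(f"duplicate labels: {labels}")
        if values.shape != (len(labels),):
            raise CompositionError(
                f"values shape {values.shape} does not match {len(labels)} labels"
            )
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise CompositionError(f"parts must be finite and non-negative: {values}")
        total = values.sum()
        if abs(total - 1.0) > _SUM_ATOL:
            raise CompositionError(f"parts must sum to 1, got {total!r}")
        if self.baseline not in labels:
            raise CompositionError(
                f"baseline {self.baseline!r} not among labels {labels}"
            )

    @property
    def D(self) -> int:
        return len(self.labels)

    @property
    def baseline_index(self) -> int:
        return self.labels.index(self.baseline)

    def __getitem__(self, label: str) -> float:
        return float(self.values[self.labels.index(label)])

    def merge(self, merge_map: Mapping[str, Sequence[str]]) -> "Composition":
        """Aggregate components according to a partition of the labels.

        ``merge_map`` maps each output label to the input labels it absorbs;
        together the groups must partition the current labels exactly.  The
        merged component's value is the sum of its inputs, so total mass is
        conserved.  The baseline follows the group that contains it.
        """
        flat = [lab for group in merge_map.values() for lab in group]
        if sorted(flat) != sorted(self.labels):
            raise CompositionError(
                f"merge_map groups {flat} do not partition labels {self.labels}"
            )
        new_labels = tuple(merge_map.keys())
        new_values = np.array(
            [sum(self[lab] for lab in group) for group in merge_map.values()]
        )
        new_baseline = next(
            out for out, group in merge_map.items() if self.baseline in group
        )
        return Composition(new_labels, new_values, new_baseline)


def laplace_smooth(comp: Composition, lam: float) -> Composition:
    """Additive (Laplace) zero replacement: values -> (values + lam) / (1 + D*lam).

    With lam > 0 every part becomes strictly positive, making the composition
    safe for log-ratio transforms; lam = 0 is the identity.  Mass is conserved
    exactly and the map is monotone toward the uniform composition as lam grows.
    """
    if lam < 0:
        raise CompositionError(f"smoothing constant must be >= 0, got {lam}")
    smoothed = (comp.values + lam) / (1.0 + comp.D * lam)
    return Composition(comp.labels, smoothed, comp.baseline)


def alr_transform(comp: Composition) -> np.ndarray:
    """ALR coordinates: ln(p_i / p_baseline) for the D-1 non-baseline parts.

    Components appear in label order with the baseline skipped.  All parts
    must be strictly positive; apply :func:`laplace_smooth` first if the
    composition contains zeros.
    """
    if np.any(comp.values <= 0):
        raise DomainError(
            "ALR requires strictly positive parts; apply laplace_smooth first"
        )
    b = comp.baseline_index
    logs = np.log(comp.values)
    return np.delete(logs - logs[b], b)


def alr_inverse(
    y: np.ndarray, labels: Sequence[str], baseline: str
) -> Composition:
    """Map ALR coordinates back onto the simplex (softmax with a unit baseline).

    Numerically stable for large coordinates via log-sum-exp.  Inverse of
    :func:`alr_transform` on the open simplex to ~1e-15 relative accuracy.
    """
    labels = tuple(labels)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise DomainError(f"ALR coordinates must be finite, got {y}")
    if len(y) != len(labels) - 1:
        raise CompositionError(
            f"expected {len(labels) - 1} coordinates for {len(labels)} labels, got {len(y)}"
        )
    b = labels.index(baseline)
    z = np.insert(y, b, 0.0)  # baseline log-ratio with itself is 0
    values = np.exp(z - logsumexp(z))
    return Composition(labels, values / values.sum(), baseline)


# -- array helpers used by the preprocessing and synthetic-data layers --------


def alr_matrix(values: np.ndarray, baseline_index: int) -> np.ndarray:
    """Row-wise ALR of an (n, D) matrix of strictly positive compositions."""
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise DomainError("ALR requires strictly positive parts")
    logs = np.log(values)
    ratios = logs - logs[:, [baseline_index]]
    return np.delete(ratios, baseline_index, axis=1)


def alr_inverse_matrix(y: np.ndarray, baseline_index: int) -> np.ndarray:
    """Row-wise inverse ALR: (n, D-1) coordinates -> (n, D) compositions."""
    y = np.asarray(y, dtype=float)
    z = np.insert(y, baseline_index, 0.0, axis=1)
    z -= z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
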