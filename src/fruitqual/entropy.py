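"""Entropy weight method: objective indicator weights from data dispersion.

All indicators are first oriented to a common benefit scale in [0, 1]
(:func:`orient`): larger oriented values are always better.  Shannon entropy
of each oriented column's proportion distribution then measures how little
the indicator discriminates between samples; weights are proportional to
``1 - H_j``, so low-entropy (high-dispersion) indicators weigh more.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import Hierarchy, SampleMatrix, ValidationError


@dataclass
class OrientedMatrix:
    """Sample matrix after orientation + min-max scaling; columns span [0, 1]."""

    values: np.ndarray
    columns: list[str]
    sample_ids: list[str]
    transforms: dict[str, str]


def _orient_column(x: np.ndarray, orientation: str, bounds) -> np.ndarray:
    if orientation == "interval":
        lo, hi = bounds
        excess = np.maximum(lo - x, x - hi)
        excess = np.maximum(excess, 0.0)
        m = excess.max()
        if m == 0.0:  # every sample already inside the optimal range
            return np.ones_like(x)
        return 1.0 - excess / m
    span = x.max() - x.min()
    if span == 0.0:  # constant column carries no information
        return np.ones_like(x)
    if orientation == "benefit":
        return (x - x.min()) / span
    if orientation == "cost":
        return (x.max() - x) / span
    raise ValidationError(f"unknown orientation {orientation!r}")


def orient(samples: SampleMatrix, hierarchy: Hierarchy) -> OrientedMatrix:
    """Map every column onto the [0, 1] benefit scale.

    benefit: ``(x - min) / (max - min)``; cost: ``(max - x) / (max - min)``;
    interval with bounds (lo, hi): 1 inside the range, else
    ``1 - max(lo - x, x - hi) / M`` with ``M`` the largest excess in the
    column.  Constant columns (including interval columns with all samples
    in range) become all ones.
    """
    if samples.n_samples < 2:
        raise ValidationError("orientation needs at least 2 samples")
    if samples.columns != hierarchy.indicator_ids:
        raise ValidationError("sample columns are not in canonical hierarchy order")
    out = np.empty_like(samples.values)
    transforms = {}
    for j, ind in enumerate(hierarchy.indicators):
        out[:, j] = _orient_column(samples.values[:, j], ind.orientation, ind.interval_bounds)
        transforms[ind.id] = ind.orientation
    return OrientedMatrix(
        values=out,
        columns=list(samples.columns),
        sample_ids=list(samples.sample_ids),
        transforms=transforms,
    )


@dataclass(frozen=True)
class EntropyResult:
    """Per-indicator Shannon entropy H_j in [0, 1] and objective weights."""

    entropy: dict[str, float]
    objective: dict[str, float]

    def as_vector(self, order: Sequence[str]) -> np.ndarray:
        return np.array([self.objective[i] for i in order])


def _column_entropy(y: np.ndarray) -> float:
    total = y.sum()
    if total == 0.0:  # all-zero column: no information, like a constant
        return 1.0
    if np.ptp(y) == 0.0:  # constant column: uniform proportions, H exactly 1
        return 1.0
    p = y / total
    n = len(y)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)  # 0*ln 0 := 0
    h = -terms.sum() / np.log(n)
    return float(min(max(h, 0.0), 1.0))


def entropy_weights(oriented: OrientedMatrix) -> EntropyResult:
    """Entropy H_j and objective weights beta_j = (1 - H_j) / sum(1 - H_k)."""
    n = oriented.values.shape[0]
    if n < 2:
        raise ValidationError("entropy weights need at least 2 samples")
    H = {c: _column_entropy(oriented.values[:, j]) for j, c in enumerate(oriented.columns)}
    return EntropyResult(entropy=H, objective=objective_from_entropy(H))


def objective_from_entropy(entropy: Mapping[str, float]) -> dict[str, float]:
    """The (1 - H) normalization on its own, usable on published entropy tables."""
    residual = {c: 1.0 - h for c, h in entropy.items()}
    total = sum(residual.values())
    if total <= 0.0:
        raise ValidationError("all indicators have maximal entropy; objective weights undefined")
    return {c: r / total for c, r in residual.items()}
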