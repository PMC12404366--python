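"""Analytic Hierarchy Process: subjective weights from pairwise comparisons.

An expert fills a reciprocal judgment matrix ``A`` on Saaty's 1-9 scale
(``a_ij`` is how much more important criterion ``i`` is than ``j``;
``a_ji = 1/a_ij``).  The weight vector is the normalized principal right
eigenvector of ``A``, obtained here by power iteration — a deterministic
procedure with no randomness, so results are exactly reproducible.  Judgment
consistency is screened with Saaty's consistency ratio
``CR = CI / RI``, ``CI = (lambda_max - k) / (k - 1)``; ``CR <= 0.1`` passes.

Two-level aggregation multiplies each indicator's within-group weight by its
group's weight, yielding global subjective weights that sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import ConsistencyError, Hierarchy, ValidationError, parse_ratio

#: Saaty's random consistency index by matrix size.
RANDOM_INDEX = {
    1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12,
    6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49,
}

CR_THRESHOLD = 0.1
_SCALE_MIN, _SCALE_MAX = 1.0 / 9.0, 9.0


@dataclass(frozen=True)
class JudgmentMatrix:
    """Reciprocal pairwise-comparison matrix on the 1-9 scale."""

    labels: tuple[str, ...]
    entries: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", a)
        k = len(self.labels)
        if a.shape != (k, k):
            raise ValidationError(f"judgment matrix must be {k}x{k}, got {a.shape}")
        if np.any(a <= 0):
            raise ValidationError("judgment matrix entries must be positive")
        if not np.allclose(np.diag(a), 1.0, rtol=1e-9):
            raise ValidationError("judgment matrix diagonal must be all ones")
        if not np.allclose(a * a.T, 1.0, rtol=1e-9):
            i, j = np.unravel_index(np.argmax(np.abs(a * a.T - 1.0)), a.shape)
            raise ValidationError(
                f"matrix is not reciprocal at ({self.labels[i]}, {self.labels[j]}): "
                f"a_ij*a_ji = {a[i, j] * a[j, i]:.6g}"
            )
        tol = 1e-9
        if np.any(a < _SCALE_MIN * (1 - tol)) or np.any(a > _SCALE_MAX * (1 + tol)):
            raise ValidationError("entries must lie within the 1/9..9 scale")

    @property
    def size(self) -> int:
        return len(self.labels)

    @classmethod
    def from_rows(cls, labels: Sequence[str], rows: Sequence[Sequence[object]]) -> "JudgmentMatrix":
        """Build from a full grid; entries may be numbers or fraction strings."""
        a = np.array([[parse_ratio(v) for v in row] for row in rows], dtype=float)
        return cls(tuple(labels), a)

    @classmethod
    def from_upper(cls, labels: Sequence[str], upper: Sequence[Sequence[object]]) -> "JudgmentMatrix":
        """Build from strictly-upper-triangle rows; reciprocity fills the rest.

        ``upper[i]`` holds the entries ``a_{i,i+1} .. a_{i,k-1}``.
        """
        k = len(labels)
        a = np.eye(k)
        if len(upper) != k - 1:
            raise ValidationError(f"expected {k - 1} upper-triangle rows, got {len(upper)}")
        for i, row in enumerate(upper):
            if len(row) != k - 1 - i:
                raise ValidationError(f"upper row {i} must have {k - 1 - i} entries")
            for offset, v in enumerate(row):
                j = i + 1 + offset
                a[i, j] = parse_ratio(v)
                a[j, i] = 1.0 / a[i, j]
        return cls(tuple(labels), a)

    def permuted(self, order: Sequence[str]) -> "JudgmentMatrix":
        """Same judgments with criteria listed in a different order."""
        idx = [self.labels.index(lab) for lab in order]
        return JudgmentMatrix(tuple(order), self.entries[np.ix_(idx, idx)])


@dataclass(frozen=True)
class ConsistencyReport:
    """Saaty consistency diagnostics for one judgment matrix."""

    lambda_max: float
    ci: float
    ri: float
    cr: float
    passed: bool

    @classmethod
    def from_lambda(cls, lambda_max: float, k: int) -> "ConsistencyReport":
        if k <= 2:
            return cls(lambda_max=lambda_max, ci=0.0, ri=RANDOM_INDEX.get(k, 0.0),
                       cr=0.0, passed=True)
        ci = (lambda_max - k) / (k - 1)
        try:
            ri = RANDOM_INDEX[k]
        except KeyError:
            raise ValidationError(f"no random index tabulated for size {k}") from None
        cr = ci / ri
        return cls(lambda_max=lambda_max, ci=ci, ri=ri, cr=cr, passed=cr <= CR_THRESHOLD)


def eigen_weights(
    m: JudgmentMatrix, tol: float = 1e-12, max_iter: int = 100_000
) -> tuple[np.ndarray, ConsistencyReport]:
    """Principal-eigenvector weights by power iteration from the uniform vector.

    Iterates ``w <- A w / sum(A w)`` until successive normalized iterates agree
    to ``tol`` in max norm; ``lambda_max`` is estimated from the final iterate
    as the mean component-wise Rayleigh ratio ``(A w)_i / w_i``.
    """
    a = m.entries
    k = m.size
    w = np.full(k, 1.0 / k)
    for _ in range(max_iter):
        v = a @ w
        v /= v.sum()
        if np.max(np.abs(v - w)) < tol:
            w = v
            break
        w = v
    else:
        raise ValidationError("power iteration did not converge (malformed matrix?)")
    lambda_max = float(np.mean((a @ w) / w))
    return w, ConsistencyReport.from_lambda(lambda_max, k)


def geometric_mean_weights(m: JudgmentMatrix) -> tuple[np.ndarray, ConsistencyReport]:
    """Row-geometric-mean weight extraction (alternative to the eigenvector).

    Agrees with the eigenvector exactly on consistent matrices and on any
    3x3 reciprocal matrix; differs slightly for inconsistent k >= 4.
    """
    g = np.exp(np.log(m.entries).mean(axis=1))
    w = g / g.sum()
    lambda_max = float(np.mean((m.entries @ w) / w))
    return w, ConsistencyReport.from_lambda(lambda_max, m.size)


_METHODS = {"eigen": eigen_weights, "geometric_mean": geometric_mean_weights}


@dataclass(frozen=True)
class SubjectiveWeights:
    """Two-level AHP weights: group, within-group and global (product) weights."""

    group_weights: dict[str, float]
    within_group: dict[str, float]
    global_weights: dict[str, float]
    reports: dict[str, ConsistencyReport]

    def as_vector(self, order: Sequence[str]) -> np.ndarray:
        return np.array([self.global_weights[i] for i in order])


def aggregate_subjective(
    hierarchy: Hierarchy,
    first: JudgmentMatrix,
    groups: Mapping[str, JudgmentMatrix],
    method: str = "eigen",
    strict: bool = True,
) -> SubjectiveWeights:
    """Global subjective weights: within-group weight times group weight.

    ``strict`` turns a failed consistency test (CR > 0.1) into an error;
    otherwise the failure is only recorded in the matrix's report.
    """
    extract = _METHODS[method]
    if set(first.labels) != set(hierarchy.first_level):
        raise ValidationError("first-level matrix labels do not match hierarchy groups")
    missing = set(hierarchy.first_level) - set(groups)
    if missing:
        raise ValidationError(f"missing group judgment matrices: {sorted(missing)}")

    w_first, rep_first = extract(first)
    reports = {"first_level": rep_first}
    if strict and not rep_first.passed:
        raise ConsistencyError(f"first-level matrix fails consistency: CR = {rep_first.cr:.4f}")
    group_weights = dict(zip(first.labels, w_first))

    within: dict[str, float] = {}
    global_w: dict[str, float] = {}
    for g in hierarchy.first_level:
        m = groups[g]
        members = hierarchy.group_members(g)
        if set(m.labels) != set(members):
            raise ValidationError(f"matrix for group {g!r} does not cover its indicators")
        w, rep = extract(m)
        reports[g] = rep
        if strict and not rep.passed:
            raise ConsistencyError(f"group {g!r} matrix fails consistency: CR = {rep.cr:.4f}")
        for lab, wi in zip(m.labels, w):
            within[lab] = float(wi)
            global_w[lab] = float(wi * group_weights[g])

    # canonical indicator order; normalization is exact up to float rounding
    global_w = {i: global_w[i] for i in hierarchy.indicator_ids}
    total = sum(global_w.values())
    global_w = {i: v / total for i, v in global_w.items()}
    return SubjectiveWeights(
        group_weights={g: float(group_weights[g]) for g in hierarchy.first_level},
        within_group=within,
        global_weights=global_w,
        reports=reports,
    )
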