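"""TOPSIS ranking on an oriented decision matrix.

Alternatives are scored by relative closeness ``C = D- / (D+ + D-)`` to the
ideal point, where ``D+``/``D-`` are Euclidean distances to the ideal
(per-column max) and anti-ideal (per-column min) of the weighted, normalized
matrix.  Because orientation has already mapped every column to a benefit
scale, max is always best.  Vector (root-sum-of-squares) normalization is
the default; min-max is available for sensitivity checks.

Conventions: if an alternative is equidistant from both poles because the
matrix is degenerate (``D+ = D- = 0``), its closeness is 0.5; tied scores
share the smaller rank; output ordering breaks score ties by sample id.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .core import Hierarchy, ValidationError
from .entropy import OrientedMatrix
from .fusion import ComprehensiveWeights


@dataclass
class TopsisResult:
    """Closeness scores, ranks and distances for one TOPSIS run."""

    scores: dict[str, float]
    ranks: dict[str, int]
    d_plus: dict[str, float]
    d_minus: dict[str, float]
    weighted: bool

    def as_vector(self, order: Sequence[str] | None = None) -> np.ndarray:
        order = order if order is not None else sorted(self.scores)
        return np.array([self.scores[s] for s in order])

    def top(self) -> str:
        """Best-ranked sample id (ties broken by id)."""
        return min(self.ranks, key=lambda s: (self.ranks[s], s))


def _normalize(values: np.ndarray, normalization: str) -> np.ndarray:
    if normalization == "vector":
        norms = np.sqrt((values**2).sum(axis=0))
        out = np.zeros_like(values)
        nz = norms > 0
        out[:, nz] = values[:, nz] / norms[nz]
        return out
    if normalization == "minmax":
        span = values.max(axis=0) - values.min(axis=0)
        out = np.zeros_like(values)
        nz = span > 0
        out[:, nz] = (values[:, nz] - values.min(axis=0)[nz]) / span[nz]
        return out
    raise ValidationError(f"unknown normalization {normalization!r}")


def topsis_score(
    oriented: OrientedMatrix,
    weights: Mapping[str, float] | None = None,
    normalization: str = "vector",
) -> TopsisResult:
    """Score all samples; ``weights=None`` is the uniform ("before weighting") mode."""
    n, m = oriented.values.shape
    if n < 2:
        raise ValidationError("TOPSIS needs at least 2 samples")
    if weights is None:
        w = np.full(m, 1.0 / m)
        weighted = False
    else:
        w = np.array([weights[c] for c in oriented.columns], dtype=float)
        if np.any(w < 0):
            raise ValidationError("weights must be non-negative")
        if w.sum() == 0:
            raise ValidationError("weights sum to zero")
        w = w / w.sum()
        weighted = True

    v = _normalize(oriented.values, normalization) * w
    ideal = v.max(axis=0)
    anti = v.min(axis=0)
    d_plus = np.sqrt(((v - ideal) ** 2).sum(axis=1))
    d_minus = np.sqrt(((v - anti) ** 2).sum(axis=1))
    denom = d_plus + d_minus
    closeness = np.where(denom > 0, d_minus / np.where(denom > 0, denom, 1.0), 0.5)

    ranks = rankdata(-closeness, method="min").astype(int)
    ids = oriented.sample_ids
    return TopsisResult(
        scores={s: float(c) for s, c in zip(ids, closeness)},
        ranks={s: int(r) for s, r in zip(ids, ranks)},
        d_plus={s: float(d) for s, d in zip(ids, d_plus)},
        d_minus={s: float(d) for s, d in zip(ids, d_minus)},
        weighted=weighted,
    )


def group_scores(
    oriented: OrientedMatrix,
    hierarchy: Hierarchy,
    weights: ComprehensiveWeights | Mapping[str, float] | None = None,
    normalization: str = "vector",
) -> dict[str, TopsisResult]:
    """TOPSIS per first-level group, on that group's columns only.

    In weighted mode each group's weights are renormalized to sum to one
    within the group; ``weights=None`` runs every group uniform.
    """
    wmap = weights.w if isinstance(weights, ComprehensiveWeights) else weights
    results: dict[str, TopsisResult] = {}
    for g in hierarchy.first_level:
        members = hierarchy.group_members(g)
        idx = [oriented.columns.index(c) for c in members]
        sub = OrientedMatrix(
            values=oriented.values[:, idx],
            columns=members,
            sample_ids=list(oriented.sample_ids),
            transforms={c: oriented.transforms[c] for c in members},
        )
        sub_w = None if wmap is None else {c: wmap[c] for c in members}
        results[g] = topsis_score(sub, sub_w, normalization)
    return results
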