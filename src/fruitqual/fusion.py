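"""Fusion of subjective (AHP) and objective (entropy) weights.

The default is the normalized geometric mean
``w_j = sqrt(alpha_j * beta_j) / sum_k sqrt(alpha_k * beta_k)`` — the
standard multiplicative synthesis, whose log-weights average the two
sources.  The normalized plain product
``w_j = alpha_j * beta_j / sum_k alpha_k * beta_k`` is also available; it
amplifies agreement between the two sources much more aggressively.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .ahp import SubjectiveWeights
from .core import ValidationError
from .entropy import EntropyResult

FUSION_METHODS = ("geometric", "product")


@dataclass(frozen=True)
class ComprehensiveWeights:
    """Fused per-indicator weights; sum to one."""

    w: dict[str, float]
    method: str

    def as_vector(self, order: Sequence[str]) -> np.ndarray:
        return np.array([self.w[i] for i in order])


def _coerce(weights) -> Mapping[str, float]:
    if isinstance(weights, SubjectiveWeights):
        return weights.global_weights
    if isinstance(weights, EntropyResult):
        return weights.objective
    return weights


def fuse(alpha, beta, method: str = "geometric") -> ComprehensiveWeights:
    """Combine subjective and objective weights over a common indicator set."""
    a = _coerce(alpha)
    b = _coerce(beta)
    if set(a) != set(b):
        raise ValidationError(
            f"subjective and objective weights cover different indicators: "
            f"{sorted(set(a) ^ set(b))}"
        )
    if method not in FUSION_METHODS:
        raise ValidationError(f"unknown fusion method {method!r}")
    keys = list(a)
    av = np.array([a[k] for k in keys], dtype=float)
    bv = np.array([b[k] for k in keys], dtype=float)
    if np.any(av < 0) or np.any(bv < 0):
        raise ValidationError("weights must be non-negative")
    raw = np.sqrt(av * bv) if method == "geometric" else av * bv
    total = raw.sum()
    if total == 0.0:
        raise ValidationError("all fused weights are zero; indicator sets share no mass")
    return ComprehensiveWeights(w=dict(zip(keys, raw / total)), method=method)
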