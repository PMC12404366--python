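"""Synthetic sample-table generator and packaged study fixtures.

The generator draws per-indicator values from configurable uniform or normal
distributions (optionally clipped to physical ranges) so that the pipeline's
statistical behaviour can be exercised without any real measurements.  The
default pineapple generator emulates the structure the entropy stage expects
from real market data: most indicators vary moderately within plausible
agronomic ranges; the sugar-acid ratio spans both sides of its optimal
interval; and the mechanical-damage ratio is zero for many fruits and spread
out for the rest, giving it the high dispersion (hence large objective
weight) typical of a market survey.

``fixtures()`` returns the packaged study inputs: the 4-group / 15-indicator
pineapple hierarchy, the five expert judgment matrices, and a SYNTHETIC
23-sample stand-in table (the study's raw measurement supplement is not
redistributed with this package).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .ahp import JudgmentMatrix
from .core import (
    Hierarchy,
    SampleMatrix,
    ValidationError,
    default_config_path,
    load_config,
)


@dataclass(frozen=True)
class ColumnDistribution:
    """Sampling recipe for one indicator column.

    kind ``uniform`` uses (low, high); kind ``normal`` uses (mean, sd).
    ``clip`` bounds are applied after sampling (clipping a normal at a
    physical zero is how sparse, zero-inflated columns such as a damage
    ratio are produced).
    """

    kind: str
    a: float
    b: float
    clip: tuple[float | None, float | None] = (None, None)

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "normal"):
            raise ValidationError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "uniform" and not self.a < self.b:
            raise ValidationError(f"uniform needs low < high, got ({self.a}, {self.b})")
        if self.kind == "normal" and self.b < 0:
            raise ValidationError(f"normal needs sd >= 0, got {self.b}")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "uniform":
            x = rng.uniform(self.a, self.b, size=n)
        else:
            x = rng.normal(self.a, self.b, size=n)
        lo, hi = self.clip
        if lo is not None or hi is not None:
            x = np.clip(x, lo if lo is not None else -np.inf,
                        hi if hi is not None else np.inf)
        return x


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for a synthetic sample table."""

    hierarchy: Hierarchy
    distributions: Mapping[str, ColumnDistribution]
    n_samples: int = 23
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValidationError("n_samples must be positive")
        missing = set(self.hierarchy.indicator_ids) - set(self.distributions)
        if missing:
            raise ValidationError(f"no distribution for indicators: {sorted(missing)}")


#: Plausible market-survey ranges per pineapple indicator, in indicator units.
_PINEAPPLE_DISTRIBUTIONS: dict[str, ColumnDistribution] = {
    "freshness": ColumnDistribution("uniform", 5.0, 10.0),
    "peculiar_taste": ColumnDistribution("uniform", 0.0, 6.0),
    "peel_color_l": ColumnDistribution("uniform", 50.0, 75.0),
    # spans both sides of the optimal [8, 20] range so the interval
    # orientation is exercised below, inside and above it
    "sugar_acid_ratio": ColumnDistribution("uniform", 4.0, 30.0),
    "titratable_acid": ColumnDistribution("uniform", 0.3, 1.2),
    "juice_yield": ColumnDistribution("uniform", 45.0, 65.0),
    "moisture": ColumnDistribution("uniform", 80.0, 90.0),
    "polyphenol": ColumnDistribution("uniform", 30.0, 90.0),
    "flavone": ColumnDistribution("uniform", 5.0, 25.0),
    "total_sugar": ColumnDistribution("uniform", 8.0, 16.0),
    "vitamin_c": ColumnDistribution("uniform", 10.0, 60.0),
    "soluble_solids": ColumnDistribution("uniform", 10.0, 18.0),
    # clipped normal puts a point mass at 0: many undamaged fruits, a
    # dispersed tail of damaged ones -> high-dispersion cost column
    "physical_injury": ColumnDistribution("normal", 0.05, 0.15, clip=(0.0, 1.0)),
    "fruit_weight": ColumnDistribution("normal", 1100.0, 250.0, clip=(300.0, None)),
    "edible_rate": ColumnDistribution("uniform", 55.0, 75.0),
}


def pineapple_hierarchy() -> Hierarchy:
    """The packaged 4-group / 15-indicator pineapple index system."""
    hierarchy, _, _, _ = load_config(default_config_path())
    return hierarchy


def pineapple_judgment_matrices() -> tuple[JudgmentMatrix, dict[str, JudgmentMatrix]]:
    """The packaged expert judgment matrices (first level, per group)."""
    _, first, groups, _ = load_config(default_config_path())
    return first, groups


def published_entropy() -> dict[str, float]:
    """Entropy values published for the 23-sample pineapple study."""
    _, _, _, extras = load_config(default_config_path())
    return {k: float(v) for k, v in extras["published_entropy"].items()}


def default_generator_spec(n_samples: int = 23, seed: int = 0) -> GeneratorSpec:
    """Generator spec emulating a pineapple market survey."""
    return GeneratorSpec(
        hierarchy=pineapple_hierarchy(),
        distributions=dict(_PINEAPPLE_DISTRIBUTIONS),
        n_samples=n_samples,
        seed=seed,
    )


def generate(spec: GeneratorSpec) -> SampleMatrix:
    """Draw a reproducible synthetic sample table for the spec's hierarchy."""
    rng = np.random.default_rng(spec.seed)
    ids = spec.hierarchy.indicator_ids
    cols = [spec.distributions[i].sample(rng, spec.n_samples) for i in ids]
    values = np.column_stack(cols)
    sample_ids = [str(i + 1) for i in range(spec.n_samples)]
    return SampleMatrix(sample_ids=sample_ids, values=values, columns=list(ids))


def fixtures(seed: int = 20230915) -> tuple[Hierarchy, dict[str, JudgmentMatrix], SampleMatrix]:
    """Packaged study inputs for tests and demos.

    Returns the pineapple hierarchy, all five judgment matrices keyed by
    ``first_level`` and the group ids, and a SYNTHETIC 23 x 15 sample table
    drawn from :func:`default_generator_spec` — a stand-in with the same
    shape and column semantics as the study's measurement table, not real
    pineapple data.
    """
    hierarchy, first, groups, _ = load_config(default_config_path())
    matrices = {"first_level": first, **groups}
    samples = generate(default_generator_spec(n_samples=23, seed=seed))
    return hierarchy, matrices, samples
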