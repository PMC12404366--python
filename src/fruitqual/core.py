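"""Domain types and I/O for multi-criteria fruit-quality evaluation.

A study is described by a two-level index system (a :class:`Hierarchy` of
first-level criteria groups, each holding second-level indicators with an
orientation), a set of expert pairwise-comparison matrices (see
:mod:`fruitqual.ahp`), and an alternatives-by-indicators measurement table
(:class:`SampleMatrix`).  All of these live in plain text: one YAML config
for the hierarchy plus judgment matrices, and a CSV for the samples.

Indicator order in the hierarchy is the canonical column order: every
matrix, weight vector and score table downstream uses it, and loaders
reorder inputs to it so that column order in user files never matters.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

ORIENTATIONS = ("benefit", "cost", "interval")


class ValidationError(ValueError):
    """An input violates a structural invariant (bad config, bad table)."""


class ConsistencyError(ValueError):
    """A judgment matrix failed the consistency test in strict mode."""


def parse_ratio(value: object) -> float:
    """Parse a judgment-matrix entry; fraction literals like ``1/7`` are exact."""
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str):
        try:
            return float(Fraction(value.strip()))
        except (ValueError, ZeroDivisionError) as exc:
            raise ValidationError(f"cannot parse ratio entry {value!r}") from exc
    raise ValidationError(f"cannot parse ratio entry {value!r}")


@dataclass(frozen=True)
class IndicatorSpec:
    """One second-level indicator of the index system.

    orientation:
        ``benefit`` — larger is better; ``cost`` — smaller is better;
        ``interval`` — best inside ``interval_bounds = (lo, hi)``.
    """

    id: str
    label: str
    group: str
    orientation: str
    interval_bounds: tuple[float, float] | None = None
    units: str = ""

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValidationError(
                f"indicator {self.id!r}: unknown orientation {self.orientation!r}"
            )
        if self.orientation == "interval":
            if self.interval_bounds is None:
                raise ValidationError(
                    f"indicator {self.id!r}: interval orientation requires interval_bounds"
                )
            lo, hi = self.interval_bounds
            if not lo < hi:
                raise ValidationError(
                    f"indicator {self.id!r}: interval bounds must satisfy lo < hi, got ({lo}, {hi})"
                )
        elif self.interval_bounds is not None:
            raise ValidationError(
                f"indicator {self.id!r}: interval_bounds given but orientation is {self.orientation!r}"
            )


@dataclass(frozen=True)
class Hierarchy:
    """Two-level criteria tree; indicator order is the canonical column order."""

    first_level: tuple[str, ...]
    indicators: tuple[IndicatorSpec, ...]

    def __post_init__(self) -> None:
        ids = [ind.id for ind in self.indicators]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate indicator ids: {sorted(dupes)}")
        if len(set(self.first_level)) != len(self.first_level):
            raise ValidationError("duplicate group ids in first_level")
        for ind in self.indicators:
            if ind.group not in self.first_level:
                raise ValidationError(
                    f"indicator {ind.id!r} references unknown group {ind.group!r}"
                )
        for g in self.first_level:
            if not any(ind.group == g for ind in self.indicators):
                raise ValidationError(f"group {g!r} has no indicators")

    @property
    def indicator_ids(self) -> list[str]:
        return [ind.id for ind in self.indicators]

    def indicator(self, indicator_id: str) -> IndicatorSpec:
        for ind in self.indicators:
            if ind.id == indicator_id:
                return ind
        raise KeyError(indicator_id)

    def group_members(self, group: str) -> list[str]:
        """Indicator ids belonging to ``group``, in canonical order."""
        return [ind.id for ind in self.indicators if ind.group == group]


@dataclass
class SampleMatrix:
    """Alternatives-by-indicators measurement table (finite floats, no gaps)."""

    sample_ids: list[str]
    values: np.ndarray  # shape (n_samples, n_indicators), canonical column order
    columns: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("sample values must be a 2-D table")
        n, m = self.values.shape
        if n != len(self.sample_ids):
            raise ValidationError("row count does not match number of sample ids")
        if m != len(self.columns):
            raise ValidationError("column count does not match number of indicators")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            bad = [
                (self.sample_ids[i], self.columns[j])
                for i, j in zip(*np.where(~np.isfinite(self.values)))
            ]
            raise ValidationError(f"non-finite cells at {bad[:5]}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.columns)


def default_config_path() -> Path:
    """Path of the packaged pineapple study config."""
    return Path(importlib.resources.files("fruitqual").joinpath("data/pineapple.yaml"))


def _read_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"config {path} is not a mapping")
    return cfg


def hierarchy_from_dict(cfg: Mapping) -> Hierarchy:
    groups = [g["id"] for g in cfg.get("groups", [])]
    indicators = []
    for entry in cfg.get("indicators", []):
        bounds = entry.get("interval_bounds")
        indicators.append(
            IndicatorSpec(
                id=entry["id"],
                label=entry.get("label", entry["id"]),
                group=entry["group"],
                orientation=entry["orientation"],
                interval_bounds=tuple(float(b) for b in bounds) if bounds else None,
                units=str(entry.get("units", "")),
            )
        )
    return Hierarchy(first_level=tuple(groups), indicators=tuple(indicators))


def load_hierarchy(path: str | Path) -> Hierarchy:
    """Load and validate the index system from a YAML config file."""
    return hierarchy_from_dict(_read_config(path))


def load_config(path: str | Path):
    """Load hierarchy plus judgment matrices (and any reference tables).

    Returns ``(hierarchy, first_level_matrix, group_matrices, extras)`` where
    ``group_matrices`` maps group id to its :class:`~fruitqual.ahp.JudgmentMatrix`
    and ``extras`` holds optional sections such as ``published_entropy``.
    """
    from .ahp import JudgmentMatrix  # local import to avoid a cycle

    cfg = _read_config(path)
    hierarchy = hierarchy_from_dict(cfg)
    matrices_cfg = cfg.get("judgment_matrices", {})
    if "first_level" not in matrices_cfg:
        raise ValidationError("config lacks judgment_matrices.first_level")

    def build(section: Mapping) -> JudgmentMatrix:
        labels = tuple(section["labels"])
        if "rows" in section:
            return JudgmentMatrix.from_rows(labels, section["rows"])
        if "upper" in section:
            return JudgmentMatrix.from_upper(labels, section["upper"])
        raise ValidationError("judgment matrix needs 'rows' or 'upper'")

    first = build(matrices_cfg["first_level"])
    if set(first.labels) != set(hierarchy.first_level):
        raise ValidationError("first_level matrix labels do not match the groups")
    groups = {}
    for g in hierarchy.first_level:
        if g not in matrices_cfg:
            raise ValidationError(f"missing judgment matrix for group {g!r}")
        m = build(matrices_cfg[g])
        if set(m.labels) != set(hierarchy.group_members(g)):
            raise ValidationError(
                f"judgment matrix for group {g!r} does not cover its indicators"
            )
        groups[g] = m
    extras = {k: cfg[k] for k in ("published_entropy", "name") if k in cfg}
    return hierarchy, first, groups, extras


def load_samples(path: str | Path, hierarchy: Hierarchy) -> SampleMatrix:
    """Read a delimited sample table and reorder columns to canonical order.

    The first column holds sample ids; remaining column headers must be
    exactly the hierarchy's indicator ids (any order).
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValidationError("sample table needs an id column plus indicator columns")
    id_col = df.columns[0]
    sample_ids = [str(s) for s in df[id_col]]
    data = df.drop(columns=[id_col])
    return samples_from_dataframe(data, hierarchy, sample_ids)


def samples_from_dataframe(
    data: pd.DataFrame, hierarchy: Hierarchy, sample_ids: Sequence[str] | None = None
) -> SampleMatrix:
    """Validate a DataFrame of measurements against the hierarchy."""
    want = hierarchy.indicator_ids
    have = list(data.columns)
    unknown = [c for c in have if c not in want]
    if unknown:
        raise ValidationError(f"unknown indicator columns: {unknown}")
    missing = [c for c in want if c not in have]
    if missing:
        raise ValidationError(f"missing indicator columns: {missing}")
    data = data[want]
    if sample_ids is None:
        sample_ids = [str(i) for i in data.index]
    try:
        values = data.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric cell in sample table: {exc}") from exc
    return SampleMatrix(sample_ids=list(sample_ids), values=values, columns=list(want))


def write_samples(samples: SampleMatrix, path: str | Path) -> None:
    df = samples.to_dataframe()
    df.index.name = "sample"
    df.to_csv(path)
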