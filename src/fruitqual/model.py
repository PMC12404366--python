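"""End-to-end evaluation model: AHP -> entropy -> fusion -> TOPSIS.

:class:`QualityModel` bundles the study inputs (hierarchy, judgment
matrices, sample table); :meth:`QualityModel.fit` runs the whole chain and
returns :class:`EvaluationResults`, which carries every intermediate weight
vector, the weighted and unweighted scores overall and per group, and the
before/after-weighting correlation diagnostics, plus a ``summary()`` table.

The pipeline is fully deterministic: refitting the same inputs with the same
options reproduces the report bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .ahp import JudgmentMatrix, SubjectiveWeights, aggregate_subjective
from .core import (
    Hierarchy,
    SampleMatrix,
    ValidationError,
    load_config,
    load_samples,
    samples_from_dataframe,
)
from .entropy import EntropyResult, entropy_weights, orient
from .fusion import ComprehensiveWeights, fuse
from .topsis import TopsisResult, group_scores, topsis_score

logger = logging.getLogger("fruitqual")


def pearson(x, y) -> float:
    """Product-moment correlation; constant input is undefined, not zero."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("correlation needs two equal-length vectors")
    if len(x) < 3:
        raise ValidationError("correlation needs at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def spearman(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


@dataclass
class EvaluationResults:
    """Full report of one evaluation run.

    ``correlations`` maps scope ("comprehensive" or a group id) to the
    Pearson r between weighted and unweighted closeness scores; ``None``
    marks an undefined correlation (a constant score vector).
    """

    hierarchy: Hierarchy
    subjective: SubjectiveWeights
    objective: EntropyResult
    comprehensive: ComprehensiveWeights
    overall_weighted: TopsisResult
    overall_unweighted: TopsisResult
    group_weighted: dict[str, TopsisResult]
    group_unweighted: dict[str, TopsisResult]
    correlations: dict[str, float | None]
    spearman_correlations: dict[str, float | None]
    provenance: dict = field(default_factory=dict)

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        ids = self.hierarchy.indicator_ids

        def topsis_dict(t: TopsisResult) -> dict:
            return {
                "scores": t.scores,
                "ranks": t.ranks,
                "d_plus": t.d_plus,
                "d_minus": t.d_minus,
                "weighted": t.weighted,
            }

        return {
            "indicators": ids,
            "groups": list(self.hierarchy.first_level),
            "subjective": {
                "group_weights": self.subjective.group_weights,
                "within_group": self.subjective.within_group,
                "global": self.subjective.global_weights,
                "consistency": {
                    k: {"lambda_max": r.lambda_max, "ci": r.ci, "ri": r.ri,
                        "cr": r.cr, "passed": r.passed}
                    for k, r in self.subjective.reports.items()
                },
            },
            "objective": {
                "entropy": self.objective.entropy,
                "weights": self.objective.objective,
            },
            "comprehensive": {"weights": self.comprehensive.w,
                              "method": self.comprehensive.method},
            "topsis": {
                "overall": {
                    "weighted": topsis_dict(self.overall_weighted),
                    "unweighted": topsis_dict(self.overall_unweighted),
                },
                "groups": {
                    g: {
                        "weighted": topsis_dict(self.group_weighted[g]),
                        "unweighted": topsis_dict(self.group_unweighted[g]),
                    }
                    for g in self.hierarchy.first_level
                },
            },
            "correlations": {"pearson": self.correlations,
                             "spearman": self.spearman_correlations},
            "provenance": self.provenance,
        }

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    # -- presentation --------------------------------------------------
    def weights_frame(self) -> pd.DataFrame:
        ids = self.hierarchy.indicator_ids
        return pd.DataFrame(
            {
                "group": [self.hierarchy.indicator(i).group for i in ids],
                "subjective": [self.subjective.global_weights[i] for i in ids],
                "objective": [self.objective.objective[i] for i in ids],
                "comprehensive": [self.comprehensive.w[i] for i in ids],
            },
            index=pd.Index(ids, name="indicator"),
        )

    def scores_frame(self) -> pd.DataFrame:
        ids = list(self.overall_weighted.scores)
        df = pd.DataFrame(
            {
                "score_weighted": [self.overall_weighted.scores[s] for s in ids],
                "score_unweighted": [self.overall_unweighted.scores[s] for s in ids],
                "rank_weighted": [self.overall_weighted.ranks[s] for s in ids],
                "rank_unweighted": [self.overall_unweighted.ranks[s] for s in ids],
            },
            index=pd.Index(ids, name="sample"),
        )
        return df.sort_values(["rank_weighted", "score_weighted"],
                              ascending=[True, False], kind="mergesort")

    def summary(self, digits: int = 4) -> str:
        """Human-readable report: weights, consistency, scores, correlations."""
        lines = []
        lines.append("Comprehensive fruit-quality evaluation")
        lines.append(f"fusion method: {self.comprehensive.method}; "
                     f"samples: {len(self.overall_weighted.scores)}; "
                     f"indicators: {len(self.hierarchy.indicator_ids)}")
        lines.append("")
        lines.append("Consistency of judgment matrices (CR <= 0.1 passes):")
        for name, r in self.subjective.reports.items():
            lines.append(f"  {name:<12} lambda_max={r.lambda_max:.4f}  "
                         f"CI={r.ci:.4f}  CR={r.cr:.4f}  "
                         f"{'pass' if r.passed else 'FAIL'}")
        lines.append("")
        lines.append("Indicator weights:")
        lines.append(self.weights_frame().round(digits).to_string())
        lines.append("")
        lines.append("Sample scores (TOPSIS closeness, 1 = coincides with ideal):")
        lines.append(self.scores_frame().round(digits).to_string())
        lines.append("")
        lines.append("Correlation of scores before vs after weighting (Pearson):")
        for scope, r in self.correlations.items():
            txt = "undefined" if r is None else f"{r:.{digits}f}"
            lines.append(f"  {scope:<14} r = {txt}")
        return "\n".join(lines)


class QualityModel:
    """Multi-criteria quality-evaluation model for one study.

    Parameters
    ----------
    hierarchy : Hierarchy
        Two-level index system; its indicator order is canonical.
    first_level : JudgmentMatrix
        Pairwise comparisons between the first-level groups.
    group_matrices : mapping of group id to JudgmentMatrix
        Pairwise comparisons within each group.
    samples : SampleMatrix
        Measurements, one row per alternative.
    """

    def __init__(
        self,
        hierarchy: Hierarchy,
        first_level: JudgmentMatrix,
        group_matrices: Mapping[str, JudgmentMatrix],
        samples: SampleMatrix,
    ) -> None:
        self.hierarchy = hierarchy
        self.first_level = first_level
        self.group_matrices = dict(group_matrices)
        self.samples = samples

    @classmethod
    def from_config(cls, config_path, samples=None, samples_path=None) -> "QualityModel":
        """Build from a YAML study config plus a sample table (CSV path,
        DataFrame, or SampleMatrix)."""
        hierarchy, first, groups, _ = load_config(config_path)
        if samples is None and samples_path is None:
            raise ValidationError("provide samples or samples_path")
        if samples is None:
            samples = load_samples(samples_path, hierarchy)
        elif isinstance(samples, pd.DataFrame):
            samples = samples_from_dataframe(samples, hierarchy)
        return cls(hierarchy, first, groups, samples)

    def fit(
        self,
        fusion: str = "geometric",
        normalization: str = "vector",
        ahp_method: str = "eigen",
        strict_consistency: bool = True,
    ) -> EvaluationResults:
        """Run the full evaluation chain and return the report."""
        subjective = aggregate_subjective(
            self.hierarchy, self.first_level, self.group_matrices,
            method=ahp_method, strict=strict_consistency,
        )
        logger.info("subjective weights: %s", subjective.global_weights)
        oriented = orient(self.samples, self.hierarchy)
        objective = entropy_weights(oriented)
        logger.info("entropy sum(1-H) = %.6f",
                    sum(1 - h for h in objective.entropy.values()))
        comprehensive = fuse(subjective, objective, method=fusion)
        logger.info("comprehensive weights (%s): %s", fusion, comprehensive.w)

        overall_w = topsis_score(oriented, comprehensive.w, normalization)
        overall_u = topsis_score(oriented, None, normalization)
        groups_w = group_scores(oriented, self.hierarchy, comprehensive, normalization)
        groups_u = group_scores(oriented, self.hierarchy, None, normalization)

        order = list(self.samples.sample_ids)

        def corr(fn, a: TopsisResult, b: TopsisResult):
            try:
                return fn([a.scores[s] for s in order], [b.scores[s] for s in order])
            except ValidationError:
                return None

        correlations = {"comprehensive": corr(pearson, overall_w, overall_u)}
        spearman_corr = {"comprehensive": corr(spearman, overall_w, overall_u)}
        for g in self.hierarchy.first_level:
            correlations[g] = corr(pearson, groups_w[g], groups_u[g])
            spearman_corr[g] = corr(spearman, groups_w[g], groups_u[g])

        provenance = {
            "version": __version__,
            "fusion": fusion,
            "normalization": normalization,
            "ahp_method": ahp_method,
            "input_hash": self._input_hash(),
        }
        return EvaluationResults(
            hierarchy=self.hierarchy,
            subjective=subjective,
            objective=objective,
            comprehensive=comprehensive,
            overall_weighted=overall_w,
            overall_unweighted=overall_u,
            group_weighted=groups_w,
            group_unweighted=groups_u,
            correlations=correlations,
            spearman_correlations=spearman_corr,
            provenance=provenance,
        )

    def _input_hash(self) -> str:
        h = hashlib.sha256()
        h.update(",".join(self.hierarchy.indicator_ids).encode())
        h.update(self.first_level.entries.tobytes())
        for g in self.hierarchy.first_level:
            h.update(self.group_matrices[g].entries.tobytes())
        h.update(self.samples.values.tobytes())
        return h.hexdigest()[:16]


def run_evaluation(
    hierarchy: Hierarchy,
    first_level: JudgmentMatrix,
    group_matrices: Mapping[str, JudgmentMatrix],
    samples: SampleMatrix,
    fusion: str = "geometric",
    normalization: str = "vector",
    ahp_method: str = "eigen",
    strict_consistency: bool = True,
) -> EvaluationResults:
    """Functional entry point equivalent to ``QualityModel(...).fit(...)``."""
    return QualityModel(hierarchy, first_level, group_matrices, samples).fit(
        fusion=fusion,
        normalization=normalization,
        ahp_method=ahp_method,
        strict_consistency=strict_consistency,
    )


def write_report(results: EvaluationResults, path: str | Path) -> None:
    """Write the machine-readable JSON report and a text summary next to it.

    ``path`` names the JSON file; the summary goes to ``path`` with a
    ``.txt`` suffix.
    """
    if not results.overall_weighted.scores:
        raise ValidationError("report has no scores; nothing to write")
    path = Path(path)
    path.write_text(results.to_json(), encoding="utf-8")
    path.with_suffix(".txt").write_text(results.summary() + "\n", encoding="utf-8")


def read_report(path: str | Path) -> dict:
    """Load a JSON report written by :func:`write_report`."""
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
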