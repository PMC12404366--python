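"""Minimal diagnostic plots: before/after score scatter and weight bars."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .model import EvaluationResults


def plot_score_scatter(results: EvaluationResults, ax=None):
    """Weighted vs unweighted closeness scores, one point per sample."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ids = list(results.overall_weighted.scores)
    x = [results.overall_unweighted.scores[s] for s in ids]
    y = [results.overall_weighted.scores[s] for s in ids]
    ax.scatter(x, y, s=18)
    lo, hi = min(x + y), max(x + y)
    ax.plot([lo, hi], [lo, hi], lw=0.8, ls="--", color="grey")
    r = results.correlations.get("comprehensive")
    ax.set_xlabel("closeness, uniform weights")
    ax.set_ylabel("closeness, comprehensive weights")
    ax.set_title("before vs after weighting" + (f" (r = {r:.3f})" if r is not None else ""))
    return ax


def plot_weights(results: EvaluationResults, ax=None):
    """Grouped bar chart of subjective, objective and comprehensive weights."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3.5))
    df = results.weights_frame()[["subjective", "objective", "comprehensive"]]
    df.plot.bar(ax=ax, width=0.8)
    ax.set_ylabel("weight")
    ax.figure.tight_layout()
    return ax
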