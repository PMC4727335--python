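"""Optional plot output: consensus ROC curves and null-p qq plots.

matplotlib is imported lazily so headless/pipeline use of the package never
pays for it.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .evaluation import ConsensusROC

__all__ = ["plot_consensus_roc", "plot_qq"]


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    _, ax = plt.subplots(figsize=(4.5, 4.5))
    return ax


def plot_consensus_roc(curves: dict, ax=None, fpr_max: float = 1.0):
    """Overlay named consensus ROC curves; returns the matplotlib axes.

    ``curves`` maps a method label to a :class:`ConsensusROC`.
    """
    ax = _axes(ax)
    for label, cons in curves.items():
        keep = cons.fpr_grid <= fpr_max
        ax.plot(cons.fpr_grid[keep], cons.mean_tpr[keep], label=label, lw=1.5)
    ax.plot([0, fpr_max], [0, fpr_max], ls=":", color="grey", lw=1)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_xlim(0, fpr_max)
    ax.set_ylim(0, 1)
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_qq(qq_summary: dict, ax=None, max_replicates: Optional[int] = 50):
    """Replicate qq curves (grey), their mean (black) and the diagonal.

    ``qq_summary`` is the dict returned by
    :func:`dabench.evaluation.qq_uniform_summary`.
    """
    ax = _axes(ax)
    q = qq_summary["quantiles"]
    reps = qq_summary["per_replicate"]
    if max_replicates is not None:
        reps = reps[:max_replicates]
    for row in reps:
        ax.plot(q, row, color="grey", alpha=0.25, lw=0.5)
    ax.plot(q, qq_summary["mean_curve"], color="black", lw=1.5)
    ax.plot([0, 1], [0, 1], ls=":", color="black", lw=1)
    ax.set_xlabel("Uniform quantile")
    ax.set_ylabel("Observed p-value quantile")
    return ax
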