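"""Scoring of method results against ground truth.

Ranking performance is summarized by ROC curves built from p-value-sorted
gene lists (ties advance as one block, drawing a single diagonal segment;
missing p-values rank last), their trapezoid AUC, and the partial AUC up to
a false positive rate of 0.05 normalized by 0.05 (``AUC_0.05``), which
focuses on the top of the ranking.  Replicate curves are combined into a
consensus by point-wise vertical averaging of TPR on a fixed FPR grid.

Calibration diagnostics cover the p-value distribution under the null
(quantile-quantile summaries on subsamples of fixed size, pooled
histograms) and false-discovery-rate behaviour: the Benjamini-Hochberg
estimate ``n * p(k) / k`` (step-up monotonized) against the realized true
FDR ``(# false calls up to rank k) / k``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .da_methods import MethodResult
from .resampler import BenchmarkDataset

__all__ = [
    "ROCCurve",
    "ConsensusROC",
    "FDRTrack",
    "roc_curve",
    "auc",
    "consensus_roc",
    "qq_uniform_summary",
    "bh_adjust",
    "true_fdr_curve",
    "confusion_at_fdr",
    "effect_bias_summary",
    "stratified_evaluate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ROCCurve:
    """An ROC step curve as ordered (FPR, TPR) vertices from (0,0) to (1,1)."""

    fpr: np.ndarray = field(repr=False)
    tpr: np.ndarray = field(repr=False)

    def __post_init__(self):
        fpr = np.asarray(self.fpr, dtype=float)
        tpr = np.asarray(self.tpr, dtype=float)
        if fpr.shape != tpr.shape or fpr.ndim != 1:
            raise ValueError("fpr and tpr must be matching 1-D arrays")
        for name, v in (("fpr", fpr), ("tpr", tpr)):
            if (np.diff(v) < -1e-12).any() or v.min() < -1e-12 or v.max() > 1 + 1e-12:
                raise ValueError(f"{name} must be non-decreasing within [0, 1]")
        fpr.setflags(write=False)
        tpr.setflags(write=False)
        object.__setattr__(self, "fpr", fpr)
        object.__setattr__(self, "tpr", tpr)

    def tpr_at(self, fpr_grid: np.ndarray) -> np.ndarray:
        """Step interpolation: TPR at the largest achieved FPR <= grid value."""
        idx = np.searchsorted(self.fpr, np.asarray(fpr_grid), side="right") - 1
        idx = np.clip(idx, 0, len(self.fpr) - 1)
        return self.tpr[idx]


@dataclass(frozen=True)
class ConsensusROC:
    """Vertical average of replicate ROC curves on a fixed FPR grid."""

    fpr_grid: np.ndarray = field(repr=False)
    mean_tpr: np.ndarray = field(repr=False)
    per_replicate_tpr: np.ndarray = field(repr=False)

    @property
    def n_replicates(self) -> int:
        return self.per_replicate_tpr.shape[0]

    def as_curve(self) -> ROCCurve:
        return ROCCurve(self.fpr_grid, self.mean_tpr)


@dataclass(frozen=True)
class FDRTrack:
    """Estimated and realized FDR along one method's gene ranking.

    All arrays are in rank order (ascending p; missing p last).
    """

    p_ranked: np.ndarray = field(repr=False)
    truth_ranked: np.ndarray = field(repr=False)
    estimated_fdr: np.ndarray = field(repr=False)
    true_fdr: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.p_ranked)


def _rank_order(p: np.ndarray) -> np.ndarray:
    """Stable ascending order with NaN (missing) p-values last."""
    key = np.where(np.isnan(p), np.inf, p)
    return np.argsort(key, kind="stable")


def roc_curve(result: MethodResult, truth: Sequence[bool]) -> ROCCurve:
    """ROC curve of a p-value ranking against per-gene truth flags.

    Genes are sorted by ascending p-value; tied p-values (including all
    missing ones) advance as a single block so the curve gains one diagonal
    segment per tie block.  The curve is anchored at (0, 0) and ends at
    (1, 1).
    """
    truth = np.asarray(truth, dtype=bool)
    p = result.p_value
    if truth.shape != p.shape:
        raise ValueError("truth length does not match result")
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("truth must contain at least one positive and one negative")
    order = _rank_order(p)
    # finite sentinel > 1 keeps all missing p-values in a single tie block
    p_sorted = np.where(np.isnan(p), 2.0, p)[order]
    t_sorted = truth[order]
    # block boundaries: last index of each tie block
    boundary = np.flatnonzero(np.diff(p_sorted) != 0)
    ends = np.concatenate([boundary, [len(p_sorted) - 1]])
    cum_tp = np.cumsum(t_sorted)
    cum_fp = np.cumsum(~t_sorted)
    tpr = np.concatenate([[0.0], cum_tp[ends] / n_pos])
    fpr = np.concatenate([[0.0], cum_fp[ends] / n_neg])
    return ROCCurve(fpr, tpr)


def auc(curve: ROCCurve, fpr_max: float = 1.0, normalized: bool = False) -> float:
    """Trapezoid area under the ROC curve up to ``fpr_max``.

    The curve is linearly interpolated at ``fpr_max``; with ``normalized``
    the area is divided by ``fpr_max`` to lie in [0, 1].
    """
    if not (0 < fpr_max <= 1):
        raise ValueError("fpr_max must lie in (0, 1]")
    fpr, tpr = curve.fpr, curve.tpr
    if fpr_max < fpr[-1]:
        tpr_cut = float(np.interp(fpr_max, fpr, tpr))
        keep = fpr < fpr_max
        fpr = np.concatenate([fpr[keep], [fpr_max]])
        tpr = np.concatenate([tpr[keep], [tpr_cut]])
    area = float(np.trapezoid(tpr, fpr))
    return area / fpr_max if normalized else area


def consensus_roc(curves: List[ROCCurve], grid_size: int = 1001) -> ConsensusROC:
    """Point-wise vertical average of replicate ROC curves.

    Each replicate contributes, at every grid FPR, its TPR at the largest
    achieved FPR not exceeding the grid value (right-continuous step
    interpolation); the consensus TPR is the arithmetic mean across
    replicates.
    """
    if not curves:
        raise ValueError("need at least one ROC curve")
    grid = np.linspace(0.0, 1.0, grid_size)
    per_rep = np.vstack([c.tpr_at(grid) for c in curves])
    return ConsensusROC(grid, per_rep.mean(axis=0), per_rep)


def qq_uniform_summary(
    p_sets: List[np.ndarray],
    subsample_size: int = 1500,
    rng: Optional[np.random.Generator] = None,
    n_bins: int = 20,
):
    """Quantile-quantile summary of replicate p-value sets against Uniform(0,1).

    Each replicate is subsampled without replacement to exactly
    ``subsample_size`` p-values (making replicates of different size
    comparable), sorted, and plotted against the uniform plotting positions
    ``(i - 0.5) / N``; the mean curve is taken across replicates per
    quantile.  Also returns pooled histogram counts over ``n_bins`` equal
    bins of [0, 1].

    Returns a dict with keys ``quantiles``, ``mean_curve``,
    ``per_replicate`` (replicates x N), ``hist_edges``, ``hist_counts``.
    """
    rng = rng or np.random.default_rng()
    sub = []
    for i, p in enumerate(p_sets):
        p = np.asarray(p, dtype=float)
        p = p[~np.isnan(p)]
        if p.size < subsample_size:
            raise ValueError(
                f"replicate {i} has {p.size} p-values, fewer than "
                f"subsample_size={subsample_size}"
            )
        take = rng.choice(p.size, size=subsample_size, replace=False)
        sub.append(np.sort(p[take]))
    per_rep = np.vstack(sub)
    quantiles = (np.arange(1, subsample_size + 1) - 0.5) / subsample_size
    pooled = np.concatenate(sub)
    counts, edges = np.histogram(pooled, bins=n_bins, range=(0.0, 1.0))
    return {
        "quantiles": quantiles,
        "mean_curve": per_rep.mean(axis=0),
        "per_replicate": per_rep,
        "hist_edges": edges,
        "hist_counts": counts,
    }


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (estimated FDR per gene).

    Computes the raw estimator ``n * p(k) / k`` at each rank, applies the
    step-up monotonization (cumulative minimum from the largest rank) and
    caps at 1.  Missing (NaN) p-values are excluded from ``n`` and stay
    missing, as in R's ``p.adjust``.
    """
    p = np.asarray(p, dtype=float)
    finite = p[~np.isnan(p)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    idx = np.flatnonzero(~np.isnan(p))
    if idx.size == 0:
        return out
    n = idx.size
    order = np.argsort(p[idx], kind="stable")
    ranked = p[idx][order]
    raw = n * ranked / np.arange(1, n + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(raw[::-1])[::-1])
    out[idx[order]] = adj
    return out


def true_fdr_curve(result: MethodResult, truth: Sequence[bool]) -> FDRTrack:
    """Estimated (BH) and realized FDR along the p-value ranking.

    The true FDR at rank k is the number of false calls among the top k
    genes divided by k.
    """
    truth = np.asarray(truth, dtype=bool)
    p = result.p_value
    if truth.shape != p.shape:
        raise ValueError("truth length does not match result")
    order = _rank_order(p)
    p_ranked = p[order]
    t_ranked = truth[order]
    k = np.arange(1, len(p) + 1)
    tf = np.cumsum(~t_ranked) / k
    est = bh_adjust(p)[order]
    return FDRTrack(p_ranked, t_ranked, est, tf)


def confusion_at_fdr(
    track: FDRTrack,
    alpha: float = 0.05,
    comparability_subsample: Optional[int] = 1500,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[int, int, float]:
    """True/false positives and realized FDR when calling at estimated FDR <= alpha.

    With ``comparability_subsample`` set, that many genes are drawn without
    replacement (from the ranked lists) and the BH adjustment is recomputed
    on the subsample before thresholding, so replicates with different gene
    counts are comparable; tracks smaller than the subsample are used whole.
    Genes with missing p-values are never called.  Returns
    ``(TP, FP, true_fdr)``; the realized FDR is 0 when nothing is called.
    """
    p = track.p_ranked
    truth = track.truth_ranked
    if comparability_subsample is not None and track.n > comparability_subsample:
        rng = rng or np.random.default_rng()
        take = rng.choice(track.n, size=comparability_subsample, replace=False)
        p = p[take]
        truth = truth[take]
    p = np.where(np.isinf(p), np.nan, p)
    est = bh_adjust(p)
    called = ~np.isnan(est) & (est <= alpha)
    tp = int((called & truth).sum())
    fp = int((called & ~truth).sum())
    realized = fp / (tp + fp) if (tp + fp) else 0.0
    return tp, fp, realized


def effect_bias_summary(
    result: MethodResult,
    dataset: BenchmarkDataset,
    min_pre_effect_mean: float = 0.0,
) -> Tuple[float, float]:
    """Mean and SD of signed log2 effect-size error over the true DA genes.

    Estimates are oriented so that a perfectly recovered effect equals
    ``+log2 q`` regardless of which group was thinned: a gene thinned in
    group 2 should show ``log2_fold_change = -log2 q``, so its estimate is
    negated before comparison.  Null genes are excluded;
    ``min_pre_effect_mean`` additionally restricts to well-observed genes,
    where estimator bias is attributable to the method rather than to
    sampling noise.
    """
    if result.log2_fold_change is None:
        raise ValueError(f"method {result.method_name} reports no effect estimates")
    if tuple(result.gene_ids) != tuple(dataset.matrix.gene_ids):
        raise ValueError("result and dataset gene ids differ")
    g1, g2 = dataset.design.groups
    lfc = result.log2_fold_change
    errors = []
    for i, is_da in enumerate(dataset.truth):
        if not is_da or np.isnan(lfc[i]):
            continue
        if dataset.pre_effect_mean[i] < min_pre_effect_mean:
            continue
        oriented = -lfc[i] if dataset.downsampled_group[i] == g2 else lfc[i]
        errors.append(oriented - np.log2(dataset.true_q[i]))
    if not errors:
        raise ValueError("no DA genes with finite effect estimates")
    errors = np.asarray(errors)
    return float(errors.mean()), float(errors.std(ddof=1)) if errors.size > 1 else 0.0


def stratified_evaluate(
    result: MethodResult, dataset: BenchmarkDataset, fpr_max: float = 0.05
) -> dict:
    """Per-abundance-stratum ROC/AUC from a single full-data run.

    The method's p-values come from the full matrix; only the scoring is
    restricted to each stratum's genes.  Strata lacking positives or
    negatives are skipped with a logged notice.
    """
    if tuple(result.gene_ids) != tuple(dataset.matrix.gene_ids):
        raise ValueError("result and dataset gene ids differ")
    strata = np.asarray(dataset.strata)
    out = {}
    for label in ("low", "mid", "high"):
        mask = strata == label
        if not mask.any():
            continue
        truth = dataset.truth[mask]
        if truth.all() or not truth.any():
            logger.info(
                "stratum %s skipped: no %s genes",
                label,
                "negative" if truth.all() else "positive",
            )
            continue
        sub = MethodResult(
            result.method_name,
            tuple(g for g, m in zip(result.gene_ids, mask) if m),
            result.p_value[mask],
            None,
            None,
        )
        curve = roc_curve(sub, truth)
        out[label] = {
            "curve": curve,
            "auc": auc(curve),
            "auc005": auc(curve, fpr_max=fpr_max, normalized=True),
            "n_pos": int(truth.sum()),
            "n_neg": int((~truth).sum()),
        }
    return out
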