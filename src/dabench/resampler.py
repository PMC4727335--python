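"""Build benchmark datasets from a reference count matrix.

The resampling recipe that produces one benchmark replicate:

1. draw two equally-or-unequally sized groups of samples from the reference,
   uniformly without replacement, and shuffle the column order;
2. filter genes that are too sparse to carry an effect (more than 75 % zero
   cells, or mean count below 3, computed on the resampled columns);
3. stratify the surviving genes into low/mid/high abundance bands on their
   pre-effect mean counts;
4. select a fraction of genes (default 10 %) to be truly differentially
   abundant;
5. inject the effect by binomial thinning: within one group, each count ``y``
   of a selected gene is replaced by an independent ``Binomial(y, 1/q)``
   draw, so the group mean drops by the fold-change ``q`` while the count
   nature (and its zeros) is preserved.

Because thinning only removes fragments, null genes keep their resampled
counts bit-exactly and every thinned cell is bounded by its original value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .counts_io import CountMatrix, GroupDesign

__all__ = [
    "EffectSpec",
    "BenchmarkDataset",
    "sample_groups",
    "apply_filter",
    "select_da_genes",
    "inject_effect",
    "stratify",
    "make_benchmark",
    "STRATUM_PRESETS",
]

#: Abundance-stratification cutoffs (low_hi, mid_hi) used in published
#: evaluations of gut metagenomes.  The deep-shotgun presets use
#: (500, 5000); the pyrosequencing dataset has been stratified both at
#: (50, 500) and (10, 50) — both are provided, neither is canonical.
STRATUM_PRESETS = {
    "illumina": (500.0, 5000.0),
    "pyro": (50.0, 500.0),
    "pyro_alt": (10.0, 50.0),
}

GROUP_A = "A"
GROUP_B = "B"


@dataclass(frozen=True)
class EffectSpec:
    """How effects are injected.

    fold_change : float, > 1
        Effect size ``q``; thinning keep-probability is ``1/q``.
    da_fraction : float in [0, 1)
        Fraction of genes made truly differentially abundant (0 gives a
        null benchmark).
    direction_rule : {"per_gene", "fixed_group"}
        Whether the thinned group is drawn independently per DA gene
        (default; effects in both directions) or once for the dataset.
    """

    fold_change: float = 5.0
    da_fraction: float = 0.10
    direction_rule: str = "per_gene"

    def __post_init__(self):
        if self.fold_change <= 1:
            raise ValueError("fold_change q must be > 1")
        if not (0 <= self.da_fraction < 1):
            raise ValueError("da_fraction must lie in [0, 1)")
        if self.direction_rule not in ("per_gene", "fixed_group"):
            raise ValueError("direction_rule must be 'per_gene' or 'fixed_group'")


@dataclass(frozen=True)
class BenchmarkDataset:
    """One resampled benchmark replicate with ground truth.

    ``matrix`` holds post-filter, post-effect counts; ``truth`` flags the DA
    genes; ``true_q`` is the injected fold-change (1 for null genes);
    ``downsampled_group`` names the thinned group per DA gene (None for null
    genes); ``strata`` labels each gene low/mid/high on its pre-effect mean
    (``pre_effect_mean``).
    """

    matrix: CountMatrix
    design: GroupDesign
    truth: np.ndarray = field(repr=False)
    true_q: np.ndarray = field(repr=False)
    downsampled_group: tuple = field(repr=False)
    strata: tuple = field(repr=False)
    pre_effect_mean: np.ndarray = field(repr=False)

    def __post_init__(self):
        n = self.matrix.n_genes
        for name in ("truth", "true_q", "pre_effect_mean"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match gene count")
        if len(self.downsampled_group) != n or len(self.strata) != n:
            raise ValueError("per-gene annotation length mismatch")

    @property
    def n_da(self) -> int:
        return int(np.sum(self.truth))


def sample_groups(
    reference: CountMatrix, m1: int, m2: int, rng: np.random.Generator
) -> Tuple[CountMatrix, GroupDesign]:
    """Draw ``m1 + m2`` distinct reference columns and assign group labels.

    Columns are chosen uniformly without replacement and their order is
    randomized before the first ``m1`` are labelled group A and the rest
    group B.
    """
    m = m1 + m2
    if m1 < 1 or m2 < 1:
        raise ValueError("both groups must be non-empty")
    if m > reference.n_samples:
        raise ValueError(
            f"cannot draw {m} samples from a {reference.n_samples}-sample reference"
        )
    cols = rng.choice(reference.n_samples, size=m, replace=False)
    matrix = reference.select_samples(cols)
    labels = (GROUP_A,) * m1 + (GROUP_B,) * m2
    design = GroupDesign(matrix.sample_ids, labels)
    return matrix, design


def apply_filter(
    matrix: CountMatrix,
    zero_fraction_max: float = 0.75,
    min_mean: float = 3.0,
    enabled: bool = True,
) -> Tuple[CountMatrix, list]:
    """Remove genes with too many zeros or too low a mean count.

    A gene is removed iff strictly more than ``zero_fraction_max`` of its
    cells are zero, or its mean count is strictly below ``min_mean`` —
    boundary cases (exactly 75 % zeros, mean exactly 3) are kept.  Filter
    statistics are computed on the given (resampled) matrix, not on any
    larger source.  Returns the filtered matrix and the removed gene ids.
    """
    if not enabled:
        return matrix, []
    zero_frac = (matrix.counts == 0).mean(axis=1)
    means = matrix.counts.mean(axis=1)
    keep = (zero_frac <= zero_fraction_max) & (means >= min_mean)
    removed = [g for g, k in zip(matrix.gene_ids, keep) if not k]
    return matrix.select_genes(keep), removed


def select_da_genes(
    gene_ids, da_fraction: float, rng: np.random.Generator
) -> set:
    """Uniformly choose ``round(da_fraction * n)`` genes to carry an effect."""
    gene_ids = list(gene_ids)
    if not (0 < da_fraction < 1):
        raise ValueError("da_fraction must lie in (0, 1)")
    k = round(da_fraction * len(gene_ids))
    if k == 0:
        raise ValueError(
            f"da_fraction {da_fraction} selects zero of {len(gene_ids)} genes"
        )
    chosen = rng.choice(len(gene_ids), size=k, replace=False)
    return {gene_ids[i] for i in chosen}


def inject_effect(
    matrix: CountMatrix,
    da_genes: set,
    spec: EffectSpec,
    design: GroupDesign,
    rng: np.random.Generator,
) -> Tuple[CountMatrix, dict]:
    """Thin the counts of each DA gene within one group by ``Binomial(y, 1/q)``.

    Returns the modified matrix and a map gene id -> thinned group label.
    Cells outside the chosen group, and all null genes, are untouched.
    """
    q = spec.fold_change
    unknown = da_genes - set(matrix.gene_ids)
    if unknown:
        raise ValueError(f"unknown DA genes: {sorted(unknown)[:5]}")
    in_b = design.membership(matrix.sample_ids)
    groups = design.groups
    counts = matrix.counts.copy()
    gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}

    if spec.direction_rule == "fixed_group":
        fixed = groups[int(rng.integers(2))]

    downsampled = {}
    for g in sorted(da_genes):  # sorted for seed-stable iteration
        if spec.direction_rule == "per_gene":
            target = groups[int(rng.integers(2))]
        else:
            target = fixed
        mask = in_b if target == groups[1] else ~in_b
        i = gene_index[g]
        counts[i, mask] = rng.binomial(counts[i, mask], 1.0 / q)
        downsampled[g] = target
    return CountMatrix(matrix.gene_ids, matrix.sample_ids, counts), downsampled


def stratify(
    pre_effect_matrix: CountMatrix, cutoffs: Tuple[float, float]
) -> tuple:
    """Label genes low/mid/high by pre-effect mean count.

    ``low`` if mean < low_hi; ``mid`` if low_hi <= mean <= mid_hi; ``high``
    if mean > mid_hi.
    """
    low_hi, mid_hi = cutoffs
    if low_hi <= 0 or mid_hi <= 0 or low_hi >= mid_hi:
        raise ValueError("cutoffs must be positive with low_hi < mid_hi")
    means = pre_effect_matrix.counts.mean(axis=1)
    labels = np.where(means < low_hi, "low", np.where(means > mid_hi, "high", "mid"))
    return tuple(labels)


def make_benchmark(
    reference: CountMatrix,
    m1: int,
    m2: int,
    spec: EffectSpec,
    cutoffs: Tuple[float, float],
    rng: np.random.Generator,
    filter_enabled: bool = True,
    zero_fraction_max: float = 0.75,
    min_mean: float = 3.0,
) -> BenchmarkDataset:
    """Run the full resampling pipeline and return one benchmark replicate.

    Stage order: group sampling -> gene filter -> stratification (on
    pre-effect counts) -> DA-gene selection -> effect injection.  With
    ``spec.da_fraction == 0`` no effects are injected and the result is a
    null benchmark for p-value-uniformity studies.
    """
    resampled, design = sample_groups(reference, m1, m2, rng)
    filtered, _removed = apply_filter(
        resampled, zero_fraction_max, min_mean, enabled=filter_enabled
    )
    if filtered.n_genes == 0:
        raise ValueError("no genes survive the abundance filter")
    strata = stratify(filtered, cutoffs)
    pre_effect_mean = filtered.counts.mean(axis=1)

    n = filtered.n_genes
    truth = np.zeros(n, dtype=bool)
    true_q = np.ones(n, dtype=float)
    downsampled: dict = {}
    if spec.da_fraction > 0:
        da = select_da_genes(filtered.gene_ids, spec.da_fraction, rng)
        matrix, downsampled = inject_effect(filtered, da, spec, design, rng)
        for i, g in enumerate(filtered.gene_ids):
            if g in da:
                truth[i] = True
                true_q[i] = spec.fold_change
    else:
        matrix = filtered
    ds_group = tuple(downsampled.get(g) for g in matrix.gene_ids)
    return BenchmarkDataset(
        matrix=matrix,
        design=design,
        truth=truth,
        true_q=true_q,
        downsampled_group=ds_group,
        strata=strata,
        pre_effect_mean=pre_effect_mean,
    )
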