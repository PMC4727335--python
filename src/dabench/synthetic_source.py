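"""Synthetic metagenomic reference matrices.

Real gut-metagenome count tables show four statistical features that matter
for differential-abundance testing: a heavy-tailed gene abundance profile,
large sample-to-sample library-size variation, between-sample overdispersion
(variance well above the Poisson mean), and excess zeros concentrated in
low-abundance genes.  :func:`generate_reference` emulates all four with a
zero-inflated negative-binomial model on top of a log-normal abundance
profile:

* per-sample depth ``D_j ~ LogNormal`` with mean ``mean_depth`` and
  coefficient of variation ``depth_cv``;
* per-gene relative abundance ``a_i ~ LogNormal(abundance_log_mean,
  abundance_log_sd)``, renormalized to sum to one;
* cell counts ``y_ij ~ NB(mean = a_i * D_j, dispersion)`` where the NB
  variance is ``mu + dispersion * mu**2`` (``dispersion = 0`` is the Poisson
  limit);
* extra dropout: each cell is zeroed with probability
  ``zero_inflation_max * exp(-a_i * mean_depth / zero_inflation_tau)``,
  so zero inflation fades out for abundant genes.

Two presets mimic published human-gut references at desk scale:
``pyro_like`` (pyrosequencing: ~2150 genes, ~156k fragments/sample, mild zero
inflation) and ``illumina_like`` (short-read shotgun: ~3000 genes, deep
libraries, strong zero inflation among rare genes).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Union

import numpy as np

from .counts_io import CountMatrix

__all__ = ["ReferenceModel", "generate_reference", "preset", "PRESETS"]


@dataclass(frozen=True)
class ReferenceModel:
    """Parameters of the zero-inflated negative-binomial reference generator.

    Attributes
    ----------
    n_genes, n_samples : int
        Matrix dimensions.
    mean_depth : float
        Expected fragments per sample (the mean of the library-size law).
    depth_cv : float
        Coefficient of variation of the library size across samples.
    abundance_log_mean, abundance_log_sd : float
        Log-scale location/scale of the gene relative-abundance profile
        (the location cancels on renormalization; the scale sets tail weight).
    dispersion : float or ndarray
        Negative-binomial overdispersion; scalar or per-gene array.
        Variance of a cell is ``mu + dispersion * mu**2``.
    zero_inflation_max : float
        Maximal extra-dropout probability, applied to the rarest genes.
    zero_inflation_tau : float
        Expected-count scale over which dropout decays with abundance.
    seed : int or None
        RNG seed; identical seeds give identical matrices.
    """

    n_genes: int = 2000
    n_samples: int = 100
    mean_depth: float = 100_000.0
    depth_cv: float = 0.5
    abundance_log_mean: float = 0.0
    abundance_log_sd: float = 1.5
    dispersion: Union[float, np.ndarray] = 0.3
    zero_inflation_max: float = 0.1
    zero_inflation_tau: float = 30.0
    seed: Union[int, None] = None

    def __post_init__(self):
        if self.n_genes < 1 or self.n_samples < 1:
            raise ValueError("n_genes and n_samples must be positive")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.depth_cv < 0:
            raise ValueError("depth_cv must be non-negative")
        if self.abundance_log_sd < 0:
            raise ValueError("abundance_log_sd must be non-negative")
        disp = np.asarray(self.dispersion, dtype=float)
        if (disp < 0).any():
            raise ValueError("dispersion must be non-negative")
        if disp.ndim not in (0, 1) or (disp.ndim == 1 and disp.size != self.n_genes):
            raise ValueError("dispersion must be scalar or length n_genes")
        if not (0 <= self.zero_inflation_max < 1):
            raise ValueError("zero_inflation_max must lie in [0, 1)")
        if self.zero_inflation_tau <= 0:
            raise ValueError("zero_inflation_tau must be positive")

    def with_(self, **kwargs) -> "ReferenceModel":
        """A copy with the given fields replaced."""
        return replace(self, **kwargs)


def relative_abundances(model: ReferenceModel, rng: np.random.Generator) -> np.ndarray:
    """Draw the renormalized log-normal gene relative-abundance profile."""
    a = rng.lognormal(model.abundance_log_mean, model.abundance_log_sd, model.n_genes)
    return a / a.sum()


def _lognormal_depths(model: ReferenceModel, rng: np.random.Generator) -> np.ndarray:
    if model.depth_cv == 0:
        return np.full(model.n_samples, model.mean_depth)
    sigma2 = np.log1p(model.depth_cv**2)
    mu = np.log(model.mean_depth) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), model.n_samples)


def dropout_probabilities(model: ReferenceModel, abundances: np.ndarray) -> np.ndarray:
    """Per-gene extra-dropout probability, decaying with expected count."""
    expected = abundances * model.mean_depth
    return model.zero_inflation_max * np.exp(-expected / model.zero_inflation_tau)


def generate_reference(model: ReferenceModel) -> CountMatrix:
    """Draw one reference count matrix from the generator model.

    The result is fully reproducible from ``model.seed``; gene ids are
    ``g0001...`` and sample ids ``s001...``.
    """
    rng = np.random.default_rng(model.seed)
    abundances = relative_abundances(model, rng)
    depths = _lognormal_depths(model, rng)
    mu = abundances[:, None] * depths[None, :]

    disp = np.broadcast_to(
        np.asarray(model.dispersion, dtype=float), (model.n_genes,)
    ).copy()
    counts = np.empty((model.n_genes, model.n_samples), dtype=np.int64)
    poisson_rows = disp == 0
    if poisson_rows.any():
        counts[poisson_rows] = rng.poisson(mu[poisson_rows])
    nb_rows = ~poisson_rows
    if nb_rows.any():
        shape = 1.0 / disp[nb_rows]
        lam = rng.gamma(shape[:, None], disp[nb_rows, None] * mu[nb_rows])
        counts[nb_rows] = rng.poisson(lam)

    if model.zero_inflation_max > 0:
        p_drop = dropout_probabilities(model, abundances)
        drop = rng.random(counts.shape) < p_drop[:, None]
        counts[drop] = 0

    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError(
            "generated an all-zero sample; increase mean_depth or lower "
            "zero_inflation_max"
        )
    gw = len(str(model.n_genes))
    sw = len(str(model.n_samples))
    gene_ids = tuple(f"g{i + 1:0{gw}d}" for i in range(model.n_genes))
    sample_ids = tuple(f"s{j + 1:0{sw}d}" for j in range(model.n_samples))
    return CountMatrix(gene_ids, sample_ids, counts)


#: Desk-scale preset models emulating published gut-metagenome references.
PRESETS = {
    # Pyrosequencing-style: ~156k reads/sample, ~2150 genes post-filter,
    # mild zero inflation.
    "pyro_like": ReferenceModel(
        n_genes=2150,
        n_samples=110,
        mean_depth=155_890.0,
        depth_cv=0.6,
        abundance_log_sd=1.5,
        dispersion=0.3,
        zero_inflation_max=0.1,
        zero_inflation_tau=30.0,
    ),
    # Illumina-style shotgun: ~3000 genes post-filter, deep libraries
    # (62.5 M reads in the emulated study, scaled to 1 M for desk-scale
    # runs), strong zero inflation among low-abundance genes.
    "illumina_like": ReferenceModel(
        n_genes=3029,
        n_samples=120,
        mean_depth=1_000_000.0,
        depth_cv=0.6,
        abundance_log_sd=2.0,
        dispersion=0.5,
        zero_inflation_max=0.5,
        zero_inflation_tau=50.0,
    ),
}

#: Literal sequencing depth of the deep-shotgun reference the illumina_like
#: preset is scaled down from.
ILLUMINA_FULL_DEPTH = 62_500_000.0


def preset(name: str, full_depth: bool = False, seed: Union[int, None] = None) -> ReferenceModel:
    """Return a named preset model.

    Parameters
    ----------
    name : {"pyro_like", "illumina_like"}
    full_depth : bool
        For ``illumina_like``, restore the literal 62.5 M fragments/sample
        depth instead of the desk-scale 1 M default.
    seed : int, optional
        Seed stored on the returned model.
    """
    try:
        model = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None
    if full_depth and name == "illumina_like":
        model = model.with_(mean_depth=ILLUMINA_FULL_DEPTH)
    if seed is not None:
        model = model.with_(seed=seed)
    return model
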