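"""Two-group differential-abundance tests on count matrices.

Nine native methods are provided, all operating on a :class:`CountMatrix`
plus a two-group :class:`GroupDesign` and returning per-gene p-values in the
original gene order:

* ``poisson_glm_test`` — Poisson GLM with log link and ``log N_j`` offset;
  Wald z-test (or likelihood-ratio chi-square) on the group coefficient.
* ``overdispersed_glm_test`` — the same mean model with a gene-specific
  quasi-Poisson dispersion ``phi = Pearson X^2 / (m - 2)``; standard errors
  scaled by ``sqrt(phi)`` and the Wald statistic referred to a t
  distribution with ``m - 2`` degrees of freedom.  No information is shared
  across genes.
* ``fisher_pooled_test`` / ``binomial_pooled_test`` — exact tests on counts
  pooled within groups; both use the minimum-likelihood two-sided
  convention (sum of outcomes whose point probability does not exceed the
  observed one), matching R's ``fisher.test`` / ``binom.test``.
* ``transformed_t_test`` — Student or Welch t-test on total-count-normalized
  values, optionally variance-stabilized by ``sqrt(y)`` or ``log(y + 1)``.
* ``wmw_test`` — Wilcoxon-Mann-Whitney on normalized values; exact null
  distribution when a gene has no tied values, otherwise the
  tie-corrected normal approximation with continuity correction.

For the two-group Poisson log-linear model with offsets the maximum
likelihood estimates are available in closed form (each fitted group rate is
the pooled gene count over the pooled library size), so the GLM methods are
fully vectorized across genes rather than fitted gene by gene; the results
are identical to an iterative GLM fit.

Effect sizes are reported as ``log2`` fold-changes of group 2 relative to
group 1 (groups ordered by first appearance in the design), so swapping the
group labels negates every ``log2_fold_change`` and leaves p-values
unchanged.  Genes where a statistic is undefined (e.g. a group with zero
pooled counts in the Poisson GLM, or zero variance in both groups for the
t-test) carry ``NaN`` p-values; downstream ranking places them last.
"""

from __future__ import annotations

import logging
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import special, stats

from .counts_io import (
    CountMatrix,
    GroupDesign,
    total_count_normalize,
    write_count_table,
    write_design,
)

__all__ = [
    "MethodResult",
    "poisson_glm_test",
    "overdispersed_glm_test",
    "fisher_pooled_test",
    "binomial_pooled_test",
    "transformed_t_test",
    "wmw_test",
    "run_external_method",
    "METHODS",
]

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)


@dataclass(frozen=True)
class MethodResult:
    """Per-gene output of one differential-abundance method."""

    method_name: str
    gene_ids: tuple
    p_value: np.ndarray = field(repr=False)
    log2_fold_change: Optional[np.ndarray] = field(default=None, repr=False)
    statistic: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        p = np.asarray(self.p_value, dtype=float)
        if p.shape != (len(self.gene_ids),):
            raise ValueError("p_value length does not match gene_ids")
        finite = p[~np.isnan(p)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("p-values must lie in [0, 1]")
        p.setflags(write=False)
        object.__setattr__(self, "p_value", p)
        for name in ("log2_fold_change", "statistic"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != p.shape:
                    raise ValueError(f"{name} length does not match gene_ids")
                v.setflags(write=False)
                object.__setattr__(self, name, v)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.p_value).sum())

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"gene_id": list(self.gene_ids), "p_value": self.p_value})
        if self.log2_fold_change is not None:
            df["log2_fold_change"] = self.log2_fold_change
        if self.statistic is not None:
            df["statistic"] = self.statistic
        return df


def _pooled(matrix: CountMatrix, design: GroupDesign):
    """Pooled per-group gene counts (x1, x2) and library sizes (T1, T2)."""
    in_b = design.membership(matrix.sample_ids)
    totals = matrix.column_totals
    x1 = matrix.counts[:, ~in_b].sum(axis=1)
    x2 = matrix.counts[:, in_b].sum(axis=1)
    return x1, x2, int(totals[~in_b].sum()), int(totals[in_b].sum()), in_b


def _glm_core(matrix: CountMatrix, design: GroupDesign):
    """Closed-form two-group Poisson GLM: coefficient, Wald SE, Pearson X^2.

    The MLE of the log rate ratio is ``log((x2/T2)/(x1/T1))`` with asymptotic
    variance ``1/x1 + 1/x2``; the Pearson statistic is computed from the
    fitted means ``mu_ij = rate_group(j) * N_j``.
    """
    x1, x2, t1, t2, in_b = _pooled(matrix, design)
    totals = matrix.column_totals.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.log(x2 / t2) - np.log(x1 / t1)
        se = np.sqrt(1.0 / x1 + 1.0 / x2)
    rate = np.where(in_b[None, :], (x2 / t2)[:, None], (x1 / t1)[:, None])
    mu = rate * totals[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        pearson = np.where(mu > 0, (matrix.counts - mu) ** 2 / mu, 0.0).sum(axis=1)
    undefined = (x1 == 0) | (x2 == 0)
    return beta, se, pearson, undefined, (x1, x2, t1, t2)


def _glm_lrt(x1, x2, t1, t2):
    """Likelihood-ratio (deviance) statistic of group vs pooled rate."""
    r = (x1 + x2) / (t1 + t2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = special.xlogy(x1, x1 / (t1 * r)) + special.xlogy(x2, x2 / (t2 * r))
    return 2.0 * ll


def poisson_glm_test(
    matrix: CountMatrix, design: GroupDesign, inference: str = "wald"
) -> MethodResult:
    """Poisson log-linear model ``counts ~ group`` with offset ``log N_j``.

    ``inference`` selects the Wald z-test (default) or the likelihood-ratio
    chi-square test on the group coefficient.  Genes with zero pooled counts
    in either group have no finite coefficient and get ``NaN``.
    """
    beta, se, _pearson, undefined, pooled = _glm_core(matrix, design)
    if inference == "wald":
        with np.errstate(invalid="ignore"):
            z = beta / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        statistic = z
    elif inference == "lrt":
        g2 = _glm_lrt(*pooled)
        p = stats.chi2.sf(g2, df=1)
        statistic = g2
    else:
        raise ValueError("inference must be 'wald' or 'lrt'")
    p = np.where(undefined, np.nan, p)
    statistic = np.where(undefined, np.nan, statistic)
    if undefined.any():
        logger.info("poisson_glm: %d genes with a zero-count group", undefined.sum())
    return MethodResult("poisson_glm", matrix.gene_ids, p, beta / LN2, statistic)


def overdispersed_glm_test(
    matrix: CountMatrix,
    design: GroupDesign,
    inference: str = "wald",
    floor_dispersion: bool = False,
) -> MethodResult:
    """Quasi-Poisson GLM with gene-specific dispersion (no shrinkage).

    The dispersion ``phi = Pearson X^2 / (m - 2)`` scales the Poisson
    standard error by ``sqrt(phi)``; inference uses a t distribution with
    ``m - 2`` degrees of freedom (Wald, default) or an F(1, m-2) test on the
    scaled deviance (``inference='lrt'``).  ``floor_dispersion`` clamps
    ``phi`` at 1 so the quasi model is never more liberal than Poisson.
    """
    m = matrix.n_samples
    if m < 3:
        raise ValueError("overdispersed GLM needs m1 + m2 >= 3 (df = m - 2 > 0)")
    beta, se, pearson, undefined, pooled = _glm_core(matrix, design)
    df = m - 2
    phi = pearson / df
    if floor_dispersion:
        phi = np.maximum(phi, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        if inference == "wald":
            t = beta / (np.sqrt(phi) * se)
            t = np.where(beta == 0, 0.0, t)  # 0/0 when the fit is exact
            p = 2.0 * stats.t.sf(np.abs(t), df=df)
            statistic = t
        elif inference == "lrt":
            f = _glm_lrt(*pooled) / phi
            p = stats.f.sf(f, 1, df)
            statistic = f
        else:
            raise ValueError("inference must be 'wald' or 'lrt'")
    p = np.where(undefined, np.nan, p)
    statistic = np.where(undefined, np.nan, statistic)
    return MethodResult("oglm", matrix.gene_ids, p, beta / LN2, statistic)


def _pooled_log2fc(x1, x2, t1, t2):
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.log2((x2 / t2) / (x1 / t1))
    return np.where((x1 == 0) | (x2 == 0), np.nan, fc)


def fisher_pooled_test(matrix: CountMatrix, design: GroupDesign) -> MethodResult:
    """Fisher's exact test on the gene-specific pooled 2x2 table.

    Rows: fragments matching / not matching the gene; columns: the two
    groups.  Two-sided p by the minimum-likelihood convention.
    """
    x1, x2, t1, t2, _ = _pooled(matrix, design)
    p = np.empty(matrix.n_genes)
    for i in range(matrix.n_genes):
        a, b = int(x1[i]), int(x2[i])
        p[i] = stats.fisher_exact([[a, t1 - a], [b, t2 - b]]).pvalue
    p = np.minimum(p, 1.0)
    return MethodResult("fisher", matrix.gene_ids, p, _pooled_log2fc(x1, x2, t1, t2))


def binomial_pooled_test(matrix: CountMatrix, design: GroupDesign) -> MethodResult:
    """Two-sided exact binomial test on pooled counts.

    Tests ``x1 ~ Binomial(x1 + x2, T1 / (T1 + T2))``; a gene with zero
    pooled counts in both groups is uninformative and gets p = 1.
    """
    x1, x2, t1, t2, _ = _pooled(matrix, design)
    p0 = t1 / (t1 + t2)
    p = np.empty(matrix.n_genes)
    for i in range(matrix.n_genes):
        n = int(x1[i] + x2[i])
        p[i] = 1.0 if n == 0 else stats.binomtest(int(x1[i]), n, p0).pvalue
    return MethodResult("binomial", matrix.gene_ids, p, _pooled_log2fc(x1, x2, t1, t2))


_TRANSFORMS = {
    "identity": lambda y: y,
    "sqrt": np.sqrt,
    "log1p": np.log1p,
}


def transformed_t_test(
    matrix: CountMatrix,
    design: GroupDesign,
    transform: str = "identity",
    variance: str = "pooled",
) -> MethodResult:
    """Two-sample t-test on (optionally variance-stabilized) normalized counts.

    Counts are divided by their column totals and rescaled to the mean
    library size before the transform (``identity``, ``sqrt`` or ``log1p``)
    is applied cell-wise.  ``variance='pooled'`` gives the Student test,
    ``'welch'`` the unequal-variance test.  Genes with zero variance in both
    groups have an undefined statistic and get ``NaN``.
    """
    if transform not in _TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    if variance not in ("pooled", "welch"):
        raise ValueError("variance must be 'pooled' or 'welch'")
    in_b = design.membership(matrix.sample_ids)
    m1, m2 = int((~in_b).sum()), int(in_b.sum())
    if m1 < 2 or m2 < 2:
        raise ValueError("t-test needs at least two samples per group")
    norm = total_count_normalize(matrix, rescale_to_mean_depth=True)
    z = _TRANSFORMS[transform](norm)
    a1, a2 = z[:, ~in_b], z[:, in_b]
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a2, a1, axis=1, equal_var=(variance == "pooled"))
    p = np.asarray(res.pvalue, dtype=float)
    t = np.asarray(res.statistic, dtype=float)
    degenerate = (np.ptp(a1, axis=1) == 0) & (np.ptp(a2, axis=1) == 0)
    if degenerate.any():
        logger.info("t-test: %d genes with zero variance in both groups", degenerate.sum())
    p[degenerate] = np.nan
    t[degenerate] = np.nan

    mean1, mean2 = a1.mean(axis=1), a2.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if transform == "log1p":
            lfc = (mean2 - mean1) / LN2  # difference of mean log(y+1), in log2 units
        elif transform == "sqrt":
            lfc = np.log2(mean2**2 / mean1**2)
        else:
            lfc = np.log2(mean2 / mean1)
    return MethodResult(f"{variance}_t_{transform}", matrix.gene_ids, p, lfc, t)


def wmw_test(matrix: CountMatrix, design: GroupDesign) -> MethodResult:
    """Wilcoxon-Mann-Whitney test on total-count-normalized values.

    Genes without tied values use the exact rank-sum null distribution;
    genes with ties use the tie-corrected normal approximation with
    continuity correction (so a gene whose values are all equal gets p = 1).
    """
    in_b = design.membership(matrix.sample_ids)
    m1, m2 = int((~in_b).sum()), int(in_b.sum())
    if m1 < 2 or m2 < 2:
        raise ValueError("WMW needs at least two samples per group")
    norm = total_count_normalize(matrix, rescale_to_mean_depth=True)
    a1, a2 = norm[:, ~in_b], norm[:, in_b]
    m = m1 + m2
    has_ties = np.array(
        [np.unique(norm[i]).size < m for i in range(matrix.n_genes)]
    )
    p = np.empty(matrix.n_genes)
    u = np.empty(matrix.n_genes)
    exact = ~has_ties
    if exact.any():
        res = stats.mannwhitneyu(
            a2[exact], a1[exact], axis=1, method="exact", alternative="two-sided"
        )
        p[exact] = res.pvalue
        u[exact] = res.statistic
    if has_ties.any():
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.mannwhitneyu(
                a2[has_ties],
                a1[has_ties],
                axis=1,
                method="asymptotic",
                use_continuity=True,
                alternative="two-sided",
            )
        p[has_ties] = np.nan_to_num(res.pvalue, nan=1.0)
        u[has_ties] = res.statistic
    p = np.minimum(p, 1.0)
    mean1, mean2 = a1.mean(axis=1), a2.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(mean2 / mean1)
    return MethodResult("wmw", matrix.gene_ids, p, lfc, u)


def run_external_method(
    matrix: CountMatrix, design: GroupDesign, adapter, name: Optional[str] = None
) -> MethodResult:
    """Invoke an external tool through the plugin exchange contract.

    ``adapter`` is the executable (string or argv prefix list); it is called
    as ``<cmd> --counts <tsv> --design <tsv> --out <tsv>`` and must write a
    TSV with columns ``gene_id, p_value, log2_fold_change`` (``NA``
    allowed in the last column) covering every input gene.
    """
    argv = [adapter] if isinstance(adapter, (str, Path)) else list(adapter)
    name = name or Path(str(argv[0])).stem
    with tempfile.TemporaryDirectory(prefix="dabench_ext_") as tmp:
        tmp = Path(tmp)
        counts_path = tmp / "counts.tsv"
        design_path = tmp / "design.tsv"
        out_path = tmp / "result.tsv"
        write_count_table(matrix, counts_path)
        write_design(design, design_path)
        cmd = [str(a) for a in argv] + [
            "--counts", str(counts_path),
            "--design", str(design_path),
            "--out", str(out_path),
        ]
        try:
            subprocess.run(cmd, check=True, capture_output=True, text=True)
        except FileNotFoundError as exc:
            raise RuntimeError(f"adapter executable not found: {argv[0]}") from exc
        except subprocess.CalledProcessError as exc:
            raise RuntimeError(
                f"adapter {name} failed (exit {exc.returncode}): {exc.stderr[-500:]}"
            ) from exc
        if not out_path.exists():
            raise RuntimeError(f"adapter {name} produced no output file")
        out = pd.read_csv(out_path, sep="\t", dtype={"gene_id": str}, na_values=["NA"])
    required = {"gene_id", "p_value"}
    if not required.issubset(out.columns):
        raise RuntimeError(f"adapter {name} output lacks columns {sorted(required)}")
    out = out.set_index("gene_id")
    missing = [g for g in matrix.gene_ids if g not in out.index]
    if missing:
        raise RuntimeError(f"adapter {name} output missing gene {missing[0]!r}")
    out = out.loc[list(matrix.gene_ids)]
    p = out["p_value"].to_numpy(dtype=float)
    bad = p[~np.isnan(p)]
    if bad.size and (bad.min() < 0 or bad.max() > 1):
        raise RuntimeError(f"adapter {name} returned p-values outside [0, 1]")
    lfc = (
        out["log2_fold_change"].to_numpy(dtype=float)
        if "log2_fold_change" in out.columns
        else None
    )
    return MethodResult(name, matrix.gene_ids, p, lfc)


#: Registry of the native methods under their short names.
METHODS = {
    "poisson_glm": poisson_glm_test,
    "oglm": overdispersed_glm_test,
    "fisher": fisher_pooled_test,
    "binomial": binomial_pooled_test,
    "t_test": lambda m, d: transformed_t_test(m, d, "identity", "pooled"),
    "welch_t_test": lambda m, d: transformed_t_test(m, d, "identity", "welch"),
    "sqrt_t_test": lambda m, d: transformed_t_test(m, d, "sqrt", "pooled"),
    "log_t_test": lambda m, d: transformed_t_test(m, d, "log1p", "pooled"),
    "wmw": wmw_test,
}
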