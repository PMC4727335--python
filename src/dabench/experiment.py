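"""Config-driven orchestration of benchmark sweeps.

An :class:`ExperimentPlan` names a reference source (a generator preset or a
count-table TSV), the group sizes and fold-changes to sweep, the number of
resampling replicates, and the methods to run.  :func:`run_experiment`
executes the full grid, evaluates every method on every replicate, and
writes a report directory:

``manifest.json``
    plan parameters, replicate seeds, software version.
``auc_table.tsv``
    one row per method x condition (x stratum): consensus-ROC AUC and
    normalized AUC_0.05, plus replicate medians.
``fdr_confusion.tsv``
    one row per method x condition x replicate: TP, FP, realized FDR at the
    estimated-FDR threshold.
``consensus_roc.tsv``
    consensus TPR on the FPR grid per method x condition.
``qq_summary.tsv``
    for null plans (``da_fraction = 0``): mean qq curve and pooled
    histogram per method.

Replicate seeds are derived from the master seed together with the
condition parameters and the replicate index, so adding conditions to a
plan never perturbs the data of existing ones, and a rerun with the same
master seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .counts_io import CountMatrix, read_count_table
from .da_methods import METHODS, run_external_method
from .evaluation import (
    auc,
    confusion_at_fdr,
    consensus_roc,
    qq_uniform_summary,
    roc_curve,
    true_fdr_curve,
)
from .resampler import EffectSpec, make_benchmark
from .synthetic_source import PRESETS, generate_reference, preset

__all__ = ["ExperimentPlan", "run_experiment", "summarize", "replicate_seed"]

logger = logging.getLogger(__name__)


@dataclass
class ExperimentPlan:
    """Full description of a benchmark sweep (YAML-serializable)."""

    reference_source: str = "pyro_like"
    group_sizes: List[Tuple[int, int]] = field(default_factory=lambda: [(6, 6)])
    fold_changes: List[float] = field(default_factory=lambda: [5.0])
    da_fraction: float = 0.10
    n_replicates: int = 100
    methods: List[str] = field(default_factory=lambda: ["oglm", "sqrt_t_test"])
    adapters: dict = field(default_factory=dict)
    stratum_cutoffs: Tuple[float, float] = (50.0, 500.0)
    filter_enabled: bool = True
    alpha_fdr: float = 0.05
    fdr_subsample: Optional[int] = 1500
    qq_subsample: int = 1500
    master_seed: int = 0
    reference_seed_offset: int = 1

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.da_fraction == 0:
            if not self.fold_changes:
                self.fold_changes = [1.0]
        elif any(q <= 1 for q in self.fold_changes):
            raise ValueError("fold_changes must all be > 1 (or set da_fraction = 0)")
        self.group_sizes = [tuple(int(v) for v in gs) for gs in self.group_sizes]
        self.stratum_cutoffs = tuple(float(v) for v in self.stratum_cutoffs)
        self.fold_changes = [float(q) for q in self.fold_changes]
        unknown = [
            m for m in self.methods if m not in METHODS and m not in self.adapters
        ]
        if unknown:
            raise ValueError(f"unknown methods with no adapter: {unknown}")

    @property
    def is_null_plan(self) -> bool:
        return self.da_fraction == 0

    @classmethod
    def from_yaml(cls, path) -> "ExperimentPlan":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["group_sizes"] = [list(gs) for gs in self.group_sizes]
        d["stratum_cutoffs"] = list(self.stratum_cutoffs)
        return d


def replicate_seed(master_seed: int, m1: int, m2: int, q: float, rep: int) -> int:
    """Stable per-replicate seed; independent of the rest of the sweep grid."""
    ss = np.random.SeedSequence(
        [int(master_seed), int(m1), int(m2), int(round(q * 1000)), int(rep)]
    )
    return int(ss.generate_state(1)[0] % (2**31))


def _load_reference(plan: ExperimentPlan) -> CountMatrix:
    src = plan.reference_source
    if src in PRESETS:
        model = preset(src, seed=plan.master_seed + plan.reference_seed_offset)
        return generate_reference(model)
    return read_count_table(src)


def _run_method(name: str, plan: ExperimentPlan, matrix, design):
    if name in plan.adapters:
        return run_external_method(matrix, design, plan.adapters[name], name=name)
    return METHODS[name](matrix, design)


def run_experiment(plan: ExperimentPlan, out_dir) -> Path:
    """Execute the sweep and write the report directory (returned).

    Failures are isolated per (method, replicate): the sweep continues and
    the failures are listed in the manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reference = _load_reference(plan)
    logger.info(
        "reference: %d genes x %d samples", reference.n_genes, reference.n_samples
    )

    auc_rows, fdr_rows, roc_rows, qq_rows = [], [], [], []
    failures = []
    seeds_used = {}
    t0 = time.time()

    conditions = [
        (m1, m2, q) for (m1, m2) in plan.group_sizes for q in plan.fold_changes
    ]
    for m1, m2, q in conditions:
        cond = f"{m1}+{m2},q={q:g}"
        curves = {m: [] for m in plan.methods}
        rep_auc005 = {m: [] for m in plan.methods}
        rep_auc = {m: [] for m in plan.methods}
        null_pvals = {m: [] for m in plan.methods}
        strat_curves = {m: {} for m in plan.methods}
        for rep in range(plan.n_replicates):
            seed = replicate_seed(plan.master_seed, m1, m2, q, rep)
            seeds_used[f"{cond}/rep{rep}"] = seed
            rng = np.random.default_rng(seed)
            spec = EffectSpec(
                fold_change=q if not plan.is_null_plan else 2.0,
                da_fraction=plan.da_fraction,
            )
            try:
                ds = make_benchmark(
                    reference,
                    m1,
                    m2,
                    spec,
                    plan.stratum_cutoffs,
                    rng,
                    filter_enabled=plan.filter_enabled,
                )
            except Exception as exc:  # degenerate draw: record and move on
                failures.append({"condition": cond, "replicate": rep, "error": str(exc)})
                continue
            for mname in plan.methods:
                try:
                    res = _run_method(mname, plan, ds.matrix, ds.design)
                except Exception as exc:
                    failures.append(
                        {
                            "condition": cond,
                            "replicate": rep,
                            "method": mname,
                            "error": str(exc),
                        }
                    )
                    continue
                if plan.is_null_plan:
                    null_pvals[mname].append(res.p_value)
                    continue
                curve = roc_curve(res, ds.truth)
                curves[mname].append(curve)
                rep_auc[mname].append(auc(curve))
                rep_auc005[mname].append(auc(curve, 0.05, normalized=True))
                track = true_fdr_curve(res, ds.truth)
                tp, fp, realized = confusion_at_fdr(
                    track,
                    plan.alpha_fdr,
                    plan.fdr_subsample,
                    np.random.default_rng(seed + 1),
                )
                fdr_rows.append(
                    {
                        "method": mname,
                        "m1": m1,
                        "m2": m2,
                        "fold_change": q,
                        "replicate": rep,
                        "tp": tp,
                        "fp": fp,
                        "true_fdr": realized,
                    }
                )
                from .evaluation import stratified_evaluate

                for label, sres in stratified_evaluate(res, ds).items():
                    strat_curves[mname].setdefault(label, []).append(sres["curve"])

        for mname in plan.methods:
            if plan.is_null_plan:
                if not null_pvals[mname]:
                    continue
                usable = [
                    p[~np.isnan(p)]
                    for p in null_pvals[mname]
                ]
                size = min(plan.qq_subsample, min(p.size for p in usable))
                qq = qq_uniform_summary(
                    usable, size, np.random.default_rng(plan.master_seed + 17)
                )
                step = max(1, size // 100)
                for i in range(0, size, step):
                    qq_rows.append(
                        {
                            "method": mname,
                            "m1": m1,
                            "m2": m2,
                            "quantile": qq["quantiles"][i],
                            "mean_p": qq["mean_curve"][i],
                        }
                    )
                continue
            if not curves[mname]:
                continue
            cons = consensus_roc(curves[mname])
            cons_curve = cons.as_curve()
            auc_rows.append(
                {
                    "method": mname,
                    "m1": m1,
                    "m2": m2,
                    "fold_change": q,
                    "stratum": "all",
                    "n_replicates": len(curves[mname]),
                    "auc": auc(cons_curve),
                    "auc005": auc(cons_curve, 0.05, normalized=True),
                    "median_rep_auc": float(np.median(rep_auc[mname])),
                    "median_rep_auc005": float(np.median(rep_auc005[mname])),
                }
            )
            grid = cons.fpr_grid
            step = max(1, len(grid) // 200)
            for i in range(0, len(grid), step):
                roc_rows.append(
                    {
                        "method": mname,
                        "m1": m1,
                        "m2": m2,
                        "fold_change": q,
                        "fpr": grid[i],
                        "mean_tpr": cons.mean_tpr[i],
                    }
                )
            for label, clist in sorted(strat_curves[mname].items()):
                scons = consensus_roc(clist).as_curve()
                auc_rows.append(
                    {
                        "method": mname,
                        "m1": m1,
                        "m2": m2,
                        "fold_change": q,
                        "stratum": label,
                        "n_replicates": len(clist),
                        "auc": auc(scons),
                        "auc005": auc(scons, 0.05, normalized=True),
                        "median_rep_auc": np.nan,
                        "median_rep_auc005": np.nan,
                    }
                )

    float_fmt = "%.6g"
    if auc_rows:
        pd.DataFrame(auc_rows).to_csv(
            out_dir / "auc_table.tsv", sep="\t", index=False, float_format=float_fmt
        )
    if fdr_rows:
        pd.DataFrame(fdr_rows).to_csv(
            out_dir / "fdr_confusion.tsv", sep="\t", index=False, float_format=float_fmt
        )
    if roc_rows:
        pd.DataFrame(roc_rows).to_csv(
            out_dir / "consensus_roc.tsv", sep="\t", index=False, float_format=float_fmt
        )
    if qq_rows:
        pd.DataFrame(qq_rows).to_csv(
            out_dir / "qq_summary.tsv", sep="\t", index=False, float_format=float_fmt
        )
    manifest = {
        "version": __version__,
        "plan": plan.to_dict(),
        "replicate_seeds": seeds_used,
        "failures": failures,
        "elapsed_seconds": round(time.time() - t0, 2),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    if failures:
        logger.warning("%d stage failures; see manifest.json", len(failures))
    return out_dir


def summarize(report_dir) -> str:
    """Render a Markdown summary of a report directory.

    Produces an AUC_0.05 pivot (methods x conditions, 'NA' where a cell is
    missing) and, when present, median TP/FP/true-FDR per method.  The
    Markdown text is returned and also written to ``summary.md``.
    """
    report_dir = Path(report_dir)
    parts = []
    auc_path = report_dir / "auc_table.tsv"
    manifest_path = report_dir / "manifest.json"
    method_order = None
    if manifest_path.exists():
        with open(manifest_path) as fh:
            method_order = json.load(fh)["plan"]["methods"]
    if auc_path.exists():
        df = pd.read_csv(auc_path, sep="\t")
        df["condition"] = (
            df["m1"].astype(str) + "+" + df["m2"].astype(str)
            + " q=" + df["fold_change"].map("{:g}".format)
        )
        for stratum, sub in df.groupby("stratum", sort=True):
            pivot = sub.pivot_table(
                index="method", columns="condition", values="auc005", aggfunc="first",
                sort=False,
            )
            if method_order:
                pivot = pivot.reindex([m for m in method_order if m in pivot.index])
            parts.append(f"## AUC_0.05 ({stratum} genes)\n")
            parts.append(pivot.to_markdown(floatfmt=".3f").replace("nan", " NA") + "\n")
    fdr_path = report_dir / "fdr_confusion.tsv"
    if fdr_path.exists():
        df = pd.read_csv(fdr_path, sep="\t")
        med = (
            df.groupby(["method", "m1", "m2", "fold_change"])[["tp", "fp", "true_fdr"]]
            .median()
            .reset_index()
        )
        if method_order:
            med["method"] = pd.Categorical(med["method"], method_order, ordered=True)
            med = med.sort_values(["method", "m1", "fold_change"])
        parts.append("## Median TP / FP / realized FDR at the estimated-FDR cutoff\n")
        parts.append(med.to_markdown(index=False, floatfmt=".3f") + "\n")
    qq_path = report_dir / "qq_summary.tsv"
    if qq_path.exists():
        df = pd.read_csv(qq_path, sep="\t")
        dev = (
            df.assign(dev=(df["mean_p"] - df["quantile"]).abs())
            .groupby("method")["dev"]
            .max()
            .reset_index()
            .rename(columns={"dev": "max_qq_deviation"})
        )
        parts.append("## Null p-value uniformity (max |mean qq curve - diagonal|)\n")
        parts.append(dev.to_markdown(index=False, floatfmt=".4f") + "\n")
    if not parts:
        raise ValueError(f"no report tables found in {report_dir}")
    text = "\n".join(parts)
    (report_dir / "summary.md").write_text(text)
    return text
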