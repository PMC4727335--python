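"""Gene-by-sample count matrices, two-group designs, and total-count normalization.

The central data structure is :class:`CountMatrix`: an ``n_genes x m_samples``
table of non-negative integer fragment counts ``y_ij`` with per-sample library
sizes ``N_j`` (column totals).  The canonical on-disk representation is a plain
TSV with a ``gene_id`` column followed by one column per sample; designs are
two-column TSVs mapping ``sample_id`` to one of exactly two group labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "GroupDesign",
    "read_count_table",
    "write_count_table",
    "read_design",
    "write_design",
    "total_count_normalize",
    "column_totals",
]


class CountTableError(ValueError):
    """Raised when a count table or design violates its invariants."""


@dataclass(frozen=True)
class CountMatrix:
    """A gene x sample table of fragment counts.

    Parameters
    ----------
    gene_ids : sequence of str
        Unique row identifiers, order preserved.
    sample_ids : sequence of str
        Unique column identifiers, order preserved.
    counts : ndarray of int, shape (n_genes, m_samples)
        Non-negative fragment counts ``y_ij``.
    """

    gene_ids: tuple
    sample_ids: tuple
    counts: np.ndarray = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise CountTableError("counts must be a 2-D array")
        if counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise CountTableError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.array_equal(rounded, counts):
                bad = np.argwhere(rounded != counts)[0]
                raise CountTableError(
                    f"non-integer count at gene {self.gene_ids[bad[0]]!r}, "
                    f"sample {self.sample_ids[bad[1]]!r}"
                )
            counts = counts.astype(np.int64)
        else:
            counts = counts.astype(np.int64, copy=True)
        if counts.size and counts.min() < 0:
            bad = np.argwhere(counts < 0)[0]
            raise CountTableError(
                f"negative count at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            seen, dup = set(), None
            for g in self.gene_ids:
                if g in seen:
                    dup = g
                    break
                seen.add(g)
            raise CountTableError(f"duplicate gene id {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise CountTableError("duplicate sample ids")
        totals = counts.sum(axis=0)
        if len(self.gene_ids) and (totals == 0).any():
            j = int(np.argmin(totals))
            raise CountTableError(
                f"sample {self.sample_ids[j]!r} has zero total count"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def shape(self) -> tuple:
        return self.counts.shape

    @property
    def column_totals(self) -> np.ndarray:
        """Per-sample library sizes ``N_j``."""
        return self.counts.sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    def select_genes(self, index) -> "CountMatrix":
        """New matrix restricted to the given gene positions (order kept)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CountMatrix(
            tuple(self.gene_ids[i] for i in index),
            self.sample_ids,
            self.counts[index, :],
        )

    def select_samples(self, index) -> "CountMatrix":
        """New matrix restricted to the given sample positions (order kept)."""
        index = np.asarray(index)
        return CountMatrix(
            self.gene_ids,
            tuple(self.sample_ids[j] for j in index),
            self.counts[:, index],
        )

    def __eq__(self, other):
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass(frozen=True)
class GroupDesign:
    """A two-group assignment of samples.

    ``groups`` holds the two distinct labels in order of first appearance;
    every statistical method reports effects as group 2 relative to group 1.
    """

    sample_ids: tuple
    group_labels: tuple
    group_order: Optional[tuple] = None

    def __post_init__(self):
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "group_labels", tuple(self.group_labels))
        if len(self.sample_ids) != len(self.group_labels):
            raise CountTableError("sample_ids and group_labels length mismatch")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise CountTableError("duplicate sample ids in design")
        observed = set(self.group_labels)
        if len(observed) != 2:
            raise CountTableError(
                f"design must have exactly two groups, found {len(observed)}"
            )
        if self.group_order is not None:
            order = tuple(self.group_order)
            if set(order) != observed or len(order) != 2:
                raise CountTableError("group_order must permute the two group labels")
            object.__setattr__(self, "group_order", order)

    @property
    def groups(self) -> tuple:
        """The two labels; order of first appearance unless overridden."""
        if self.group_order is not None:
            return self.group_order
        seen = []
        for g in self.group_labels:
            if g not in seen:
                seen.append(g)
        return tuple(seen)

    @property
    def group_sizes(self) -> tuple:
        g1, g2 = self.groups
        n1 = sum(1 for x in self.group_labels if x == g1)
        return (n1, len(self.group_labels) - n1)

    def membership(self, matrix_sample_ids: Sequence[str]) -> np.ndarray:
        """Boolean mask: True where the sample belongs to the second group."""
        ids = tuple(matrix_sample_ids)
        if set(ids) != set(self.sample_ids):
            missing = set(ids) ^ set(self.sample_ids)
            raise CountTableError(
                f"design and matrix sample ids differ: {sorted(missing)}"
            )
        lookup = dict(zip(self.sample_ids, self.group_labels))
        g2 = self.groups[1]
        return np.array([lookup[s] == g2 for s in ids], dtype=bool)

    def swapped(self) -> "GroupDesign":
        """The same partition with the reference (first) group exchanged."""
        g1, g2 = self.groups
        return GroupDesign(self.sample_ids, self.group_labels, group_order=(g2, g1))


def read_count_table(path) -> CountMatrix:
    """Read a TSV count table (``gene_id`` column + one column per sample)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={0: str}, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise CountTableError(f"malformed count table {path}: {exc}") from exc
    if df.index.name is None or df.columns.size == 0 and df.shape[0] > 0:
        raise CountTableError(f"malformed count table {path}: missing header")
    values = df.to_numpy()
    if values.size and not np.issubdtype(values.dtype, np.number):
        raise CountTableError(f"non-numeric cell in count table {path}")
    return CountMatrix(tuple(df.index.astype(str)), tuple(df.columns.astype(str)), values)


def write_count_table(matrix: CountMatrix, path) -> None:
    """Write a CountMatrix as canonical TSV (bit-stable for identical input)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for gid, row in zip(matrix.gene_ids, matrix.counts):
            fh.write(gid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_design(path) -> GroupDesign:
    """Read a two-column TSV design: ``sample_id<TAB>group``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "group"]:
        raise CountTableError(
            f"design file {path} must have columns 'sample_id' and 'group'"
        )
    return GroupDesign(tuple(df["sample_id"]), tuple(df["group"]))


def write_design(design: GroupDesign, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id\tgroup\n")
        for s, g in zip(design.sample_ids, design.group_labels):
            fh.write(f"{s}\t{g}\n")


def column_totals(matrix: CountMatrix) -> np.ndarray:
    """Per-sample totals ``N_j``, used as normalization factors / GLM offsets."""
    return matrix.column_totals


def total_count_normalize(
    matrix: CountMatrix, rescale_to_mean_depth: bool = False
) -> np.ndarray:
    """Divide each column by its total ``N_j``.

    With ``rescale_to_mean_depth`` the proportions are multiplied by the mean
    library size so values stay on a count-like scale (each column then sums
    to ``mean(N_j)``), which keeps pseudo-counts such as ``log(y + 1)``
    meaningful.
    """
    totals = matrix.column_totals.astype(float)
    if (totals == 0).any():
        j = int(np.argmin(totals))
        raise CountTableError(f"zero column total for sample {matrix.sample_ids[j]!r}")
    out = matrix.counts / totals[np.newaxis, :]
    if rescale_to_mean_depth:
        out = out * totals.mean()
    return out
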