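"""Count-matrix I/O and the core data model.

The entry point of every analysis is a tab-delimited count table whose rows
are genes and whose columns are sequencing samples: one header row of sample
IDs and a first column of gene IDs.  :func:`read_count_table` parses such a
file into a :class:`CountMatrix` plus a :class:`GroupDesign` mapping each
sample to its experimental group; :func:`write_results` serialises a fitted
:class:`~mbcdeg.deg_calling.DEGResult` back to TSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "GroupDesign", "read_count_table", "write_results"]


@dataclass
class CountMatrix:
    """A gene x sample matrix of nonnegative integer read counts.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per row (length ``G``).
    sample_ids
        Unique sample identifiers, one per column.
    counts
        ``(G, n_samples)`` array of nonnegative integers.
    """

    gene_ids: list
    sample_ids: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        g, n = self.counts.shape
        if g < 1:
            raise ValueError("need at least one gene")
        if n < 2:
            raise ValueError("need at least two samples")
        if len(self.gene_ids) != g:
            raise ValueError("gene_ids length does not match counts rows")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match counts columns")
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicate gene IDs")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample IDs")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_float = np.asarray(self.counts, dtype=float)
            if not np.all(np.isfinite(as_float)):
                raise ValueError("counts contain non-finite values")
            if np.any(as_float != np.round(as_float)):
                raise ValueError("counts must be integral")
            self.counts = as_float.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> np.ndarray:
        """Per-sample total counts (column sums)."""
        return self.counts.sum(axis=0)


@dataclass
class GroupDesign:
    """Assignment of samples to compared groups.

    ``group_names`` lists the ``I`` groups in order of first appearance in
    the sample labels; ``group_index`` holds, per sample, the 0-based index
    into ``group_names``.  All group-ordered quantities downstream (effect
    vectors, cluster centers) follow this order.
    """

    group_names: list
    group_index: np.ndarray

    def __post_init__(self) -> None:
        self.group_names = list(self.group_names)
        self.group_index = np.asarray(self.group_index, dtype=np.int64)
        if self.group_index.ndim != 1:
            raise ValueError("group_index must be 1-D")
        i = len(self.group_names)
        if i < 1:
            raise ValueError("need at least one group")
        if self.group_index.min(initial=0) < 0 or (
            self.group_index.size and self.group_index.max() >= i
        ):
            raise ValueError("group_index out of range")
        counts = np.bincount(self.group_index, minlength=i)
        if np.any(counts < 1):
            raise ValueError("every group needs at least one replicate")

    @classmethod
    def from_labels(cls, labels: Sequence[str]) -> "GroupDesign":
        """Build a design from per-sample labels, groups ordered by first appearance."""
        names: list = []
        index = []
        for lab in labels:
            if lab not in names:
                names.append(lab)
            index.append(names.index(lab))
        return cls(group_names=names, group_index=np.asarray(index))

    @property
    def n_groups(self) -> int:
        return len(self.group_names)

    @property
    def replicates(self) -> np.ndarray:
        """Number of replicates per group (length ``I``)."""
        return np.bincount(self.group_index, minlength=self.n_groups)


def read_count_table(path, group_labels: Sequence[str]):
    """Read a tab-delimited count table and pair it with a group design.

    The file must have one header row of sample IDs and a first column of
    gene IDs.  ``group_labels`` gives, per data column, the group of the
    corresponding sample; group indices are assigned in order of first
    appearance.  Both LF and CRLF line endings are accepted.

    Returns
    -------
    (CountMatrix, GroupDesign)
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if raw.shape[1] < 1:
        raise ValueError(f"{path}: no sample columns found")
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene ID {dup!r}")
    if pd.Index(raw.columns).duplicated().any():
        raise ValueError(f"{path}: duplicate sample IDs in header")
    if len(group_labels) != raw.shape[1]:
        raise ValueError(
            f"{len(group_labels)} group labels given for {raw.shape[1]} samples"
        )

    counts = np.empty(raw.shape, dtype=np.int64)
    for j, col in enumerate(raw.columns):
        vals = pd.to_numeric(raw[col].str.strip(), errors="coerce")
        if vals.isna().any():
            gene = raw.index[int(np.argmax(vals.isna().to_numpy()))]
            raise ValueError(
                f"{path}: non-numeric count at gene {gene!r}, sample {col!r}"
            )
        arr = vals.to_numpy(dtype=float)
        if np.any(arr < 0):
            gene = raw.index[int(np.argmax(arr < 0))]
            raise ValueError(
                f"{path}: negative count at gene {gene!r}, sample {col!r}"
            )
        if np.any(arr != np.round(arr)):
            gene = raw.index[int(np.argmax(arr != np.round(arr)))]
            raise ValueError(
                f"{path}: non-integral count at gene {gene!r}, sample {col!r}"
            )
        counts[:, j] = arr.astype(np.int64)

    matrix = CountMatrix(
        gene_ids=list(raw.index), sample_ids=list(raw.columns), counts=counts
    )
    design = GroupDesign.from_labels(list(group_labels))
    return matrix, design


def write_results(result, path) -> None:
    """Write a DEG result table as TSV.

    Columns: ``gene_id``, ``cluster`` (1-based, by maximum posterior, lowest
    index on ties), ``pp_1 .. pp_K``, ``nondeg_pp``, ``de_score``, ``rank``.
    Floats are printed with six decimals; genes keep their input order.
    """
    post = result.model.posteriors
    k = post.shape[1]
    frame = pd.DataFrame({"gene_id": result.gene_ids})
    frame["cluster"] = post.argmax(axis=1) + 1 if len(frame) else []
    for kk in range(k):
        frame[f"pp_{kk + 1}"] = post[:, kk]
    frame["nondeg_pp"] = result.nondeg_pp
    frame["de_score"] = result.de_score
    frame["rank"] = result.rank
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")
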