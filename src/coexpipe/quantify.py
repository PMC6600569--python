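"""Count containers, RPKM normalization and per-comparison log2 ratios.

RPKM (reads per kilobase of transcript per million mapped reads) is the
length- and depth-normalized expression unit used throughout the pipeline:

    rpkm[g, s] = 1e9 * counts[g, s] / (library_size[s] * length[g])

Fold changes between two samples are computed on pseudocounted RPKM so that
genes silent in one condition have a finite, sign-correct log2 ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "compute_rpkm",
    "log2_ratio",
    "default_comparisons",
]


@dataclass
class CountMatrix:
    """Integer read counts per gene per sample, with gene lengths.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per row of ``counts``.
    lengths
        Transcript length in bp per gene (>= 1).
    counts
        Non-negative integer matrix, genes x samples.
    sample_labels
        One label per column, e.g. ``["0h", "2h", "4h"]``.
    library_sizes
        Total mapped reads per sample.  When omitted it defaults to the
        column sum of ``counts``; a supplied value may exceed the column
        sum (reads mapped outside the quantified gene set).
    """

    gene_ids: list[str]
    lengths: np.ndarray
    counts: np.ndarray
    sample_labels: list[str]
    library_sizes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_labels = list(self.sample_labels)
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x samples matrix")
        n_genes, n_samples = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} count rows"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids must be unique")
        if len(self.sample_labels) != n_samples:
            raise ValueError(
                f"{len(self.sample_labels)} sample labels for "
                f"{n_samples} count columns"
            )
        if self.lengths.shape != (n_genes,):
            raise ValueError("lengths must have one entry per gene")
        if (self.lengths < 1).any():
            bad = self.gene_ids[int(np.argmax(self.lengths < 1))]
            raise ValueError(f"gene {bad!r} has non-positive length")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(np.int64)
        else:
            self.library_sizes = np.asarray(self.library_sizes, dtype=np.int64)
        if self.library_sizes.shape != (n_samples,):
            raise ValueError("library_sizes must have one entry per sample")
        if (self.library_sizes < 1).any():
            bad = self.sample_labels[int(np.argmax(self.library_sizes < 1))]
            raise ValueError(f"sample {bad!r} has non-positive library size")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_index(self, label: str) -> int:
        try:
            return self.sample_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown sample label {label!r}") from None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.sample_labels)
        df.insert(0, "length", self.lengths)
        df.insert(0, "gene_id", self.gene_ids)
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path: str | Path, library_sizes: Sequence[int] | None = None
    ) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t")
        if list(df.columns[:2]) != ["gene_id", "length"]:
            raise ValueError(
                "count table must start with 'gene_id' and 'length' columns"
            )
        samples = list(df.columns[2:])
        return cls(
            gene_ids=df["gene_id"].astype(str).tolist(),
            lengths=df["length"].to_numpy(),
            counts=df[samples].to_numpy(),
            sample_labels=samples,
            library_sizes=None if library_sizes is None else np.asarray(library_sizes),
        )


@dataclass
class ExpressionMatrix:
    """Non-negative RPKM values per gene per sample."""

    gene_ids: list[str]
    sample_labels: list[str]
    rpkm: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.rpkm = np.asarray(self.rpkm, dtype=float)
        if self.rpkm.shape != (len(self.gene_ids), len(self.sample_labels)):
            raise ValueError("rpkm shape does not match id/label lists")
        if (self.rpkm < 0).any():
            raise ValueError("rpkm must be non-negative")

    def sample_index(self, label: str) -> int:
        try:
            return self.sample_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown sample label {label!r}") from None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rpkm, columns=self.sample_labels)
        df.insert(0, "gene_id", self.gene_ids)
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t")
        samples = list(df.columns[1:])
        return cls(
            gene_ids=df["gene_id"].astype(str).tolist(),
            sample_labels=samples,
            rpkm=df[samples].to_numpy(dtype=float),
        )


def compute_rpkm(counts: CountMatrix) -> ExpressionMatrix:
    """Normalize a count matrix to RPKM.

    Zero counts map to zero RPKM; lengths and library sizes are validated
    by :class:`CountMatrix`, so the division is always well defined.
    """
    denom = counts.library_sizes.astype(float)[None, :] * counts.lengths.astype(
        float
    )[:, None]
    rpkm = 1e9 * counts.counts / denom
    return ExpressionMatrix(
        gene_ids=counts.gene_ids,
        sample_labels=counts.sample_labels,
        rpkm=rpkm,
    )


def default_comparisons(sample_labels: Sequence[str]) -> list[tuple[str, str]]:
    """All ordered (earlier, later) sample pairs in time order.

    For the canonical three-point design ``["0h", "2h", "4h"]`` this yields
    (0h, 2h), (0h, 4h) and (2h, 4h).
    """
    labels = list(sample_labels)
    return [
        (labels[i], labels[j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    ]


def log2_ratio(
    expr: ExpressionMatrix,
    comparison: tuple[str, str],
    pseudocount: float = 1.0,
) -> np.ndarray:
    """Per-gene log2 fold change of the later sample over the earlier one.

    ``log2((rpkm_later + p) / (rpkm_earlier + p))`` with pseudocount ``p``
    in RPKM units.  With a symmetric pseudocount the value is antisymmetric
    under reversing the comparison.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    earlier, later = comparison
    a = expr.rpkm[:, expr.sample_index(earlier)]
    b = expr.rpkm[:, expr.sample_index(later)]
    with np.errstate(divide="ignore"):
        return np.log2(b + pseudocount) - np.log2(a + pseudocount)


def log2_ratio_counts(
    counts: CountMatrix,
    comparison: tuple[str, str],
    pseudocount: float = 1.0,
) -> np.ndarray:
    """Log2 ratio computed on raw counts instead of RPKM (optional route)."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    earlier, later = comparison
    a = counts.counts[:, counts.sample_index(earlier)].astype(float)
    b = counts.counts[:, counts.sample_index(later)].astype(float)
    with np.errstate(divide="ignore"):
        return np.log2(b + pseudocount) - np.log2(a + pseudocount)
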