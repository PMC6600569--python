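"""No-replicate differential expression via the Audic-Claverie exact test.

Given counts x and y of one gene in two libraries of sizes N1 and N2, the
Audic-Claverie model treats y conditionally on x as

    p(y | x) = C(x + y, y) * q**y * (1 - q)**(x + 1),   q = N2 / (N1 + N2)

which is the negative-binomial pmf with x + 1 successes and success
probability N1 / (N1 + N2).  Tail sums of this series give exact one-sided
p-values; the two-sided p is twice the smaller tail, capped at 1.

All tail accumulation happens in log space (log-sum-exp over log pmf
terms); the upper tail is truncated once terms fall below 1e-16 of the
running maximum, so the summation is exact to double precision.

A gene is called differentially expressed for a comparison when its BH
q-value, absolute log2 ratio and abundance clear a configurable threshold
set; all threshold comparisons are inclusive.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .quantify import (
    CountMatrix,
    ExpressionMatrix,
    default_comparisons,
    log2_ratio,
    log2_ratio_counts,
)

__all__ = [
    "ThresholdSet",
    "ac_pvalue",
    "bh_fdr",
    "call_degs",
    "deg_sets",
    "venn_partition",
    "VennPartition",
]

#: abundance / FDR / fold-change presets named after their use
THRESHOLD_PRESETS = {
    "strict": (2.0, 0.05, 2.0),  # main DEG set
    "lenient": (0.0, 0.05, 2.0),  # abundance-unfiltered DEG set
    "gcn": (0.0, 0.05, 1.5),  # eligibility for the co-expression network
}


@dataclass(frozen=True)
class ThresholdSet:
    """Inclusive filters applied to each (gene, comparison) test."""

    min_rpkm: float = 2.0
    max_fdr: float = 0.05
    min_abs_log2: float = 2.0

    def __post_init__(self) -> None:
        if not (
            math.isfinite(self.min_rpkm)
            and math.isfinite(self.max_fdr)
            and math.isfinite(self.min_abs_log2)
        ):
            raise ValueError("thresholds must be finite")
        if self.min_rpkm < 0 or self.min_abs_log2 < 0:
            raise ValueError("min_rpkm and min_abs_log2 must be >= 0")
        if not 0 < self.max_fdr <= 1:
            raise ValueError("max_fdr must lie in (0, 1]")

    @classmethod
    def preset(cls, name: str) -> "ThresholdSet":
        return cls(*THRESHOLD_PRESETS[name])


def _log_pmf(y: np.ndarray, x: int, log_q: float, log_1mq: float) -> np.ndarray:
    """log p(y | x) of the conditional (negative-binomial) series."""
    return (
        gammaln(x + y + 1)
        - gammaln(y + 1)
        - gammaln(x + 1)
        + y * log_q
        + (x + 1) * log_1mq
    )


def ac_pvalue(x: int, y: int, N1: int, N2: int) -> float:
    """Two-sided Audic-Claverie p-value for counts x (library N1) and y (N2).

    Exact log-space tail summation; symmetric under swapping (x, N1) with
    (y, N2).
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if N1 < 1 or N2 < 1:
        raise ValueError("library sizes must be >= 1")
    q = N2 / (N1 + N2)
    log_q = math.log(q)
    log_1mq = math.log1p(-q)

    # lower tail: finite sum over y' = 0..y
    lower = logsumexp(_log_pmf(np.arange(y + 1), x, log_q, log_1mq))

    # upper tail: chunked sum from y upward until terms are negligible
    chunk = 512
    start = y
    pieces = []
    peak = -np.inf
    while True:
        ys = np.arange(start, start + chunk)
        lp = _log_pmf(ys, x, log_q, log_1mq)
        pieces.append(lp)
        peak = max(peak, float(lp.max()))
        if lp[-1] < peak + math.log(1e-16):
            break
        start += chunk
    upper = logsumexp(np.concatenate(pieces))

    p = 2.0 * math.exp(min(lower, upper))
    # the point mass at y keeps both tails positive mathematically; guard
    # against exp() underflow so p stays in (0, 1]
    return min(1.0, max(p, 2.2250738585072014e-308))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, order preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    expr: ExpressionMatrix,
    counts: CountMatrix,
    thresholds: ThresholdSet = ThresholdSet(),
    comparisons: Sequence[tuple[str, str]] | None = None,
    pseudocount: float = 1.0,
    ratio_on: str = "rpkm",
) -> pd.DataFrame:
    """Test every gene in every comparison and apply the DEG filters.

    Returns a tidy table with one row per (gene, comparison):
    ``gene_id comparison x y log2_ratio p q direction passes`` where
    ``direction`` is up/down by the sign of the log2 ratio for passing
    genes and ``none`` otherwise.  BH correction is applied within each
    comparison separately.
    """
    if expr.gene_ids != counts.gene_ids:
        raise ValueError("expression and count matrices are not aligned")
    if counts.n_genes == 0:
        raise ValueError("empty count matrix")
    if comparisons is None:
        comparisons = default_comparisons(counts.sample_labels)
    if ratio_on not in ("rpkm", "counts"):
        raise ValueError("ratio_on must be 'rpkm' or 'counts'")

    frames = []
    for comp in comparisons:
        i = counts.sample_index(comp[0])
        j = counts.sample_index(comp[1])
        x = counts.counts[:, i]
        y = counts.counts[:, j]
        N1 = int(counts.library_sizes[i])
        N2 = int(counts.library_sizes[j])
        if ratio_on == "rpkm":
            lr = log2_ratio(expr, comp, pseudocount)
        else:
            lr = log2_ratio_counts(counts, comp, pseudocount)
        p = np.array([ac_pvalue(int(xi), int(yi), N1, N2) for xi, yi in zip(x, y)])
        q = bh_fdr(p)
        max_rpkm = np.maximum(
            expr.rpkm[:, expr.sample_index(comp[0])],
            expr.rpkm[:, expr.sample_index(comp[1])],
        )
        passes = (
            (q <= thresholds.max_fdr)
            & (np.abs(lr) >= thresholds.min_abs_log2)
            & (max_rpkm >= thresholds.min_rpkm)
        )
        direction = np.where(
            ~passes, "none", np.where(lr > 0, "up", "down")
        )
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": counts.gene_ids,
                    "comparison": f"{comp[0]}_vs_{comp[1]}",
                    "x": x,
                    "y": y,
                    "log2_ratio": lr,
                    "p": p,
                    "q": q,
                    "direction": direction,
                    "passes": passes,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def deg_sets(table: pd.DataFrame) -> dict[str, set[str]]:
    """Passing gene sets keyed by comparison label."""
    out: dict[str, set[str]] = {}
    for comp, sub in table.groupby("comparison", sort=False):
        out[str(comp)] = set(sub.loc[sub["passes"], "gene_id"])
    return out


@dataclass
class VennPartition:
    """Disjoint three-set region counts with percentages of the union.

    Region keys use the set names, ``A_only`` / ``A_and_B`` /
    ``A_and_B_and_C`` style; percentages are relative to the union size
    and rounded to one decimal.
    """

    region_counts: dict[str, int]
    totals: dict[str, int]
    union_size: int

    @property
    def percentages(self) -> dict[str, float]:
        if self.union_size == 0:
            return {k: 0.0 for k in self.region_counts}
        return {
            k: round(100.0 * v / self.union_size, 1)
            for k, v in self.region_counts.items()
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "region_counts": self.region_counts,
                    "percentages": self.percentages,
                    "totals": self.totals,
                    "union_size": self.union_size,
                },
                indent=1,
                sort_keys=True,
            )
            + "\n"
        )


def venn_partition(sets: Mapping[str, Iterable[str]]) -> VennPartition:
    """Partition three named gene sets into the 7 disjoint Venn regions."""
    if len(sets) != 3:
        raise ValueError("exactly three named sets are required")
    names = list(sets)
    A, B, C = (set(sets[n]) for n in names)
    a, b, c = names
    regions = {
        f"{a}_only": A - B - C,
        f"{b}_only": B - A - C,
        f"{c}_only": C - A - B,
        f"{a}_and_{b}": (A & B) - C,
        f"{a}_and_{c}": (A & C) - B,
        f"{b}_and_{c}": (B & C) - A,
        f"{a}_and_{b}_and_{c}": A & B & C,
    }
    return VennPartition(
        region_counts={k: len(v) for k, v in regions.items()},
        totals={a: len(A), b: len(B), c: len(C)},
        union_size=len(A | B | C),
    )


def venn_percentages(region_counts: Sequence[int], union_size: int) -> list[float]:
    """Percentages (1 decimal) of given region counts over a union size."""
    if union_size <= 0:
        raise ValueError("union size must be positive")
    return [round(100.0 * c / union_size, 1) for c in region_counts]


def triple_intersection_count(
    six_region_counts: Sequence[int], union_size: int
) -> int:
    """Recover the triple-overlap count from the six other region counts.

    The seven disjoint regions sum to the union, so the center region is
    the union size minus the six singleton/pairwise regions.
    """
    rest = int(sum(six_region_counts))
    if rest > union_size:
        raise ValueError("region counts exceed the union size")
    return union_size - rest
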