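"""Hypergeometric term enrichment of gene modules.

For a module of n genes drawn from a background of N genes, K of which
carry a term, the enrichment p-value of observing k or more carriers in
the module is the upper tail of the hypergeometric distribution:

    p = P(X >= k),  X ~ Hypergeometric(N, K, n)

Terms mapping to fewer than ``min_mapped`` module genes are excluded
before testing; the Benjamini-Hochberg adjustment is applied across the
tested terms within each module, and a term is significant when its
adjusted q falls below ``alpha``.  Plain Hochberg step-up is available as
an alternative adjustment.  Terms are flat identifiers — no ontology DAG
propagation is performed (up-propagate parents beforehand if desired).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .syndata import AnnotationMap

__all__ = ["hypergeom_pvalue", "hypergeom_enrichment", "enrich_modules"]


def hypergeom_pvalue(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not 0 <= k <= min(n, K):
        raise ValueError("need 0 <= k <= min(n, K)")
    if K > N or n > N:
        raise ValueError("K and n cannot exceed the background size N")
    return float(hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrichment(
    module_genes: Iterable[str],
    annotation: AnnotationMap,
    min_mapped: int = 2,
    alpha: float = 0.05,
    method: str = "fdr_bh",
) -> pd.DataFrame:
    """Test every annotation term for over-representation in one module.

    Returns a table ``term k n K N p q significant`` sorted by p; terms
    with fewer than ``min_mapped`` module genes are dropped before
    testing (and before the multiple-testing correction).
    """
    module = set(module_genes)
    if not module:
        raise ValueError("empty module")
    background = set(annotation.background)
    if not annotation.gene_terms:
        raise ValueError("empty annotation map")
    outside = module - background
    if outside:
        raise ValueError(
            f"module genes outside the background universe: {sorted(outside)[:5]}"
        )
    if method not in ("fdr_bh", "hochberg"):
        raise ValueError("method must be 'fdr_bh' or 'hochberg'")

    N = len(background)
    n = len(module)
    rows = []
    for term in sorted(annotation.term_universe):
        carriers = annotation.genes_with_term(term)
        k = len(carriers & module)
        if k < min_mapped:
            continue
        K = len(carriers)
        rows.append(
            {
                "term": term,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p": hypergeom_pvalue(k, N, K, n),
            }
        )
    df = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "p"])
    if len(df):
        sm_method = "simes-hochberg" if method == "hochberg" else method
        df["q"] = multipletests(df["p"].to_numpy(), method=sm_method)[1]
        df["significant"] = df["q"] < alpha
        df = df.sort_values(["p", "term"], ignore_index=True)
    else:
        df["q"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df


def enrich_modules(
    modules: Mapping[int, Iterable[str]],
    annotation: AnnotationMap,
    min_mapped: int = 2,
    alpha: float = 0.05,
    method: str = "fdr_bh",
) -> pd.DataFrame:
    """Per-module enrichment over all modules; adds a ``module`` column."""
    frames = []
    for mid in sorted(modules):
        df = hypergeom_enrichment(
            modules[mid], annotation, min_mapped=min_mapped, alpha=alpha, method=method
        )
        df.insert(0, "module", mid)
        frames.append(df)
    if not frames:
        raise ValueError("no modules to test")
    return pd.concat(frames, ignore_index=True)
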