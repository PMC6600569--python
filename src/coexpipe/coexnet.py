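"""Highest-reciprocal-rank (HRR) co-expression network construction.

For each gene, all other genes are ranked by descending Pearson
correlation of their expression profiles (rank 1 = most correlated;
negative correlations rank last; ties broken by ascending gene order for
reproducibility).  The HRR of a pair is the worse of the two mutual
ranks:

    HRR(A, B) = max(rank_A(B), rank_B(A))

and an edge is kept when HRR <= cutoff (30 by default).  Low HRR means
both genes place each other near the top of their neighbor lists, which
is robust to the hub-dominance of raw correlation thresholds.  Edge
weights are 1 / HRR, so the conventional cutoffs 5 / 15 / 25 correspond
to weights 0.2 / 0.067 / 0.04 (3 decimals).

Correlations are computed on log2(RPKM + 1).  With very short profiles
(fewer than 4 samples) Pearson r is close to degenerate and a warning is
emitted; the construction is still well defined.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "pearson_matrix",
    "hrr_matrix",
    "build_network",
    "network_stats",
    "NetworkStats",
    "hrr_weight",
]


def hrr_weight(hrr: int, ndigits: int = 3) -> float:
    """Edge weight 1/HRR, rounded for reporting (0.2 / 0.067 / 0.04)."""
    if hrr < 1:
        raise ValueError("HRR scores are positive integers")
    return round(1.0 / hrr, ndigits)


def pearson_matrix(profiles: np.ndarray, gene_ids: list[str] | None = None):
    """Pairwise Pearson correlation of gene expression profiles.

    ``profiles`` is genes x samples.  Zero-variance genes have undefined
    correlation; their rows/columns are set to 0 (diagonal stays 1) and
    the list of offending genes is returned alongside the matrix.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[1] < 2:
        raise ValueError("need a genes x samples matrix with >= 2 samples")
    if profiles.shape[1] < 4:
        warnings.warn(
            f"Pearson correlation over only {profiles.shape[1]} samples is "
            "nearly degenerate; interpret HRR edges with caution",
            stacklevel=2,
        )
    sd = profiles.std(axis=1)
    constant = np.flatnonzero(sd == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(profiles)
    corr = np.asarray(corr, dtype=float)
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    flagged = (
        [gene_ids[i] for i in constant] if gene_ids is not None else list(constant)
    )
    return corr, flagged


def hrr_matrix(corr: np.ndarray) -> np.ndarray:
    """Integer HRR scores from a symmetric correlation matrix.

    Per row, neighbors are ranked by descending r (self excluded, best
    rank 1, ties by ascending index); HRR is the elementwise max of the
    rank matrix and its transpose.  The diagonal is 0 (unused).
    """
    corr = np.asarray(corr, dtype=float)
    n = corr.shape[0]
    if corr.ndim != 2 or corr.shape != (n, n):
        raise ValueError("correlation matrix must be square")
    if n < 3:
        raise ValueError("HRR needs at least 3 genes (ranks degenerate)")
    if not np.allclose(corr, corr.T, atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")

    ranks = np.zeros((n, n), dtype=np.int64)
    idx = np.arange(n)
    for i in range(n):
        others = idx[idx != i]
        # stable sort on ascending index, then by descending r
        order = others[np.argsort(-corr[i, others], kind="stable")]
        ranks[i, order] = np.arange(1, n)
    return np.maximum(ranks, ranks.T)


def build_network(
    hrr: np.ndarray,
    gene_ids: list[str],
    cutoff: int = 30,
    corr: np.ndarray | None = None,
) -> nx.Graph:
    """Simple undirected graph with edges where HRR <= cutoff (inclusive).

    Every gene becomes a node; genes whose best reciprocal rank exceeds
    the cutoff remain isolated.  Edge attributes: ``hrr`` (int), ``weight``
    (exactly 1/hrr) and, when ``corr`` is given, ``r``.
    """
    if cutoff < 1:
        raise ValueError("HRR cutoff must be >= 1")
    hrr = np.asarray(hrr)
    n = len(gene_ids)
    if hrr.shape != (n, n):
        raise ValueError("HRR matrix does not match gene list")
    g = nx.Graph()
    g.add_nodes_from(gene_ids)
    ii, jj = np.nonzero(np.triu(hrr <= cutoff, k=1))
    for i, j in zip(ii, jj):
        score = int(hrr[i, j])
        attrs = {"hrr": score, "weight": 1.0 / score}
        if corr is not None:
            attrs["r"] = float(corr[i, j])
        g.add_edge(gene_ids[i], gene_ids[j], **attrs)
    return g


@dataclass
class NetworkStats:
    """Topology summary matching the usual graph-analyzer panel."""

    n_nodes: int
    clustering_coefficient: float
    avg_neighbors: float
    connected_components: int
    diameter: int
    radius: int
    density: float
    heterogeneity: float
    centralization: float
    isolated_nodes: int
    shortest_paths: int
    shortest_paths_percent: float
    characteristic_path_length: float
    self_loops: int = 0
    multi_edge_pairs: int = 0
    _extras: dict = field(default_factory=dict, repr=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "clustering_coefficient": self.clustering_coefficient,
            "avg_number_of_neighbours": self.avg_neighbors,
            "connected_components": self.connected_components,
            "number_of_nodes": self.n_nodes,
            "network_diameter": self.diameter,
            "network_density": self.density,
            "network_radius": self.radius,
            "network_heterogeneity": self.heterogeneity,
            "network_centralization": self.centralization,
            "isolated_nodes": self.isolated_nodes,
            "shortest_paths": self.shortest_paths,
            "shortest_paths_percent": self.shortest_paths_percent,
            "number_of_self_loops": self.self_loops,
            "characteristic_path_length": self.characteristic_path_length,
            "multi_edge_node_pairs": self.multi_edge_pairs,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def density_from_mean_degree(n_nodes: int, mean_degree: float) -> float:
    """Density = mean degree / (n - 1)."""
    if n_nodes < 2:
        raise ValueError("density undefined for fewer than 2 nodes")
    return mean_degree / (n_nodes - 1)


def network_stats(g: nx.Graph) -> NetworkStats:
    """Topology statistics of a simple undirected graph.

    Definitions: clustering coefficient averages local coefficients over
    nodes of degree >= 2; density = mean degree / (n-1); heterogeneity =
    coefficient of variation of the degree sequence; centralization =
    n/(n-2) * (max_degree/(n-1) - density); diameter and radius are the
    max / min eccentricity over non-isolated nodes, eccentricities taken
    within each connected component; shortest paths counts ordered
    connected node pairs and the characteristic path length averages
    their distances.
    """
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    mean_deg = float(degrees.mean())
    density = mean_deg / (n - 1) if n > 1 else 0.0
    heterogeneity = float(degrees.std() / mean_deg) if mean_deg > 0 else 0.0
    centralization = (
        (n / (n - 2)) * (degrees.max() / (n - 1) - density) if n > 2 else 0.0
    )

    local = nx.clustering(g)
    eligible = [v for v in g if g.degree(v) >= 2]
    cc = float(np.mean([local[v] for v in eligible])) if eligible else 0.0

    isolated = [v for v in g if g.degree(v) == 0]
    components = list(nx.connected_components(g))

    ecc_all: list[int] = []
    n_pairs = 0
    dist_sum = 0
    for comp in components:
        if len(comp) == 1:
            continue
        sub = g.subgraph(comp)
        sp = dict(nx.all_pairs_shortest_path_length(sub))
        for v, dists in sp.items():
            ecc_all.append(max(dists.values()))
            n_pairs += len(dists) - 1
            dist_sum += sum(dists.values())

    diameter = max(ecc_all) if ecc_all else 0
    radius = min(ecc_all) if ecc_all else 0
    cpl = dist_sum / n_pairs if n_pairs else 0.0

    return NetworkStats(
        n_nodes=n,
        clustering_coefficient=cc,
        avg_neighbors=mean_deg,
        connected_components=len(components),
        diameter=diameter,
        radius=radius,
        density=density,
        heterogeneity=heterogeneity,
        centralization=centralization,
        isolated_nodes=len(isolated),
        shortest_paths=n_pairs,
        shortest_paths_percent=100.0 * n_pairs / (n * (n - 1)) if n > 1 else 0.0,
        characteristic_path_length=cpl,
    )


def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    """TSV edge list ``geneA geneB r hrr weight`` (r blank when absent)."""
    rows = []
    for u, v, data in sorted(g.edges(data=True)):
        rows.append(
            {
                "geneA": u,
                "geneB": v,
                "r": data.get("r", np.nan),
                "hrr": data["hrr"],
                "weight": data["weight"],
            }
        )
    pd.DataFrame(rows, columns=["geneA", "geneB", "r", "hrr", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def read_edge_list(path: str | Path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    for row in df.itertuples(index=False):
        attrs = {"hrr": int(row.hrr), "weight": float(row.weight)}
        if not pd.isna(row.r):
            attrs["r"] = float(row.r)
        g.add_edge(str(row.geneA), str(row.geneB), **attrs)
    return g


def write_sif(g: nx.Graph, path: str | Path) -> None:
    """SIF export (``geneA <hrr> geneB``) for graph viewers; isolated
    nodes are written as bare single-column rows."""
    with open(path, "w") as fh:
        for u, v, data in sorted(g.edges(data=True)):
            fh.write(f"{u}\t{data['hrr']}\t{v}\n")
        for v in sorted(g):
            if g.degree(v) == 0:
                fh.write(f"{v}\n")
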