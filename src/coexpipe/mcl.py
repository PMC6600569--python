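"""Markov cluster algorithm (MCL) over the co-expression network.

MCL simulates flow on the graph: a column-stochastic transition matrix is
alternately *expanded* (matrix power, letting flow spread) and *inflated*
(elementwise power followed by column renormalization, strengthening
strong currents and pruning weak ones) until the matrix converges to a
collection of attractor stars whose basins are the clusters.  Inflation
controls granularity; the pipeline default is 1.6.

Self-loops are added before normalization — each node gets a loop equal
to its maximum incident edge weight (1 for isolated nodes) — which damps
the period-2 oscillations of bipartite-ish flow.  Entries below a prune
threshold are zeroed after each inflation to keep the matrix sparse-ish
and the iteration strictly deterministic.

Clusters are read off the limit matrix: attractors are nodes with
positive diagonal mass; each non-attractor joins the attractor(s) that
hold flow from it.  Nodes attracted by several attractor systems (rare
overlap) are assigned to the largest cluster, smallest cluster id on
ties.  Clusters of at least ``min_module_size`` genes are flagged as
modules.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["MclParams", "ModulePartition", "mcl_cluster", "module_composition"]


@dataclass(frozen=True)
class MclParams:
    inflation: float = 1.6
    expansion: int = 2
    prune_threshold: float = 1e-5
    convergence_tol: float = 1e-6
    max_iterations: int = 100
    min_module_size: int = 15

    def __post_init__(self) -> None:
        if not self.inflation > 1:
            raise ValueError("inflation must be > 1")
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")
        if self.prune_threshold <= 0 or self.convergence_tol <= 0:
            raise ValueError("prune_threshold and convergence_tol must be > 0")
        if self.max_iterations < 1 or self.min_module_size < 1:
            raise ValueError("max_iterations and min_module_size must be >= 1")


@dataclass
class ModulePartition:
    """Cluster assignment for every network node.

    Cluster ids are 1-based and ordered by decreasing size (ties by the
    smallest member's node order).  ``is_module`` marks clusters with at
    least ``min_module_size`` members.
    """

    assignment: dict[str, int]
    min_module_size: int
    converged: bool = True
    iterations: int = 0

    @property
    def cluster_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for c in self.assignment.values():
            sizes[c] = sizes.get(c, 0) + 1
        return dict(sorted(sizes.items()))

    @property
    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for g, c in self.assignment.items():
            out.setdefault(c, []).append(g)
        return dict(sorted(out.items()))

    def is_module(self, cluster_id: int) -> bool:
        return self.cluster_sizes[cluster_id] >= self.min_module_size

    @property
    def module_ids(self) -> list[int]:
        return [c for c, s in self.cluster_sizes.items() if s >= self.min_module_size]

    def to_frame(self) -> pd.DataFrame:
        sizes = self.cluster_sizes
        rows = [
            {
                "gene_id": g,
                "cluster_id": c,
                "cluster_size": sizes[c],
                "is_module": sizes[c] >= self.min_module_size,
            }
            for g, c in self.assignment.items()
        ]
        return pd.DataFrame(rows).sort_values(
            ["cluster_id", "gene_id"], ignore_index=True
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def summary(self) -> dict:
        sizes = self.cluster_sizes
        module_sizes = [s for s in sizes.values() if s >= self.min_module_size]
        return {
            "n_clusters": len(sizes),
            "n_modules": len(module_sizes),
            "genes_in_modules": int(sum(module_sizes)),
            "module_size_min": min(module_sizes) if module_sizes else 0,
            "module_size_max": max(module_sizes) if module_sizes else 0,
            "converged": self.converged,
            "iterations": self.iterations,
        }


def _normalize_columns(m: np.ndarray) -> np.ndarray:
    colsum = m.sum(axis=0, keepdims=True)
    colsum[colsum == 0] = 1.0
    return m / colsum


def _interpret(limit: np.ndarray, nodes: list[str], tol: float) -> dict[str, int]:
    """Read clusters off the converged flow matrix (column-stochastic:
    limit[i, j] is flow from node j retained at node i)."""
    n = len(nodes)
    attractors = np.flatnonzero(np.diag(limit) > tol)
    if attractors.size == 0:  # degenerate; every node on its own
        return {g: i + 1 for i, g in enumerate(nodes)}

    # group attractors that share any attracted node into attractor systems
    sys_graph = nx.Graph()
    sys_graph.add_nodes_from(attractors.tolist())
    support = [np.flatnonzero(limit[a, :] > tol) for a in attractors]
    for ai in range(len(attractors)):
        for aj in range(ai + 1, len(attractors)):
            if np.intersect1d(support[ai], support[aj]).size:
                sys_graph.add_edge(attractors[ai], attractors[aj])
    systems = [sorted(c) for c in nx.connected_components(sys_graph)]
    systems.sort(key=lambda s: s[0])

    raw_clusters = []
    for system in systems:
        members: set[int] = set(system)
        for a in system:
            members.update(np.flatnonzero(limit[a, :] > tol).tolist())
        raw_clusters.append(members)

    # resolve overlaps: largest cluster wins, then smallest cluster index
    owner: dict[int, int] = {}
    order = sorted(
        range(len(raw_clusters)),
        key=lambda k: (-len(raw_clusters[k]), k),
    )
    for k in order:
        for node in raw_clusters[k]:
            owner.setdefault(node, k)
    for i in range(n):  # orphan guard: nodes that lost all flow
        owner.setdefault(i, len(raw_clusters) + i)

    # relabel clusters 1..K by decreasing size, ties by first member
    groups: dict[int, list[int]] = {}
    for node, k in owner.items():
        groups.setdefault(k, []).append(node)
    ordered = sorted(groups.values(), key=lambda ms: (-len(ms), min(ms)))
    assignment: dict[str, int] = {}
    for cid, members in enumerate(ordered, start=1):
        for node in members:
            assignment[nodes[node]] = cid
    return assignment


def mcl_cluster(
    g: nx.Graph, params: MclParams = MclParams(), weight: str = "weight"
) -> ModulePartition:
    """Partition a weighted undirected graph by Markov clustering.

    Fully deterministic; raises on an empty graph.  On non-convergence
    within ``max_iterations`` the current clustering is returned with
    ``converged = False`` and a warning.
    """
    nodes = list(g.nodes())
    n = len(nodes)
    if n == 0:
        raise ValueError("empty graph")
    a = nx.to_numpy_array(g, nodelist=nodes, weight=weight)
    if (a < 0).any():
        raise ValueError("edge weights must be positive")

    loop = a.max(axis=0)
    loop[loop == 0] = 1.0
    np.fill_diagonal(a, loop)
    m = _normalize_columns(a)

    converged = False
    iterations = 0
    for iterations in range(1, params.max_iterations + 1):
        prev = m
        m = np.linalg.matrix_power(m, params.expansion)
        m = _normalize_columns(np.power(m, params.inflation))
        m[m < params.prune_threshold] = 0.0
        m = _normalize_columns(m)
        if np.abs(m - prev).max() < params.convergence_tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MCL did not converge in {params.max_iterations} iterations; "
            "returning the current clustering",
            stacklevel=2,
        )

    assignment = _interpret(m, nodes, params.prune_threshold)
    return ModulePartition(
        assignment=assignment,
        min_module_size=params.min_module_size,
        converged=converged,
        iterations=iterations,
    )


def module_composition(
    partition: ModulePartition,
    deg_table: pd.DataFrame,
    comparison: str,
) -> pd.DataFrame:
    """Up/down composition of each cluster in one comparison.

    Fractions are over cluster members present in the DEG table for that
    comparison; a cluster with no tested members gets NaN fractions
    (undefined, not zero).
    """
    sub = deg_table[deg_table["comparison"] == comparison]
    direction = dict(zip(sub["gene_id"], sub["direction"]))
    rows = []
    for cid, members in partition.clusters.items():
        calls = [direction[g] for g in members if g in direction]
        n_called = len(calls)
        if n_called == 0:
            up = down = float("nan")
        else:
            up = calls.count("up") / n_called
            down = calls.count("down") / n_called
        rows.append(
            {
                "cluster_id": cid,
                "size": len(members),
                "n_in_deg_table": n_called,
                "up_fraction": up,
                "down_fraction": down,
            }
        )
    return pd.DataFrame(rows)
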