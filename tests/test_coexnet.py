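"""HRR network construction and topology statistics."""

import itertools

import networkx as nx
import numpy as np
import pytest

from coexpipe import coexnet
from coexpipe.coexnet import (
    build_network,
    density_from_mean_degree,
    hrr_matrix,
    hrr_weight,
    network_stats,
    pearson_matrix,
)


class TestPearson:
    def test_diagonal_and_perfect_linearity(self):
        corr, flagged = pearson_matrix(
            np.array([[1.0, 2, 3], [2, 4, 6], [3, 1, 2]])
        )
        assert flagged == []
        np.testing.assert_allclose(np.diag(corr), 1.0)
        assert corr[0, 1] == pytest.approx(1.0)
        np.testing.assert_allclose(corr, corr.T)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(5, 7))
        corr, _ = pearson_matrix(x)
        for i, j in itertools.combinations(range(5), 2):
            a, b = x[i] - x[i].mean(), x[j] - x[j].mean()
            r = (a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum())
            assert corr[i, j] == pytest.approx(r, abs=1e-12)

    def test_constant_gene_flagged_and_zeroed(self):
        corr, flagged = pearson_matrix(
            np.array([[1.0, 1, 1], [1, 2, 3], [3, 2, 1]]), ["a", "b", "c"]
        )
        assert flagged == ["a"]
        assert corr[0, 1] == 0.0 and corr[0, 0] == 1.0

    def test_short_profile_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            pearson_matrix(np.random.default_rng(1).normal(size=(4, 3)))


class TestHrr:
    def test_mutual_best_neighbors_get_rank_one(self):
        # a and b are each other's top neighbor
        corr = np.array(
            [
                [1.0, 0.9, 0.1, 0.0],
                [0.9, 1.0, 0.2, 0.1],
                [0.1, 0.2, 1.0, 0.3],
                [0.0, 0.1, 0.3, 1.0],
            ]
        )
        hrr = hrr_matrix(corr)
        assert hrr[0, 1] == 1
        np.testing.assert_array_equal(hrr, hrr.T)

    def test_matches_brute_force_rank_tables(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(8, 5))
        corr, _ = pearson_matrix(x)
        hrr = hrr_matrix(corr)
        n = 8
        for a in range(n):
            # exhaustive rank table for gene a: descending r, index tie-break
            others = sorted(
                (g for g in range(n) if g != a),
                key=lambda g: (-corr[a, g], g),
            )
            rank_a = {g: k + 1 for k, g in enumerate(others)}
            for b in range(n):
                if b == a:
                    continue
                others_b = sorted(
                    (g for g in range(n) if g != b),
                    key=lambda g: (-corr[b, g], g),
                )
                rank_b = {g: k + 1 for k, g in enumerate(others_b)}
                assert hrr[a, b] == max(rank_a[b], rank_b[a])

    def test_permutation_equivariant(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(7, 6))
        corr, _ = pearson_matrix(x)
        hrr = hrr_matrix(corr)
        perm = rng.permutation(7)
        hrr_p = hrr_matrix(corr[np.ix_(perm, perm)])
        np.testing.assert_array_equal(hrr_p, hrr[np.ix_(perm, perm)])

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            hrr_matrix(np.eye(2))


class TestBuildNetwork:
    def _hrr(self, n=6, seed=5):
        corr, _ = pearson_matrix(np.random.default_rng(seed).normal(size=(n, 5)))
        return hrr_matrix(corr), [f"g{i}" for i in range(n)]

    def test_cutoff_boundary_inclusive(self):
        hrr = np.array([[0, 30, 31], [30, 0, 1], [31, 1, 0]])
        g = build_network(hrr, ["a", "b", "c"], cutoff=30)
        assert g.has_edge("a", "b") and not g.has_edge("a", "c")
        assert g.has_edge("b", "c")

    @pytest.mark.parametrize("score,weight", [(5, 0.2), (15, 0.067), (25, 0.04)])
    def test_weight_rule_reproduces_reference_weights(self, score, weight):
        assert hrr_weight(score) == weight

    def test_weight_times_hrr_is_one_exactly(self):
        hrr, genes = self._hrr()
        g = build_network(hrr, genes, cutoff=5)
        for _, _, d in g.edges(data=True):
            assert d["weight"] * d["hrr"] == 1.0

    def test_raising_cutoff_only_adds_edges(self):
        hrr, genes = self._hrr(8)
        prev = set()
        for cutoff in (1, 2, 3, 5, 7):
            edges = set(build_network(hrr, genes, cutoff).edges())
            assert prev <= edges
            prev = edges

    def test_max_cutoff_keeps_every_ranked_pair(self):
        hrr, genes = self._hrr(5)
        g = build_network(hrr, genes, cutoff=4)  # n-1
        assert g.number_of_edges() == 10  # all pairs rank <= n-1

    def test_rejects_bad_cutoff(self):
        hrr, genes = self._hrr()
        with pytest.raises(ValueError):
            build_network(hrr, genes, cutoff=0)


class TestNetworkStats:
    def test_complete_graph(self):
        s = network_stats(nx.complete_graph(4))
        assert s.clustering_coefficient == 1.0
        assert s.density == pytest.approx(1.0)
        assert s.diameter == 1 and s.radius == 1
        assert s.centralization == pytest.approx(0.0)

    def test_path_graph_hand_enumeration(self):
        s = network_stats(nx.path_graph(4))
        assert s.diameter == 3
        # unordered distances: 1,1,1,2,2,3 -> mean 10/6
        assert s.characteristic_path_length == pytest.approx(10 / 6)
        assert s.clustering_coefficient == 0.0
        assert s.shortest_paths == 12
        assert s.shortest_paths_percent == pytest.approx(100.0)

    def test_density_identities(self):
        g = nx.gnp_random_graph(25, 0.2, seed=4)
        s = network_stats(g)
        assert s.density == pytest.approx(
            2 * g.number_of_edges() / (25 * 24), abs=1e-12
        )
        assert s.density == pytest.approx(s.avg_neighbors / 24, abs=1e-12)

    def test_density_from_printed_node_count_and_mean_degree(self):
        # 1296 nodes with 22.752 mean neighbors -> 0.018 at 3 decimals
        assert round(density_from_mean_degree(1296, 22.752), 3) == 0.018

    def test_isolated_nodes_and_components(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("c", "d")])
        g.add_node("e")
        s = network_stats(g)
        assert s.isolated_nodes == 1
        assert s.connected_components == 3
        assert s.self_loops == 0 and s.multi_edge_pairs == 0

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            network_stats(nx.Graph())


def test_planted_module_has_lower_hrr_than_background(three_module_sim):
    from coexpipe import quantify

    _, counts, truth = three_module_sim
    rpkm = quantify.compute_rpkm(counts).rpkm
    genes = counts.gene_ids[:120] + counts.gene_ids[150:200]
    idx = [counts.gene_ids.index(g) for g in genes]
    corr, _ = pearson_matrix(np.log2(rpkm[idx, :] + 1), genes)
    hrr = hrr_matrix(corr)
    m0 = [i for i, g in enumerate(genes) if truth.module_membership.get(g) == 0]
    bg = [i for i, g in enumerate(genes) if g not in truth.module_membership]
    within = [hrr[i, j] for i, j in itertools.combinations(m0, 2)]
    between = [hrr[i, j] for i in m0 for j in bg]
    assert np.median(within) < np.median(between)


def test_sif_and_edge_list_roundtrip(tmp_path):
    corr, _ = pearson_matrix(np.random.default_rng(2).normal(size=(6, 5)))
    g = build_network(hrr_matrix(corr), [f"g{i}" for i in range(6)], 3, corr)
    coexnet.write_edge_list(g, tmp_path / "edges.tsv")
    back = coexnet.read_edge_list(tmp_path / "edges.tsv")
    assert {frozenset(e) for e in back.edges()} == {
        frozenset(e) for e in g.edges()
    }
    coexnet.write_sif(g, tmp_path / "net.sif")
    lines = (tmp_path / "net.sif").read_text().splitlines()
    assert len([l for l in lines if "\t" in l]) == g.number_of_edges()
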