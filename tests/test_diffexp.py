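"""Exact-test differential expression: oracles, filters and Venn logic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import nbinom

from coexpipe import diffexp, quantify
from coexpipe.diffexp import (
    ThresholdSet,
    ac_pvalue,
    bh_fdr,
    call_degs,
    triple_intersection_count,
    venn_partition,
    venn_percentages,
)


def brute_force_ac(x, y, N1, N2):
    """Independent oracle: direct summation of the conditional series."""
    q = N2 / (N1 + N2)

    def pmf(yy):
        return math.exp(
            math.lgamma(x + yy + 1)
            - math.lgamma(yy + 1)
            - math.lgamma(x + 1)
            + yy * math.log(q)
            + (x + 1) * math.log1p(-q)
        )

    lower = sum(pmf(v) for v in range(y + 1))
    upper, v = 0.0, y
    while True:
        term = pmf(v)
        upper += term
        if term < 1e-16 * max(upper, 1e-300) and v > y + 10:
            break
        v += 1
    return min(1.0, 2 * min(lower, upper))


class TestAcPvalue:
    def test_equal_counts_equal_libraries_capped_at_one(self):
        assert ac_pvalue(7, 7, 5000, 5000) == 1.0

    def test_geometric_series_closed_form(self):
        # x=0, equal libraries: upper tail sum_{y'>=5} (1/2)^(y'+1) = 2^-5
        assert ac_pvalue(0, 5, 1000, 1000) == pytest.approx(0.0625, rel=1e-12)

    @pytest.mark.parametrize(
        "x,y,N1,N2",
        [
            (3, 12, 1_000_000, 2_000_000),
            (0, 0, 10, 10),
            (25, 5, 500_000, 400_000),
            (100, 180, 1_000_000, 1_500_000),
            (1, 40, 100_000, 100_000),
        ],
    )
    def test_matches_brute_force_summation(self, x, y, N1, N2):
        assert ac_pvalue(x, y, N1, N2) == pytest.approx(
            brute_force_ac(x, y, N1, N2), rel=1e-10
        )

    @pytest.mark.parametrize(
        "x,y,N1,N2",
        [(3, 12, 1_000_000, 2_000_000), (50, 20, 3_000_000, 1_000_000), (0, 9, 7, 13)],
    )
    def test_matches_negative_binomial_tail_closed_form(self, x, y, N1, N2):
        # dual route: y | x is NB with x+1 successes, success prob N1/(N1+N2)
        pr = N1 / (N1 + N2)
        upper = nbinom.sf(y - 1, x + 1, pr) if y > 0 else 1.0
        lower = nbinom.cdf(y, x + 1, pr)
        expected = min(1.0, 2 * min(upper, lower))
        assert ac_pvalue(x, y, N1, N2) == pytest.approx(expected, rel=1e-10)

    @settings(max_examples=60, deadline=None)
    @given(
        x=st.integers(0, 300),
        y=st.integers(0, 300),
        N1=st.integers(1000, 10_000_000),
        N2=st.integers(1000, 10_000_000),
    )
    def test_symmetric_under_sample_swap_up_to_point_mass(self, x, y, N1, N2):
        # with the observed point included in both tails the swap changes
        # each tail by at most one point-mass term, so the two-sided
        # values agree to within twice the larger point mass (and the
        # half-open tail min(P(Y<=y), P(Y>y)) is exactly swap-invariant)
        p1 = ac_pvalue(x, y, N1, N2)
        p2 = ac_pvalue(y, x, N2, N1)
        m = nbinom.pmf(y, x + 1, N1 / (N1 + N2))
        bound = 2 * max(m, m * N2 / N1)
        assert abs(p1 - p2) <= bound + 1e-12

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            ac_pvalue(-1, 3, 100, 100)


class TestBhFdr:
    def test_single_pvalue_unchanged(self):
        assert bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_hand_worked_step_up(self):
        # sorted p_i * n / i = (.04, .04, .04, .04) after the step-up min
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_order_preserving_and_monotone(self):
        p = np.array([0.5, 0.001, 0.04, 0.2, 0.001])
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        assert (q >= p).all()

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [1.2], [-0.1]])
    def test_rejects_out_of_range(self, bad):
        with pytest.raises(ValueError):
            bh_fdr(bad)


class TestCallDegs:
    def test_all_filters_and_direction(self, three_module_sim):
        _, counts, truth = three_module_sim
        expr = quantify.compute_rpkm(counts)
        table = call_degs(expr, counts, ThresholdSet(2, 0.05, 2))
        passing = table[table["passes"]]
        assert len(passing) > 0
        assert (passing["q"] <= 0.05).all()
        assert (passing["log2_ratio"].abs() >= 2).all()
        assert set(passing["direction"]) <= {"up", "down"}
        assert (passing["direction"] == np.where(
            passing["log2_ratio"] > 0, "up", "down")).all()
        # q is a BH adjustment, so never below p
        assert (table["q"] >= table["p"] - 1e-12).all()
        # the planted DE gene is recovered in its comparison
        de_gene = next(iter(truth.de_calls))[0]
        row = table[(table["gene_id"] == de_gene) & (table["comparison"] == "0h_vs_2h")]
        assert bool(row["passes"].iloc[0])
        assert row["direction"].iloc[0] == "up"

    def test_inclusive_abundance_boundary(self):
        # max RPKM over the pair exactly equals min_rpkm -> still eligible
        counts = quantify.CountMatrix(
            gene_ids=["g1", "g2"],
            lengths=[1000, 1000],
            counts=np.array([[0, 2000], [1000, 1000]]),
            sample_labels=["0h", "2h"],
            library_sizes=[1_000_000_000, 1_000_000_000],
        )
        expr = quantify.compute_rpkm(counts)
        assert expr.rpkm[0, 1] == pytest.approx(2.0)
        table = call_degs(
            expr, counts, ThresholdSet(2.0, 0.05, 1.5), comparisons=[("0h", "2h")]
        )
        assert bool(table.loc[0, "passes"])

    def test_empty_matrix_rejected(self):
        empty = quantify.CountMatrix(
            gene_ids=[], lengths=[], counts=np.zeros((0, 2), dtype=int),
            sample_labels=["a", "b"], library_sizes=[1, 1],
        )
        expr = quantify.compute_rpkm(empty)
        with pytest.raises(ValueError, match="empty"):
            call_degs(expr, empty, ThresholdSet())


class TestVenn:
    NAMES = ("2h_vs_0h", "4h_vs_0h", "4h_vs_2h")

    def test_reported_region_percentages(self):
        # region counts / union -> printed one-decimal percentages
        counts = [414, 586, 174, 714, 213, 44, 3]
        assert venn_percentages(counts, 2148) == [
            19.3, 27.3, 8.1, 33.2, 9.9, 2.0, 0.1,
        ]

    def test_triple_intersection_recovered_from_totals(self):
        assert triple_intersection_count([414, 586, 174, 714, 213, 44], 2148) == 3

    def test_disjoint_sets_have_empty_overlaps(self):
        v = venn_partition({"A": {"1"}, "B": {"2"}, "C": {"3"}})
        assert v.union_size == 3
        for key, count in v.region_counts.items():
            assert count == (1 if key.endswith("_only") else 0)

    @settings(max_examples=50, deadline=None)
    @given(st.data())
    def test_matches_exhaustive_enumeration(self, data):
        universe = [f"g{i}" for i in range(20)]
        sets = {
            n: set(data.draw(st.lists(st.sampled_from(universe), max_size=20)))
            for n in ("A", "B", "C")
        }
        v = venn_partition(sets)
        A, B, C = sets["A"], sets["B"], sets["C"]
        # brute-force membership enumeration over the union
        expected = dict.fromkeys(v.region_counts, 0)
        for g in A | B | C:
            key = tuple(g in s for s in (A, B, C))
            name = {
                (True, False, False): "A_only",
                (False, True, False): "B_only",
                (False, False, True): "C_only",
                (True, True, False): "A_and_B",
                (True, False, True): "A_and_C",
                (False, True, True): "B_and_C",
                (True, True, True): "A_and_B_and_C",
            }[key]
            expected[name] += 1
        assert v.region_counts == expected
        assert sum(v.region_counts.values()) == v.union_size
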