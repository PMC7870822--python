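import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from reticulotype import (
    grubbs_outlier,
    overlap_coefficient,
    pairwise_overlap,
    summarize,
    unique_edges,
    unique_feature_edges,
)

from conftest import make_net

gene_sets = st.sets(st.sampled_from("abcdefgh"), min_size=1, max_size=8)


class TestSummarize:
    def test_path_graph(self):
        s = summarize(make_net("p", [("A", "B"), ("B", "C")]))
        assert (s.n_nodes, s.n_edges) == (3, 2)
        assert s.density == pytest.approx(2 / 3)
        assert s.diameter == 2
        assert s.characteristic_path_length == pytest.approx(4 / 3)
        # degrees (1, 2, 1): population variance 2/9, mean 4/3
        assert s.heterogeneity == pytest.approx(math.sqrt(2 / 9) / (4 / 3))

    def test_triangle(self):
        s = summarize(make_net("p", [("A", "B"), ("B", "C"), ("A", "C")]))
        assert s.density == 1.0
        assert s.diameter == 1
        assert s.characteristic_path_length == 1.0
        assert s.heterogeneity == 0.0

    def test_empty_network_flagged(self):
        s = summarize(make_net("p", []))
        assert s.undefined and math.isnan(s.density)

    def test_disconnected_metrics_cover_connected_pairs(self):
        s = summarize(make_net("p", [("A", "B"), ("C", "D")]))
        assert s.n_components == 2
        assert s.characteristic_path_length == 1.0  # unreachable pairs ignored
        assert s.diameter == 1


class TestOverlapCoefficient:
    def test_known_value(self):
        assert overlap_coefficient({"a", "b", "c"}, {"b", "c", "d"}) == pytest.approx(2 / 3)

    def test_identity_and_disjoint(self):
        assert overlap_coefficient({"a", "b"}, {"a", "b"}) == 1.0
        assert overlap_coefficient({"a"}, {"b"}) == 0.0

    def test_empty_error(self):
        with pytest.raises(ValueError):
            overlap_coefficient(set(), {"a"})

    @given(gene_sets, gene_sets)
    def test_dominates_jaccard(self, A, B):
        jaccard = len(A & B) / len(A | B)
        overlap = overlap_coefficient(A, B)
        assert overlap >= jaccard - 1e-12
        # equality exactly when the sets are identical (min = union) or
        # disjoint (both coefficients vanish); strict containment gives
        # overlap 1 but Jaccard |A|/|B| < 1
        equal = abs(overlap - jaccard) < 1e-12
        assert equal == (A == B or not (A & B))


class TestPairwiseOverlap:
    def test_identical_cohort_all_ones(self):
        nets = [make_net(f"p{i}", [("A", "B")]) for i in range(3)]
        for mode in ("node", "edge"):
            ov = pairwise_overlap(nets, mode)
            assert np.allclose(ov.values.to_numpy(), 1.0)

    def test_disjoint_networks(self):
        nets = [make_net("p1", [("A", "B")]), make_net("p2", [("C", "D")])]
        assert pairwise_overlap(nets, "node").values.iloc[0, 1] == 0.0
        assert pairwise_overlap(nets, "edge").values.iloc[0, 1] == 0.0

    def test_partial_overlap_hand_computed(self):
        nets = [
            make_net("p1", [("A", "B"), ("B", "C")]),
            make_net("p2", [("B", "C"), ("C", "D")]),
        ]
        assert pairwise_overlap(nets, "edge").values.iloc[0, 1] == pytest.approx(1 / 2)
        assert pairwise_overlap(nets, "node").values.iloc[0, 1] == pytest.approx(2 / 3)

    def test_rectangular_two_cohorts(self):
        a = [make_net("a1", [("A", "B")]), make_net("a2", [("B", "C")])]
        b = [make_net("b1", [("A", "B")])]
        ov = pairwise_overlap(a, "edge", other=b)
        assert ov.values.shape == (2, 1)
        assert ov.values.loc["a1", "b1"] == 1.0

    def test_empty_network_flagged_nan(self):
        nets = [make_net("p1", [("A", "B")]), make_net("p2", [])]
        ov = pairwise_overlap(nets, "edge")
        assert math.isnan(ov.values.loc["p2", "p1"])

    def test_order_invariance(self):
        nets = [
            make_net("p1", [("A", "B")]),
            make_net("p2", [("B", "C")]),
            make_net("p3", [("A", "B"), ("B", "C")]),
        ]
        ov = pairwise_overlap(nets, "edge").values
        rev = pairwise_overlap(nets[::-1], "edge").values
        assert np.allclose(
            ov.to_numpy(), rev.loc[ov.index, ov.columns].to_numpy()
        )


class TestUniqueEdges:
    def test_basic(self):
        nets = [
            make_net("p1", [("A", "B"), ("B", "C")]),
            make_net("p2", [("B", "C")]),
        ]
        uniq = unique_edges(nets)
        assert uniq["p1"] == {("A", "B")} and uniq["p2"] == set()

    def test_identical_networks_have_none(self):
        nets = [make_net(f"p{i}", [("A", "B")]) for i in range(3)]
        assert all(not v for v in unique_edges(nets).values())

    def test_disjoint_keep_everything(self):
        nets = [
            make_net("p1", [("A", "B")]),
            make_net("p2", [("C", "D")]),
            make_net("p3", [("E", "F")]),
        ]
        uniq = unique_edges(nets)
        assert all(uniq[n.patient_id] == n.edges for n in nets)

    def test_sum_bounded_by_union(self):
        nets = [
            make_net("p1", [("A", "B"), ("B", "C")]),
            make_net("p2", [("B", "C"), ("C", "D")]),
            make_net("p3", [("A", "B")]),
        ]
        uniq = unique_edges(nets)
        union = set().union(*(n.edges for n in nets))
        assert sum(len(v) for v in uniq.values()) <= len(union)


class TestUniqueFeatureEdges:
    def test_feature_touch_counting(self):
        nets = [
            make_net("p1", [("A", "B"), ("C", "D")]),
            make_net("p2", [("E", "F")]),
        ]
        reports = {r.patient_id: r for r in unique_feature_edges(nets, {"A"}, "fibrosis")}
        assert reports["p1"].n_unique_feature_edges == 1
        assert reports["p1"].n_unique_edges == 2
        assert reports["p2"].n_unique_feature_edges == 0

    def test_full_cover_attains_bound(self):
        nets = [
            make_net("p1", [("A", "B"), ("C", "D")]),
            make_net("p2", [("E", "F")]),
        ]
        reports = unique_feature_edges(nets, set("ABCDEF"))
        for r in reports:
            assert r.n_unique_feature_edges == r.n_unique_edges

    def test_empty_feature_set_error(self):
        nets = [make_net("p1", [("A", "B")]), make_net("p2", [("C", "D")])]
        with pytest.raises(ValueError):
            unique_feature_edges(nets, set())


class TestGrubbs:
    def test_flags_single_outlier(self):
        res = grubbs_outlier([1, 1, 1, 10], alpha=0.05)
        assert res.g == pytest.approx(1.5)
        # closed-form critical value: ((n-1)/sqrt(n)) sqrt(t^2/(n-2+t^2))
        n = 4
        t = stats.t.ppf(1 - 0.05 / (2 * n), n - 2)
        crit = (n - 1) / math.sqrt(n) * math.sqrt(t**2 / (n - 2 + t**2))
        assert res.critical == pytest.approx(crit)
        assert crit == pytest.approx(1.481, abs=5e-3)
        assert res.index == 3

    def test_symmetric_no_outlier(self):
        res = grubbs_outlier([1, 2, 3], alpha=0.05)
        assert res.g == pytest.approx(1.0)
        assert res.index is None

    def test_constant_values(self):
        res = grubbs_outlier([5, 5, 5, 5])
        assert res.index is None and res.p == 1.0

    def test_needs_three(self):
        with pytest.raises(ValueError):
            grubbs_outlier([1, 2])
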