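import numpy as np
import pytest

from oracles import naive_graph_features, random_digraph, set_cosine
from pathclass.datamodel import AnnotationUniverse, Pathway, ProteinRecord
from pathclass.graph_features import (
    LOCAL_DENSITY_CUTOFFS,
    TOPOLOGY_CUTOFFS,
    degree_statistics,
    edge_weight_statistics,
    graph_feature_block,
    local_density_change,
    singular_values,
    size_density,
    topology_change,
)
from pathclass.ontology import WeightedPathwayGraph, weight_graph


def _wrap(vertices, arcs, weights=None):
    pw = Pathway("g", list(vertices), set(arcs))
    if weights is None:
        weights = {a: 1.0 for a in pw.arcs}
    return WeightedPathwayGraph(pw, weights)


def _materialize(vertices, arcs, go_sets, universe):
    proteins = {v: ProteinRecord(v, "ACDEF", go_sets[v]) for v in vertices}
    pw = Pathway("g", list(vertices), set(arcs))
    annotations = {v: go_sets[v] for v in vertices}
    uni = AnnotationUniverse.from_annotations(annotations, terms=universe)
    wg = weight_graph(pw, proteins, uni)
    return wg, proteins, uni


class TestSizeDensity:
    def test_self_loop_counts_in_density(self):
        g = _wrap("abc", [("a", "b"), ("b", "c"), ("c", "a"), ("a", "a")])
        f = size_density(g)
        assert f["size.n_vertices"] == 3
        assert f["size.density"] == pytest.approx(4 / 9)

    def test_single_vertex_no_arcs(self):
        f = size_density(_wrap("a", []))
        assert (f["size.n_vertices"], f["size.density"]) == (1, 0.0)

    def test_complete_digraph_with_loops_has_density_one(self):
        arcs = [(a, b) for a in "ab" for b in "ab"]
        assert size_density(_wrap("ab", arcs))["size.density"] == pytest.approx(1.0)


class TestDegreeStatistics:
    def test_path_graph_population_variance(self):
        f = degree_statistics(_wrap("abc", [("a", "b"), ("b", "c")]))
        assert f["degree.in_mean"] == pytest.approx(2 / 3)
        assert f["degree.in_median"] == 1.0
        assert f["degree.in_max"] == 1.0
        assert f["degree.in_variance"] == pytest.approx(2 / 9)

    def test_edgeless_graph_all_zero(self):
        f = degree_statistics(_wrap("abc", []))
        assert all(v == 0.0 for v in f.values())

    def test_star_out_degree(self):
        f = degree_statistics(_wrap("uvwx", [("u", "v"), ("u", "w"), ("u", "x")]))
        assert f["degree.out_max"] == 3.0
        assert f["degree.in_max"] == 1.0


class TestEdgeWeightStatistics:
    def test_with_and_without_missing(self):
        g = _wrap("ab", [("a", "b")], {("a", "b"): 0.5})
        f = edge_weight_statistics(g)
        assert f["weight.mean_with_missing"] == pytest.approx(0.125)
        assert f["weight.mean_without_missing"] == pytest.approx(0.5)

    def test_equal_weights_zero_variance(self):
        g = _wrap("abc", [("a", "b"), ("b", "c")], {("a", "b"): 0.3, ("b", "c"): 0.3})
        f = edge_weight_statistics(g)
        assert f["weight.variance_without_missing"] == pytest.approx(0.0)

    def test_no_positive_arcs_degenerate(self):
        g = _wrap("ab", [("a", "b")], {("a", "b"): 0.0})
        f = edge_weight_statistics(g)
        assert f["weight.mean_without_missing"] == 0.0
        assert f["weight.variance_without_missing"] == 0.0


class TestTopologyChange:
    def test_hand_counted_change_rate(self):
        g = _wrap(
            "abcd",
            [("a", "b"), ("b", "c"), ("c", "d")],
            {("a", "b"): 0.15, ("b", "c"): 0.25, ("c", "d"): 0.25},
        )
        f = topology_change(g)
        assert f["topology_change.c0.1_0.2"] == pytest.approx(1 / 3)

    def test_all_heavy_arcs_give_zero_change(self):
        g = _wrap("ab", [("a", "b")], {("a", "b"): 0.9})
        assert all(v == 0.0 for v in topology_change(g).values())

    def test_empty_cutoff_level_guarded(self):
        f = topology_change(_wrap("ab", []))
        assert all(v == 0.0 for v in f.values())

    def test_arc_counts_nonincreasing_in_cutoff(self, rng):
        ws = rng.random(10)
        arcs = [(f"v{i}", f"v{(i + 1) % 10}") for i in range(10)]
        g = _wrap([f"v{i}" for i in range(10)], arcs, dict(zip(arcs, ws)))
        counts = [sum(1 for w in ws if w > c) for c in TOPOLOGY_CUTOFFS]
        assert counts == sorted(counts, reverse=True)


class TestSingularValues:
    def test_single_arc_rank_one(self):
        f = singular_values(_wrap("ab", [("a", "b")]))
        assert [f["singular.s1"], f["singular.s2"], f["singular.s3"]] == pytest.approx(
            [1.0, 0.0, 0.0]
        )

    def test_empty_graph(self):
        f = singular_values(_wrap("abc", []))
        assert all(v == 0.0 for v in f.values())

    def test_cycle_is_orthogonal_matrix(self):
        f = singular_values(_wrap("abc", [("a", "b"), ("b", "c"), ("c", "a")]))
        assert list(f.values()) == pytest.approx([1.0, 1.0, 1.0])


class TestLocalDensityChange:
    def test_single_neighbor_is_zero_everywhere(self):
        uni = [f"GO:{i:07d}" for i in range(1, 5)]
        wg, proteins, u = _materialize(
            "ab", [("a", "b")], {"a": {uni[0]}, "b": {uni[1]}}, uni
        )
        f = local_density_change(wg, proteins, u)
        assert all(v == 0.0 for v in f.values())

    def test_strict_cutoff_on_pairwise_cosine(self):
        # two out-neighbors sharing one of two terms each: cosine 0.5
        uni = [f"GO:{i:07d}" for i in range(1, 5)]
        go = {"h": {uni[3]}, "x": {uni[0], uni[1]}, "y": {uni[1], uni[2]}}
        wg, proteins, u = _materialize("hxy", [("h", "x"), ("h", "y")], go, uni)
        f = local_density_change(wg, proteins, u)
        assert f["local_density.out.c0.4_mean"] == pytest.approx(1 / 3)
        assert f["local_density.out.c0.4_max"] == pytest.approx(1.0)
        assert f["local_density.out.c0.5_max"] == 0.0

    def test_emits_40_values(self):
        uni = [f"GO:{i:07d}" for i in range(1, 4)]
        wg, proteins, u = _materialize("ab", [("a", "b")], {"a": {uni[0]}, "b": {uni[1]}}, uni)
        assert len(local_density_change(wg, proteins, u)) == 40
        assert len(LOCAL_DENSITY_CUTOFFS) == 10


class TestBlockInvariants:
    def test_group_sizes_match_breakdown(self):
        uni = [f"GO:{i:07d}" for i in range(1, 4)]
        wg, proteins, u = _materialize(
            "abc", [("a", "b")], {v: {uni[0]} for v in "abc"}, uni
        )
        block = graph_feature_block(wg, proteins, u)
        assert len(block) == 88
        groups = {}
        for name in block:
            groups[name.split(".")[0]] = groups.get(name.split(".")[0], 0) + 1
        assert groups == {
            "size": 2, "degree": 8, "weight": 4, "topology_change": 7,
            "degree_correlation": 6, "clustering": 6, "topological": 12,
            "singular": 3, "local_density": 40,
        }

    def test_all_finite_on_random_graphs(self, rng):
        for _ in range(20):
            vertices, arcs, go_sets, uni = random_digraph(rng)
            wg, proteins, u = _materialize(vertices, arcs, go_sets, uni)
            vals = np.array(list(graph_feature_block(wg, proteins, u).values()))
            assert np.isfinite(vals).all()


class TestOracleEquivalence:
    """All 88 features against the independent naive enumeration."""

    @pytest.mark.parametrize("seed", range(8))
    def test_random_digraphs_match_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(25):
            vertices, arcs, go_sets, uni = random_digraph(rng)
            wg, proteins, u = _materialize(vertices, arcs, go_sets, uni)
            block = graph_feature_block(wg, proteins, u)
            weights = {
                (a, b): set_cosine(go_sets[a], go_sets[b]) for a, b in arcs
            }
            expected = naive_graph_features(vertices, arcs, weights, go_sets)
            assert set(block) == set(expected)
            for name in expected:
                assert block[name] == pytest.approx(expected[name], abs=1e-9), name
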