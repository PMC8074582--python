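import itertools

import networkx as nx
import numpy as np
import pytest

from netblocks.errors import GraphDomainError
from netblocks.motifs import (
    FrequencyVariant,
    OverlapPolicy,
    build_census,
    canonical_class,
    enumerate_connected_subgraphs,
    greedy_disjoint_set,
    motif_frequencies,
    n_connected_classes,
)

from conftest import er_graph


def brute_force_occurrences(g: nx.Graph, k: int) -> set[frozenset]:
    """Oracle: test every k-subset for connectivity of its induced subgraph."""
    out = set()
    for subset in itertools.combinations(g.nodes, k):
        if nx.is_connected(g.subgraph(subset)):
            out.add(frozenset(subset))
    return out


class TestCanonicalClass:
    def test_relabelled_paths_share_class(self):
        p1 = nx.Graph([("a", "b"), ("b", "c")])
        p2 = nx.Graph([("x", "q"), ("q", "m")])
        assert canonical_class(p1) == canonical_class(p2)

    def test_path_and_triangle_differ(self, triangle):
        p = nx.Graph([("a", "b"), ("b", "c")])
        assert canonical_class(p) != canonical_class(triangle)

    @pytest.mark.parametrize("k,expected", [(3, 2), (4, 6), (5, 21)])
    def test_connected_class_counts(self, k, expected):
        assert n_connected_classes(k) == expected

    def test_disconnected_input_rejected(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_node("c")
        with pytest.raises(GraphDomainError):
            canonical_class(g)

    def test_random_relabelling_is_invariant(self):
        rng = np.random.default_rng(0)
        for seed in range(10):
            g = er_graph(5, 0.6, seed=100 + seed)
            if not nx.is_connected(g):
                continue
            perm = dict(zip(g.nodes, rng.permutation(list(g.nodes))))
            assert canonical_class(g) == canonical_class(nx.relabel_nodes(g, perm))


class TestEnumeration:
    def test_triangle(self, triangle):
        occs = enumerate_connected_subgraphs(triangle, 3)
        assert len(occs) == 1

    def test_k4_triangles(self, k4):
        occs = enumerate_connected_subgraphs(k4, 3)
        assert len(occs) == 4
        assert len({o.class_id for o in occs}) == 1

    def test_star_paths(self):
        g = nx.relabel_nodes(nx.star_graph(3), str)  # hub + 3 leaves
        occs = enumerate_connected_subgraphs(g, 3)
        assert len(occs) == 3  # the all-leaves triple is disconnected

    @pytest.mark.parametrize("k", [3, 4])
    def test_matches_brute_force_on_random_graphs(self, k):
        for seed in range(8):
            g = er_graph(10, 0.35, seed=seed)
            occs = enumerate_connected_subgraphs(g, k)
            node_sets = {o.node_set for o in occs}
            assert len(node_sets) == len(occs), "duplicate occurrences"
            assert node_sets == brute_force_occurrences(g, k)

    def test_k_out_of_range(self, k4):
        with pytest.raises(GraphDomainError):
            enumerate_connected_subgraphs(k4, 2)

    def test_relabelling_preserves_class_tallies(self):
        g = er_graph(12, 0.3, seed=5)
        perm = dict(zip(g.nodes, np.random.default_rng(1).permutation(list(g.nodes))))
        h = nx.relabel_nodes(g, perm)

        def tally(graph):
            c = build_census(graph, 4)
            return {cl.canon: n for cl, n in c.joint_counts.items()}

        assert tally(g) == tally(h)


class TestDisjointSelection:
    def test_shared_node_policies(self, fixtures):
        g = fixtures["two-triangles-shared-node"]
        occs = enumerate_connected_subgraphs(g, 3)
        triangles = [o for o in occs
                     if g.subgraph(o.node_set).number_of_edges() == 3]
        assert len(triangles) == 2
        assert len(greedy_disjoint_set(triangles, g, OverlapPolicy.NODE_DISJOINT)) == 1
        assert len(greedy_disjoint_set(triangles, g, OverlapPolicy.EDGE_DISJOINT)) == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_k4_edge_disjoint_always_one(self, k4, seed):
        # every pair of K4's four triangles shares an edge
        census = build_census(k4, 3, OverlapPolicy.EDGE_DISJOINT, seed=seed)
        assert census.total_joint == 4
        assert census.total_disjoint == 1

    def test_mis_validity_and_maximality(self):
        g = er_graph(15, 0.3, seed=9)
        occs = enumerate_connected_subgraphs(g, 3)
        kept = greedy_disjoint_set(occs, g, OverlapPolicy.NODE_DISJOINT, seed=2)
        kept_sets = [o.node_set for o in kept]
        for a, b in itertools.combinations(kept_sets, 2):
            assert not (a & b)
        for o in occs:
            if o.node_set not in kept_sets:
                assert any(o.node_set & s for s in kept_sets), "not maximal"

    def test_f_measure_ordering(self):
        for seed in range(10):
            g = er_graph(20, 0.25, seed=seed)
            joint = build_census(g, 3, OverlapPolicy.EDGE_DISJOINT, seed=0)
            node_dj = build_census(g, 3, OverlapPolicy.NODE_DISJOINT, seed=0)
            for c in joint.class_order:
                assert joint.joint_counts[c] >= joint.disjoint_counts[c]
                assert joint.disjoint_counts[c] >= 0
            assert joint.total_joint >= joint.total_disjoint >= node_dj.total_disjoint

    def test_seed_sensitivity_is_bounded(self):
        # greedy MIS size varies by <= 20% relative range across seeds
        for g_seed in range(8):
            g = er_graph(25, 0.2, seed=50 + g_seed)
            totals = [
                build_census(g, 3, OverlapPolicy.EDGE_DISJOINT, seed=s).total_disjoint
                for s in range(10)
            ]
            if max(totals) == 0:
                continue
            assert (max(totals) - min(totals)) / max(totals) <= 0.20


class TestCensusAndFrequencies:
    def test_single_triangle(self, triangle):
        c = build_census(triangle, 3)
        freqs = motif_frequencies(c, FrequencyVariant.JOINT_RATIO)
        assert freqs.tolist() == [0.0, 1.0]  # path class first, triangle second
        assert motif_frequencies(c, FrequencyVariant.DISJOINT_TOTAL_RATIO) == 1.0

    def test_k4_disjoint_ratios(self, k4):
        c = build_census(k4, 3, OverlapPolicy.EDGE_DISJOINT, seed=0)
        dis = motif_frequencies(c, FrequencyVariant.DISJOINT_RATIO)
        assert dis.sum() == pytest.approx(0.25)
        assert motif_frequencies(c, FrequencyVariant.DISJOINT_TOTAL_RATIO) == 0.25

    def test_joint_ratios_normalised(self):
        g = er_graph(15, 0.3, seed=4)
        c = build_census(g, 4)
        assert motif_frequencies(c, FrequencyVariant.JOINT_RATIO).sum() == pytest.approx(1.0)

    def test_empty_graph_census(self):
        g = nx.Graph()
        g.add_nodes_from("abcde")
        c = build_census(g, 3)
        assert c.total_joint == 0
        assert motif_frequencies(c, FrequencyVariant.JOINT_RATIO).tolist() == [0.0, 0.0]
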