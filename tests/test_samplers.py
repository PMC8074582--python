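import itertools

import networkx as nx
import numpy as np
import pytest

from netblocks.errors import ConfigError, GraphDomainError
from netblocks.graphcore import largest_component
from netblocks.samplers import (
    SamplerMethod,
    SamplerSpec,
    WALKS,
    _weighted_subset,
    draw_sample,
    walk_positions,
)

from conftest import connected_er_graph

ALL_METHODS = list(SamplerMethod)
INDUCED_METHODS = [m for m in ALL_METHODS if m is not SamplerMethod.RE]


@pytest.fixture(scope="module")
def host():
    return connected_er_graph(60, 0.1, seed=3)


@pytest.mark.parametrize("method", ALL_METHODS)
def test_determinism(host, method):
    spec = SamplerSpec(method=method, target_size=12, rng_seed=99)
    a = draw_sample(host, spec)
    b = draw_sample(host, spec)
    assert set(a.subgraph.nodes) == set(b.subgraph.nodes)
    assert set(map(frozenset, a.subgraph.edges)) == set(map(frozenset, b.subgraph.edges))


@pytest.mark.parametrize("method", ALL_METHODS)
@pytest.mark.parametrize("seed", [0, 7, 123])
def test_containment_and_size(host, method, seed):
    spec = SamplerSpec(method=method, target_size=15, rng_seed=seed)
    result = draw_sample(host, spec)
    assert set(result.subgraph.nodes) <= set(host.nodes)
    assert all(host.has_edge(*e) for e in result.subgraph.edges)
    if method is SamplerMethod.RE:
        assert result.actual_size in (15, 16)
    else:
        assert result.actual_size == 15


@pytest.mark.parametrize("method", INDUCED_METHODS)
def test_full_size_sample_is_host(method, fixtures):
    k10 = fixtures["K10"]
    result = draw_sample(k10, SamplerSpec(method=method, target_size=10, rng_seed=1))
    assert nx.utils.graphs_equal(result.subgraph, k10)


def test_oversized_request_rejected(triangle):
    with pytest.raises(GraphDomainError):
        draw_sample(triangle, SamplerSpec(method="RN", target_size=4))


def test_unknown_method_rejected():
    with pytest.raises(ValueError):
        SamplerSpec(method="FOREST_FIRE", target_size=5)


def test_invalid_params_rejected():
    with pytest.raises(ConfigError):
        SamplerSpec(method="RWJ", target_size=5, params={"jump_p": 1.5})
    with pytest.raises(ConfigError):
        SamplerSpec(method="RN", target_size=1)


def test_degree_sampling_first_draw_proportional_to_degree():
    # star with 9 leaves: hub holds half the total degree
    degrees = np.array([9.0] + [1.0] * 9)
    rng = np.random.default_rng(42)
    hub_picks = sum(_weighted_subset(rng, degrees, 1)[0] == 0 for _ in range(2000))
    assert hub_picks / 2000 == pytest.approx(0.5, abs=0.03)


def test_random_edge_on_triangle(triangle):
    # two distinct edges of a triangle always cover all three nodes
    result = draw_sample(triangle, SamplerSpec(method="RE", target_size=3, rng_seed=0))
    assert result.subgraph.number_of_nodes() == 3
    assert result.subgraph.number_of_edges() == 2


def test_random_edge_nodes_touch_edges(host):
    result = draw_sample(host, SamplerSpec(method="RE", target_size=20, rng_seed=5))
    assert all(d > 0 for _, d in result.subgraph.degree)


def test_snowball_on_path_is_contiguous(path10):
    result = draw_sample(path10, SamplerSpec(method="SB", target_size=4, rng_seed=2))
    # capped BFS on a path collects a contiguous segment
    assert nx.is_connected(result.subgraph)
    positions = sorted(int(n) for n in result.subgraph.nodes)
    assert positions == list(range(positions[0], positions[0] + 4))


def test_cse_on_star_contains_hub(star10):
    # the hub is the only node with unknown neighbours from any leaf
    result = draw_sample(star10, SamplerSpec(method="CSE", target_size=3, rng_seed=0))
    assert "0" in result.subgraph.nodes


@pytest.mark.parametrize("method", ["SB", "CSE", "SP"])
def test_exploration_outputs_connected(host, method):
    for seed in range(5):
        result = draw_sample(host, SamplerSpec(method=method, target_size=20,
                                               rng_seed=seed))
        assert nx.is_connected(result.subgraph)


class TestWalks:
    def test_nbrw_covers_cycle_without_reversing(self, fixtures):
        cycle6 = fixtures["cycle6"]
        walk = walk_positions(cycle6, SamplerMethod.NBRW, seed=0)
        first_six = list(itertools.islice(walk, 6))
        assert len(set(first_six)) == 6  # never reverses on a cycle

    def test_nbrw_trace_property(self, host):
        result = draw_sample(host, SamplerSpec(method="NBRW", target_size=25,
                                               rng_seed=8))
        trace = result.trace
        for i in range(2, len(trace)):
            if trace[i] == trace[i - 2] and trace[i - 1] != trace[i]:
                assert host.degree(trace[i - 1]) == 1

    def test_nbrw_backtracks_only_at_degree_one(self):
        path3 = nx.Graph([("a", "b"), ("b", "c")])
        result = draw_sample(path3, SamplerSpec(method="NBRW", target_size=3,
                                                rng_seed=4))
        assert result.actual_size == 3

    def test_mhrw_on_regular_graph_never_stays(self, fixtures):
        # acceptance ratio is 1 on a regular graph: behaves as plain RW
        walk = walk_positions(fixtures["cycle6"], SamplerMethod.MHRW, seed=3)
        trace = list(itertools.islice(walk, 200))
        assert all(a != b for a, b in zip(trace, trace[1:]))

    def test_walk_trace_recorded_and_spans_sample(self, host):
        for method in WALKS:
            result = draw_sample(host, SamplerSpec(method=method, target_size=10,
                                                   rng_seed=1))
            assert result.trace is not None
            assert set(result.subgraph.nodes) <= set(result.trace)

    def test_non_walk_methods_have_no_trace(self, host):
        result = draw_sample(host, SamplerSpec(method="RN", target_size=10))
        assert result.trace is None

    def test_rwj_jumps_escape_components_are_not_needed(self, host):
        result = draw_sample(host, SamplerSpec(method="RWJ", target_size=30,
                                               rng_seed=11))
        assert result.actual_size == 30


def test_triangle_rw_two_nodes_adjacent(triangle):
    result = draw_sample(triangle, SamplerSpec(method="RW", target_size=2, rng_seed=0))
    u, v = list(result.subgraph.nodes)
    assert triangle.has_edge(u, v)
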