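"""Eleven fixed-size subgraph samplers for connected host graphs.

Families:

* node-based — RN (uniform), DEGREE (degree-proportional), PRN
  (PageRank-proportional); nodes drawn without replacement, induced subgraph
  returned;
* edge-based — RE: uniform edges accumulated until the endpoint count
  reaches the target, the sampled-edge subgraph (not induced) returned, so
  the node count can overshoot by one;
* exploration — SB (snowball BFS with a branching cap), CSE (community
  structure expansion: greedily add the boundary node reaching the most
  unknown nodes), SP (random shortest paths between uniform node pairs);
* random walks — RW, MHRW (Metropolis-Hastings, uniform stationary
  distribution), RWJ (uniform jump with probability p), NBRW
  (non-backtracking); walks collect distinct visited nodes and return the
  induced subgraph.

All samplers are deterministic given ``SamplerSpec.rng_seed``.  Hosts are
expected to be connected; callers pass ``largest_component(g)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import networkx as nx
import numpy as np

from .errors import ConfigError, GraphDomainError, SamplingError
from .graphcore import induced_subgraph

logger = logging.getLogger(__name__)

__all__ = ["SamplerMethod", "SamplerSpec", "SampleResult", "draw_sample", "walk_positions"]

# stall guard for walk samplers: abort after this many steps without a new
# node (times #V), restart from a fresh uniform seed, at most MAX_RESTARTS
STALL_FACTOR = 1000
MAX_RESTARTS = 10

DEFAULTS = {"snowball_k": 10, "jump_p": 0.1, "damping": 0.85, "pagerank_tol": 1e-8}


class SamplerMethod(str, Enum):
    RN = "RN"          # random node
    DEGREE = "DEGREE"  # degree-proportional node
    PRN = "PRN"        # PageRank-proportional node
    RE = "RE"          # random edge
    SB = "SB"          # snowball (capped BFS)
    CSE = "CSE"        # community structure expansion
    SP = "SP"          # shortest path
    RW = "RW"          # random walk
    MHRW = "MHRW"      # Metropolis-Hastings random walk
    RWJ = "RWJ"        # random walk with jumps
    NBRW = "NBRW"      # non-backtracking random walk


NODE_BASED = {SamplerMethod.RN, SamplerMethod.DEGREE, SamplerMethod.PRN}
EXPLORATION = {SamplerMethod.SB, SamplerMethod.CSE, SamplerMethod.SP}
WALKS = {SamplerMethod.RW, SamplerMethod.MHRW, SamplerMethod.RWJ, SamplerMethod.NBRW}


@dataclass(frozen=True)
class SamplerSpec:
    method: SamplerMethod
    target_size: int
    rng_seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "method", SamplerMethod(str(self.method).upper()
                                                         if not isinstance(self.method, SamplerMethod)
                                                         else self.method))
        if self.target_size < 2:
            raise ConfigError(f"target_size must be >= 2, got {self.target_size}")
        p = self.param("jump_p")
        if not (0.0 < p < 1.0):
            raise ConfigError(f"jump probability must be in (0,1), got {p}")
        d = self.param("damping")
        if not (0.0 < d < 1.0):
            raise ConfigError(f"PageRank damping must be in (0,1), got {d}")
        if self.param("snowball_k") < 1:
            raise ConfigError("snowball branching k must be >= 1")

    def param(self, name: str):
        return self.params.get(name, DEFAULTS[name])


@dataclass
class SampleResult:
    """A sampled subgraph plus the spec that produced it.

    ``trace`` is the full node visit sequence for walk methods (including
    repeats and Metropolis stays), None otherwise.
    """

    subgraph: nx.Graph
    spec: SamplerSpec
    actual_size: int
    host_id: str = ""
    trace: list | None = None


def _adjacency(g: nx.Graph) -> tuple[list, dict, list[list[int]]]:
    nodes = sorted(g.nodes, key=str)
    index = {v: i for i, v in enumerate(nodes)}
    adj = [[] for _ in nodes]
    for u, v in g.edges:
        adj[index[u]].append(index[v])
        adj[index[v]].append(index[u])
    for lst in adj:
        lst.sort()
    return nodes, index, adj


def _weighted_subset(rng: np.random.Generator, weights: np.ndarray, n: int) -> list[int]:
    """n indices drawn without replacement with probability proportional to
    the (current) weights — sequential draws with removal."""
    w = np.asarray(weights, dtype=float).copy()
    chosen = []
    for _ in range(n):
        p = w / w.sum()
        i = int(rng.choice(len(w), p=p))
        chosen.append(i)
        w[i] = 0.0
    return chosen


def sample_node_based(g: nx.Graph, spec: SamplerSpec) -> SampleResult:
    rng = np.random.default_rng(spec.rng_seed)
    nodes, _, _ = _adjacency(g)
    n = spec.target_size
    if spec.method is SamplerMethod.RN:
        picked = rng.choice(len(nodes), size=n, replace=False)
    elif spec.method is SamplerMethod.DEGREE:
        weights = np.array([g.degree(v) for v in nodes], dtype=float)
        picked = _weighted_subset(rng, weights, n)
    else:  # PRN
        pr = nx.pagerank(g, alpha=spec.param("damping"), tol=spec.param("pagerank_tol"))
        weights = np.array([pr[v] for v in nodes], dtype=float)
        picked = _weighted_subset(rng, weights, n)
    chosen = [nodes[int(i)] for i in picked]
    sub = induced_subgraph(g, chosen)
    return SampleResult(subgraph=sub, spec=spec, actual_size=sub.number_of_nodes())


def sample_random_edge(g: nx.Graph, spec: SamplerSpec) -> SampleResult:
    rng = np.random.default_rng(spec.rng_seed)
    edges = sorted(tuple(sorted(e, key=str)) for e in g.edges)
    order = rng.permutation(len(edges))
    sub = nx.Graph()
    for i in order:
        u, v = edges[int(i)]
        sub.add_edge(u, v)
        if sub.number_of_nodes() >= spec.target_size:
            break
    return SampleResult(subgraph=sub, spec=spec, actual_size=sub.number_of_nodes())


def _sample_snowball(g, spec, rng, nodes, adj) -> list[int]:
    k = spec.param("snowball_k")
    n = spec.target_size
    visited: list[int] = []
    in_visited = set()
    queue: list[int] = []
    while len(visited) < n:
        if not queue:
            # fresh BFS seed; the branching cap can strand nodes, so a
            # connected host may still need re-seeding
            remaining = [i for i in range(len(nodes)) if i not in in_visited]
            seed = remaining[int(rng.integers(len(remaining)))]
            visited.append(seed)
            in_visited.add(seed)
            queue.append(seed)
            continue
        cur = queue.pop(0)
        unvisited = [w for w in adj[cur] if w not in in_visited]
        if len(unvisited) > k:
            picked_idx = rng.choice(len(unvisited), size=k, replace=False)
            unvisited = [unvisited[int(i)] for i in sorted(picked_idx)]
        for w in unvisited:
            if len(visited) >= n:
                break
            visited.append(w)
            in_visited.add(w)
            queue.append(w)
    return visited


def _sample_cse(g, spec, rng, nodes, adj) -> list[int]:
    n = spec.target_size
    start = int(rng.integers(len(nodes)))
    current = {start}
    boundary = set(adj[start])
    while len(current) < n:
        if not boundary:  # disconnected remnant; re-seed
            remaining = [i for i in range(len(nodes)) if i not in current]
            current.add(remaining[int(rng.integers(len(remaining)))])
            boundary = {w for v in current for w in adj[v]} - current
            continue
        known = current | boundary
        best_score = -1
        best_nodes: list[int] = []
        for b in sorted(boundary):
            score = sum(1 for w in adj[b] if w not in known)
            if score > best_score:
                best_score, best_nodes = score, [b]
            elif score == best_score:
                best_nodes.append(b)
        pick = best_nodes[int(rng.integers(len(best_nodes)))]
        current.add(pick)
        boundary.discard(pick)
        boundary.update(w for w in adj[pick] if w not in current)
    return sorted(current)


def _random_shortest_path(rng, adj, s, t) -> list[int]:
    """One shortest s-t path from a BFS whose neighbour order is shuffled."""
    parent = {s: None}
    frontier = [s]
    while frontier and t not in parent:
        nxt = []
        for v in frontier:
            nbrs = list(adj[v])
            rng.shuffle(nbrs)
            for w in nbrs:
                if w not in parent:
                    parent[w] = v
                    nxt.append(w)
        frontier = nxt
    path = [t]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])
    return path[::-1]


def _sample_sp(g, spec, rng, nodes, adj) -> list[int]:
    """Shortest-path sampling with a connected result.

    Paths between uniform node pairs are accumulated; after the first path,
    a drawn path must intersect the collected set (redrawn otherwise), and
    surplus nodes of the final path are truncated from the ends farthest
    from the collected set, so every kept node stays attached.
    """
    n = spec.target_size
    collected: list[int] = []
    in_collected: set[int] = set()
    while len(collected) < n:
        s = int(rng.integers(len(nodes)))
        t = int(rng.integers(len(nodes)))
        if s == t:
            continue
        path = _random_shortest_path(rng, adj, s, t)
        room = n - len(collected)
        if not collected:
            fresh = path[:room]  # keep the source end
            collected.extend(fresh)
            in_collected.update(fresh)
            continue
        if not any(v in in_collected for v in path):
            continue  # cannot attach; redraw the pair
        # maximal runs of unvisited nodes, each bordered by a collected
        # node inside the path: add run nodes inward from that border.
        # A run closed by a collected node attaches on its right (add
        # reversed); the trailing run attaches on its left (add in order).
        runs: list[list[int]] = []
        run: list[int] = []
        for v in path:
            if v in in_collected:
                if run:
                    runs.append(run[::-1])
                    run = []
            else:
                run.append(v)
        if run:
            runs.append(run)
        for run in runs:
            for v in run:
                if len(collected) >= n:
                    return collected
                collected.append(v)
                in_collected.add(v)
    return collected


def walk_positions(g: nx.Graph, method: SamplerMethod, seed: int,
                   start: int | None = None, params: dict | None = None):
    """Infinite generator of walk positions (node indices) for a walk method.

    Yields the start node first and then the position after every step;
    Metropolis rejections yield the unchanged position.  Shared by the
    samplers and by stationary-distribution diagnostics.
    """
    method = SamplerMethod(method)
    if method not in WALKS:
        raise ConfigError(f"{method} is not a walk method")
    params = params or {}
    jump_p = params.get("jump_p", DEFAULTS["jump_p"])
    rng = np.random.default_rng(seed)
    nodes, _, adj = _adjacency(g)
    n = len(nodes)
    cur = int(rng.integers(n)) if start is None else start
    prev = -1
    yield cur
    while True:
        if method is SamplerMethod.RWJ and rng.random() < jump_p:
            nxt = int(rng.integers(n))
            prev = -1  # a teleport breaks the backtracking memory
        else:
            nbrs = adj[cur]
            if method is SamplerMethod.NBRW and len(nbrs) > 1 and prev >= 0:
                choices = [w for w in nbrs if w != prev]
            else:
                choices = nbrs
            cand = choices[int(rng.integers(len(choices)))]
            if method is SamplerMethod.MHRW:
                accept = rng.random() < min(1.0, len(adj[cur]) / len(adj[cand]))
                nxt = cand if accept else cur
                if accept:
                    prev = cur
            else:
                nxt = cand
                prev = cur
        cur = nxt
        yield cur


def _sample_walk(g, spec, rng_seed) -> tuple[list[int], list[int]]:
    """Distinct visited node indices plus the full trace, with stall guard."""
    n = spec.target_size
    n_host = g.number_of_nodes()
    stall_budget = STALL_FACTOR * n_host
    master = np.random.default_rng(rng_seed)
    trace: list[int] = []
    for _ in range(MAX_RESTARTS + 1):
        walk = walk_positions(g, spec.method, seed=int(master.integers(2**31)),
                              params=spec.params)
        visited: list[int] = []
        in_visited: set[int] = set()
        since_new = 0
        for pos in walk:
            trace.append(pos)
            if pos not in in_visited:
                visited.append(pos)
                in_visited.add(pos)
                since_new = 0
                if len(visited) >= n:
                    return visited, trace
            else:
                since_new += 1
                if since_new > stall_budget:
                    break
    raise SamplingError(
        f"{spec.method.value}: restart budget exhausted ({MAX_RESTARTS} restarts) "
        f"without collecting {n} nodes"
    )


def draw_sample(g: nx.Graph, spec: SamplerSpec, host_id: str = "") -> SampleResult:
    """Draw one sample of ``g`` according to ``spec`` (dispatcher)."""
    n_host = g.number_of_nodes()
    if spec.target_size > n_host:
        raise GraphDomainError(
            f"target_size {spec.target_size} exceeds host size {n_host}"
        )
    method = spec.method
    if method in NODE_BASED:
        result = sample_node_based(g, spec)
    elif method is SamplerMethod.RE:
        result = sample_random_edge(g, spec)
    elif method in EXPLORATION:
        rng = np.random.default_rng(spec.rng_seed)
        nodes, _, adj = _adjacency(g)
        if method is SamplerMethod.SB:
            picked = _sample_snowball(g, spec, rng, nodes, adj)
        elif method is SamplerMethod.CSE:
            picked = _sample_cse(g, spec, rng, nodes, adj)
        else:
            picked = _sample_sp(g, spec, rng, nodes, adj)
        sub = induced_subgraph(g, [nodes[i] for i in picked])
        result = SampleResult(subgraph=sub, spec=spec, actual_size=sub.number_of_nodes())
    elif method in WALKS:
        nodes, _, _ = _adjacency(g)
        visited, trace = _sample_walk(g, spec, spec.rng_seed)
        sub = induced_subgraph(g, [nodes[i] for i in visited])
        result = SampleResult(subgraph=sub, spec=spec,
                              actual_size=sub.number_of_nodes(),
                              trace=[nodes[i] for i in trace])
    else:  # pragma: no cover
        raise ConfigError(f"unknown sampling method {method!r}")
    result.host_id = host_id
    return result
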