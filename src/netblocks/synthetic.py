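"""Synthetic discussion-network corpora with controlled global statistics.

A topic corpus emulates monthly reply networks of an online discussion
community: for each topic, a handful of graphs sharing a target node count,
density, global clustering and degree assortativity, with +/-10% monthly
jitter in size.  The bundled topic set mirrors six published Reddit topics
spanning the observed ranges of those statistics.

Generation is three-phase, each phase controlling one statistic while
approximately preserving the earlier ones:

1. a degree-heterogeneous random graph (power-law-like expected degrees,
   exponent 2.5) with exactly the implied edge count, fixing density;
2. triangle-closing rewiring (connect two neighbours of a common node,
   delete a random edge) accepted while global clustering is below target;
3. degree-preserving double-edge swaps accepted when they move degree
   assortativity toward target without pushing clustering out of tolerance.

Achieved statistics are validated against tolerances (density 20% relative;
clustering the larger of +/-0.01 and 50% relative; assortativity +/-0.07)
and recorded in the corpus manifest.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .errors import GenerationError
from .graphcore import GraphStats, compute_stats, write_edge_list

logger = logging.getLogger(__name__)

__all__ = [
    "TopicSpec",
    "ManifestEntry",
    "CorpusManifest",
    "BUNDLED_TOPICS",
    "generate_topic_graph",
    "generate_corpus",
    "fixture_graphs",
    "density_graded_corpus",
    "write_corpus",
]

POWERLAW_EXPONENT = 2.5
ATTEMPT_FACTOR = 20  # rewiring / swap attempt budget, times edge count

DENSITY_RTOL = 0.20
CLUSTERING_ATOL = 0.01
CLUSTERING_RTOL = 0.50
ASSORT_ATOL = 0.07


@dataclass(frozen=True)
class TopicSpec:
    """Target statistics of one topic's monthly graphs."""

    label: str
    n_nodes: int
    target_density: float
    target_clustering: float
    target_assortativity: float
    months: int = 11

    @property
    def implied_edges(self) -> int:
        return round(self.target_density * self.n_nodes * (self.n_nodes - 1) / 2)

    def validate(self) -> None:
        if self.n_nodes < 4:
            raise GenerationError(f"{self.label}: need at least 4 nodes")
        if self.implied_edges < 1:
            raise GenerationError(f"{self.label}: implied edge count is zero")


# Six topics whose published statistics span the corpus ranges
# (sparse/denser, weak/strong disassortativity, low/high clustering).
BUNDLED_TOPICS: tuple[TopicSpec, ...] = (
    TopicSpec("counterstrike", 447, 0.0025, 0.0086, -0.0668),
    TopicSpec("freedonuts", 605, 0.0026, 0.0228, -0.3823),
    TopicSpec("feminism", 675, 0.0022, 0.0259, -0.0310),
    TopicSpec("introvert", 582, 0.0022, 0.0145, -0.0863),
    TopicSpec("pizza", 616, 0.0021, 0.0198, -0.0882),
    TopicSpec("stopsmoking", 831, 0.0024, 0.0503, -0.1102),
)


def _stats_ok(spec: TopicSpec, stats: GraphStats) -> list[str]:
    problems = []
    if abs(stats.density - spec.target_density) > DENSITY_RTOL * spec.target_density:
        problems.append(f"density {stats.density:.5f} vs {spec.target_density:.5f}")
    ctol = max(CLUSTERING_ATOL, CLUSTERING_RTOL * spec.target_clustering)
    if abs(stats.global_clustering - spec.target_clustering) > ctol:
        problems.append(
            f"clustering {stats.global_clustering:.4f} vs {spec.target_clustering:.4f}"
        )
    a = stats.degree_assortativity
    # NaN means a degree-regular graph (zero endpoint-degree variance), for
    # which the Pearson coefficient is undefined rather than off-target
    if not np.isnan(a) and abs(a - spec.target_assortativity) > ASSORT_ATOL:
        problems.append(f"assortativity {a:.4f} vs {spec.target_assortativity:.4f}")
    return problems


def _chung_lu_exact(n: int, m: int, rng: np.random.Generator) -> dict[int, set[int]]:
    """m distinct edges with endpoints drawn from power-law-like weights."""
    max_edges = n * (n - 1) // 2
    if m > max_edges:
        raise GenerationError(f"edge count {m} exceeds simple-graph maximum {max_edges}")
    # expected-degree weights w_i ~ i^(-1/(exponent-1)), shuffled node order
    ranks = rng.permutation(n) + 1
    w = ranks.astype(float) ** (-1.0 / (POWERLAW_EXPONENT - 1.0))
    p = w / w.sum()
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    n_edges = 0
    attempts = 0
    while n_edges < m:
        budget = max(2 * (m - n_edges), 1000)
        us = rng.choice(n, size=budget, p=p)
        vs = rng.choice(n, size=budget, p=p)
        for u, v in zip(us, vs):
            u, v = int(u), int(v)
            if u != v and v not in adj[u]:
                adj[u].add(v)
                adj[v].add(u)
                n_edges += 1
                if n_edges == m:
                    break
        attempts += 1
        if attempts > 200:
            # dense regime: fall back to uniform fill of missing pairs
            missing = [(i, j) for i in range(n) for j in range(i + 1, n)
                       if j not in adj[i]]
            fill = rng.choice(len(missing), size=m - n_edges, replace=False)
            for idx in fill:
                i, j = missing[int(idx)]
                adj[i].add(j)
                adj[j].add(i)
            n_edges = m
    return adj


def _tri3_triads(adj: dict[int, set[int]]) -> tuple[int, int]:
    """(3 * triangle count, connected-triple count); their ratio is the
    global clustering coefficient."""
    tri3 = sum(len(adj[u] & adj[v]) for u in adj for v in adj[u] if u < v)
    triads = sum(d * (d - 1) // 2 for d in (len(s) for s in adj.values()))
    return tri3, triads


def _clustering_phase(adj, m, target, rng: np.random.Generator) -> None:
    """Rewire toward the target global clustering from either side.

    Raising move: connect two non-adjacent neighbours a,b of a common node v
    and delete a random edge not touching {v,a,b}.  Lowering move: delete a
    random edge and reconnect a uniformly drawn non-adjacent pair.  Both
    preserve the edge count; triangle and triple counts are maintained
    incrementally and a move is accepted only if it brings the coefficient
    strictly closer to target.
    """
    n = len(adj)
    tri3, triads = _tri3_triads(adj)
    edges = [(u, v) for u in adj for v in adj[u] if u < v]

    def clustering(t3=None, tr=None):
        t3 = tri3 if t3 is None else t3
        tr = triads if tr is None else tr
        return t3 / tr if tr else 0.0

    budget = 3 * ATTEMPT_FACTOR * m
    for _ in range(budget):
        gap = clustering() - target
        if abs(gap) <= 1e-4:
            break
        if gap < 0:  # raise: close a triangle at a random node
            v = int(rng.integers(n))
            nbrs = adj[v]
            if len(nbrs) < 2:
                continue
            pair = rng.choice(sorted(nbrs), size=2, replace=False)
            a, b = int(pair[0]), int(pair[1])
            if b in adj[a]:
                continue
            eidx = int(rng.integers(len(edges)))
            x, y = edges[eidx]
            if {x, y} & {a, b, v}:
                continue
        else:  # lower: scatter an edge to a random non-adjacent pair
            eidx = int(rng.integers(len(edges)))
            x, y = edges[eidx]
            a, b = int(rng.integers(n)), int(rng.integers(n))
            if a == b or b in adj[a] or {a, b} & {x, y}:
                continue
        gain = len(adj[a] & adj[b])
        loss = len(adj[x] & adj[y])
        d_triads = (len(adj[a]) + len(adj[b])) - (len(adj[x]) - 1) - (len(adj[y]) - 1)
        new_tri3 = tri3 + 3 * (gain - loss)
        new_triads = triads + d_triads
        if new_triads <= 0:
            continue
        if abs(clustering(new_tri3, new_triads) - target) >= abs(gap):
            continue
        adj[x].discard(y)
        adj[y].discard(x)
        adj[a].add(b)
        adj[b].add(a)
        tri3, triads = new_tri3, new_triads
        edges[eidx] = (a, b) if a < b else (b, a)


def _assortativity_state(adj):
    """(Se, mu, var, m): sufficient statistics of the endpoint-degree Pearson
    correlation; only Se = sum over edges of deg(u)*deg(v) changes under
    degree-preserving swaps."""
    deg = {v: len(s) for v, s in adj.items()}
    edges = [(u, v) for u in adj for v in adj[u] if u < v]
    m = len(edges)
    se = sum(deg[u] * deg[v] for u, v in edges)
    s1 = sum(deg[u] + deg[v] for u, v in edges)
    s2 = sum(deg[u] ** 2 + deg[v] ** 2 for u, v in edges)
    mu = s1 / (2 * m)
    var = s2 / (2 * m) - mu * mu
    return se, mu, var, m, deg, edges


def _assortativity_phase(adj, m, target, clustering_floor, rng) -> None:
    """Double-edge swaps toward the target assortativity.

    Swaps preserve the degree sequence; a swap is rejected when it would
    push global clustering below ``clustering_floor`` (phase-2 protection).
    """
    se, mu, var, m_edges, deg, edges = _assortativity_state(adj)
    if var <= 0:
        return

    def assort(se_val):
        return (se_val / m_edges - mu * mu) / var

    se_target = m_edges * (var * target + mu * mu)
    tri3, triads = _tri3_triads(adj)  # triads fixed: degrees are preserved

    budget = 3 * ATTEMPT_FACTOR * m
    for _ in range(budget):
        if abs(assort(se) - target) <= 0.015:
            break
        i, j = int(rng.integers(len(edges))), int(rng.integers(len(edges)))
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if len({a, b, c, d}) < 4:
            continue
        # of the two rewiring orientations, take the one that moves the
        # endpoint-degree product sum closest to its target
        options = []
        for (w1, x1), (w2, x2) in (((a, d), (c, b)), ((a, c), (b, d))):
            if x1 in adj[w1] or x2 in adj[w2]:
                continue
            d_se = (deg[w1] * deg[x1] + deg[w2] * deg[x2]
                    - deg[a] * deg[b] - deg[c] * deg[d])
            options.append((abs(se + d_se - se_target), (w1, x1), (w2, x2), d_se))
        if not options:
            continue
        _, (w1, x1), (w2, x2), d_se = min(options)
        new_se = se + d_se
        if abs(new_se - se_target) >= abs(se - se_target):
            continue
        # triangle delta: the removed pair and the added pair of edges each
        # share no node, so their contributions are independent; gains are
        # measured on the graph with both old edges removed
        loss = len(adj[a] & adj[b]) + len(adj[c] & adj[d])
        adj[a].discard(b); adj[b].discard(a)
        adj[c].discard(d); adj[d].discard(c)
        gain = len(adj[w1] & adj[x1]) + len(adj[w2] & adj[x2])
        new_tri3 = tri3 + 3 * (gain - loss)
        if triads and new_tri3 / triads < clustering_floor:
            adj[a].add(b); adj[b].add(a)
            adj[c].add(d); adj[d].add(c)
            continue
        adj[w1].add(x1); adj[x1].add(w1)
        adj[w2].add(x2); adj[x2].add(w2)
        tri3 = new_tri3
        se = new_se
        edges[i] = (w1, x1) if w1 < x1 else (x1, w1)
        edges[j] = (w2, x2) if w2 < x2 else (x2, w2)


def generate_topic_graph(spec: TopicSpec, seed: int) -> nx.Graph:
    """One graph meeting ``spec``'s targets within tolerance.

    Node identifiers are ``"n0".."n{N-1}"``.  Raises
    :class:`GenerationError` (reporting the achieved statistics) when the
    attempt budget ends outside tolerance.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    n, m = spec.n_nodes, spec.implied_edges
    adj = _chung_lu_exact(n, m, rng)
    if m < n * (n - 1) // 2:  # phases are no-ops on a complete graph
        ctol = max(CLUSTERING_ATOL, CLUSTERING_RTOL * spec.target_clustering)
        floor = max(spec.target_clustering - 0.8 * ctol, 0.0)
        # the two objectives interact (disassortative rewiring erodes
        # triangles), so the phases alternate until both are in band
        for _ in range(4):
            _clustering_phase(adj, m, spec.target_clustering, rng)
            _assortativity_phase(adj, m, spec.target_assortativity, floor, rng)
            tri3, triads = _tri3_triads(adj)
            clu = tri3 / triads if triads else 0.0
            se, mu, var, m_e, _, _ = _assortativity_state(adj)
            a = (se / m_e - mu * mu) / var if var > 0 else float("nan")
            if (abs(clu - spec.target_clustering) <= 0.9 * ctol
                    and abs(a - spec.target_assortativity) <= 0.9 * ASSORT_ATOL):
                break
    g = nx.Graph()
    g.add_nodes_from(f"n{i}" for i in range(n))
    g.add_edges_from((f"n{u}", f"n{v}") for u in adj for v in adj[u] if u < v)
    stats = compute_stats(g)
    problems = _stats_ok(spec, stats)
    if problems:
        raise GenerationError(f"{spec.label}: targets missed: " + "; ".join(problems))
    return g


@dataclass(frozen=True)
class ManifestEntry:
    label: str
    month: int
    seed: int
    ok: bool
    stats: GraphStats | None = None
    error: str = ""

    @property
    def host_id(self) -> str:
        return f"{self.label}_m{self.month:02d}"


@dataclass
class CorpusManifest:
    entries: list[ManifestEntry] = field(default_factory=list)

    def to_json(self) -> str:
        rows = []
        for e in self.entries:
            row = {"label": e.label, "month": e.month, "seed": e.seed,
                   "host_id": e.host_id, "ok": e.ok, "error": e.error}
            if e.stats is not None:
                row["stats"] = {
                    "n_nodes": e.stats.n_nodes,
                    "n_edges": e.stats.n_edges,
                    "density": e.stats.density,
                    "global_clustering": e.stats.global_clustering,
                    "degree_assortativity": e.stats.degree_assortativity,
                }
            rows.append(row)
        return json.dumps(rows, indent=2, sort_keys=True)


def month_seed(base_seed: int, label: str, month: int) -> int:
    return (base_seed + zlib.crc32(f"{label}:{month}".encode())) % (2**31)


def generate_corpus(
    specs: list[TopicSpec] | tuple[TopicSpec, ...] = BUNDLED_TOPICS,
    base_seed: int = 0,
) -> tuple[CorpusManifest, dict[str, nx.Graph]]:
    """``months`` graphs per topic with per-month seeds and +/-10% size jitter.

    Failures are recorded in the manifest and do not abort the corpus.
    """
    manifest = CorpusManifest()
    graphs: dict[str, nx.Graph] = {}
    for spec in specs:
        for month in range(spec.months):
            seed = month_seed(base_seed, spec.label, month)
            rng = np.random.default_rng(seed)
            n_month = max(4, round(spec.n_nodes * (1.0 + rng.uniform(-0.1, 0.1))))
            month_spec = TopicSpec(
                label=spec.label,
                n_nodes=n_month,
                target_density=spec.target_density,
                target_clustering=spec.target_clustering,
                target_assortativity=spec.target_assortativity,
                months=spec.months,
            )
            entry_seed = int(rng.integers(2**31))
            try:
                g = generate_topic_graph(month_spec, entry_seed)
            except GenerationError as exc:
                logger.warning("corpus generation failure: %s", exc)
                manifest.entries.append(ManifestEntry(
                    label=spec.label, month=month, seed=entry_seed, ok=False,
                    error=str(exc)))
                continue
            entry = ManifestEntry(label=spec.label, month=month, seed=entry_seed,
                                  ok=True, stats=compute_stats(g))
            manifest.entries.append(entry)
            graphs[entry.host_id] = g
    return manifest, graphs


def write_corpus(manifest: CorpusManifest, graphs: dict[str, nx.Graph],
                 out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for host_id, g in graphs.items():
        write_edge_list(g, out / f"{host_id}.edges")
    (out / "manifest.json").write_text(manifest.to_json())


def density_graded_corpus(
    n_nodes: int, densities, base_seed: int = 0
) -> dict[str, nx.Graph]:
    """Erdos-Renyi calibration corpus with a graded density sweep.

    Used to study how well sample motif features track a host property that
    varies cleanly across hosts (e.g. regression-recovery checks).
    """
    graphs = {}
    for i, p in enumerate(densities):
        g = nx.gnp_random_graph(n_nodes, float(p), seed=base_seed + i)
        graphs[f"er_d{i:03d}"] = nx.relabel_nodes(g, str)
    return graphs


def fixture_graphs() -> dict[str, nx.Graph]:
    """Deterministic toy graphs used throughout the test-suite."""
    two_tri = nx.Graph([("a", "b"), ("b", "c"), ("c", "a"),
                        ("c", "d"), ("d", "e"), ("e", "c")])
    return {
        "triangle": nx.relabel_nodes(nx.cycle_graph(3), str),
        "path10": nx.relabel_nodes(nx.path_graph(10), str),
        "star10": nx.relabel_nodes(nx.star_graph(9), str),
        "cycle6": nx.relabel_nodes(nx.cycle_graph(6), str),
        "K4": nx.relabel_nodes(nx.complete_graph(4), str),
        "K10": nx.relabel_nodes(nx.complete_graph(10), str),
        "two-triangles-shared-node": two_tri,
        "barbell(5,5)": nx.relabel_nodes(nx.barbell_graph(5, 0), str),
    }
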