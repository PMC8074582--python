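"""Graph data model, edge-list I/O and global topological statistics.

Graphs are simple undirected :class:`networkx.Graph` objects whose node
identifiers are strings.  Self-loops and duplicate edges are dropped at load
time; directions and weights are never interpreted.  The statistics collected
in :class:`GraphStats` are the four columns used to characterise discussion
corpora: node count, density, global (transitivity-based) clustering and
degree assortativity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .errors import EdgeListParseError, GraphDomainError

logger = logging.getLogger(__name__)

__all__ = [
    "GraphStats",
    "load_edge_list",
    "load_graph",
    "write_edge_list",
    "read_edge_list",
    "degree_assortativity",
    "compute_stats",
    "induced_subgraph",
    "largest_component",
]


@dataclass(frozen=True)
class GraphStats:
    """Global topological statistics of a simple undirected graph.

    ``degree_assortativity`` is the Pearson correlation of degrees over the
    2m ordered edge-endpoint pairs (both orientations counted) and is NaN
    when the endpoint degree sequence has zero variance.
    """

    n_nodes: int
    n_edges: int
    density: float
    global_clustering: float
    degree_assortativity: float


def load_edge_list(path: str | Path, comment_prefix: str = "#") -> nx.Graph:
    """Read a whitespace-separated edge list into a simple undirected graph.

    Each non-blank, non-comment line must contain at least two tokens; the
    first two are the edge endpoints, kept verbatim as strings.  Self-loops
    are dropped with a warning and duplicate edges collapse silently.
    """
    g = nx.Graph()
    n_loops = 0
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(comment_prefix):
                continue
            tokens = stripped.split()
            if len(tokens) < 2:
                raise EdgeListParseError(
                    f"{path}: line {lineno}: expected at least 2 tokens, got {len(tokens)}"
                )
            u, v = tokens[0], tokens[1]
            if u == v:
                n_loops += 1
                g.add_node(u)
                continue
            g.add_edge(u, v)
    if n_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, n_loops)
    return g


def load_graph(path: str | Path) -> nx.Graph:
    """Load a graph from an edge list or, for ``.graphml`` files, GraphML.

    Node identifiers are coerced to strings either way.
    """
    path = Path(path)
    if path.suffix.lower() == ".graphml":
        g = nx.read_graphml(path)
        g = nx.Graph(g)  # collapse multi-edges / directions if present
        g.remove_edges_from(nx.selfloop_edges(g))
        return nx.relabel_nodes(g, {n: str(n) for n in g.nodes})
    return load_edge_list(path)


def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    """Write one ``u v`` line per edge, nodes sorted for reproducibility.

    Isolated nodes are recorded as ``# node <id>`` comment lines so that a
    round-trip through :func:`load_edge_list` preserves the node set.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"{u} {v}\n")
        for n in sorted(g.nodes):
            if g.degree(n) == 0:
                fh.write(f"# node {n}\n")


def _read_isolated_nodes(path: str | Path, g: nx.Graph) -> None:
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            tokens = line.split()
            if len(tokens) == 3 and tokens[0] == "#" and tokens[1] == "node":
                g.add_node(tokens[2])


def read_edge_list(path: str | Path) -> nx.Graph:
    """Round-trip partner of :func:`write_edge_list` (restores isolates)."""
    g = load_edge_list(path)
    _read_isolated_nodes(path, g)
    return g


def degree_assortativity(g: nx.Graph) -> float:
    """Pearson degree–degree correlation over edge endpoints.

    Both orientations of every edge are counted, so the estimate is the
    standard one reported for undirected graphs; NaN when every endpoint has
    the same degree (zero variance).
    """
    if g.number_of_edges() == 0:
        return math.nan
    deg = dict(g.degree())
    du = np.fromiter((deg[u] for u, v in g.edges), dtype=float, count=g.number_of_edges())
    dv = np.fromiter((deg[v] for u, v in g.edges), dtype=float, count=g.number_of_edges())
    x = np.concatenate([du, dv])
    y = np.concatenate([dv, du])
    if np.var(x) == 0.0:
        return math.nan
    return float(np.corrcoef(x, y)[0, 1])


def compute_stats(g: nx.Graph) -> GraphStats:
    """Compute the five corpus-characterisation statistics of ``g``.

    Disconnected graphs are summarised whole; the density denominator is
    n(n-1)/2 and clustering is the global transitivity 3*triangles/triads.
    """
    n = g.number_of_nodes()
    if n < 2:
        raise GraphDomainError(f"compute_stats requires >= 2 nodes, got {n}")
    return GraphStats(
        n_nodes=n,
        n_edges=g.number_of_edges(),
        density=nx.density(g),
        global_clustering=nx.transitivity(g),
        degree_assortativity=degree_assortativity(g),
    )


def induced_subgraph(g: nx.Graph, node_subset) -> nx.Graph:
    """Induced subgraph on ``node_subset`` as an independent copy."""
    subset = set(node_subset)
    if not subset:
        raise GraphDomainError("node subset must be non-empty")
    unknown = subset - set(g.nodes)
    if unknown:
        raise GraphDomainError(f"nodes not in graph: {sorted(unknown)[:5]}")
    return nx.Graph(g.subgraph(subset))


def largest_component(g: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Ties on component size are broken deterministically in favour of the
    component containing the lexicographically smallest node identifier.
    """
    if g.number_of_nodes() == 0:
        raise GraphDomainError("empty graph has no components")
    components = list(nx.connected_components(g))
    best_size = max(len(c) for c in components)
    winners = [c for c in components if len(c) == best_size]
    best = min(winners, key=lambda c: min(str(n) for n in c))
    return induced_subgraph(g, best)
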