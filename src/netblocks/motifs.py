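"""Census of connected k-node induced subgraphs (motifs), k in {3,4,5}.

Enumeration uses the ESU tree scheme: a subgraph is grown from its
lowest-ordered node by adding only exclusive neighbours with a higher node
order, which visits every connected k-node induced subgraph exactly once.
Occurrences are grouped into isomorphism classes by a canonical form — the
lexicographically smallest upper-triangular adjacency bit-string over all k!
node permutations, which is exhaustive but trivially cheap for k <= 5.

Three frequency variants are derived from a census:

* ``JOINT_RATIO`` — per-class share of all occurrences (overlaps allowed),
* ``DISJOINT_RATIO`` — per-class count of a greedy maximal independent set
  of non-overlapping occurrences, divided by the total occurrence count,
* ``DISJOINT_TOTAL_RATIO`` — the scalar share of occurrences surviving the
  disjointness filter.

Disjointness means sharing no edge (``EDGE_DISJOINT``) or no node
(``NODE_DISJOINT``); the independent set is found by the shuffle-then-filter
greedy heuristic with a recorded RNG seed.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from pathlib import Path

import networkx as nx
import numpy as np

from .errors import GraphDomainError

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapPolicy",
    "FrequencyVariant",
    "MotifClassId",
    "MotifOccurrence",
    "MotifCensus",
    "canonical_class",
    "connected_classes",
    "n_connected_classes",
    "enumerate_connected_subgraphs",
    "greedy_disjoint_set",
    "build_census",
    "motif_frequencies",
]

MIN_K, MAX_K = 3, 5


class OverlapPolicy(str, Enum):
    EDGE_DISJOINT = "EDGE_DISJOINT"
    NODE_DISJOINT = "NODE_DISJOINT"


class FrequencyVariant(str, Enum):
    JOINT_RATIO = "JOINT_RATIO"
    DISJOINT_RATIO = "DISJOINT_RATIO"
    DISJOINT_TOTAL_RATIO = "DISJOINT_TOTAL_RATIO"


# --------------------------------------------------------------------------
# canonical forms


def _pair_bits(k: int) -> list[tuple[int, int]]:
    """Row-major upper-triangular pair order; bit 0 is the (0,1) pair."""
    return list(itertools.combinations(range(k), 2))


@lru_cache(maxsize=None)
def _canon_tables(k: int) -> tuple[dict[int, int], tuple[int, ...]]:
    """For every adjacency mask on k labelled nodes: its canonical mask.

    Returns ``(canon_of_mask, connected_canons)`` where the second element
    is the sorted tuple of canonical masks of *connected* graphs.  Masks use
    the row-major upper-triangular bit order with bit index increasing along
    the pair order, and the canonical form is the minimum mask over all k!
    relabellings (lexicographic minimum of the bit-string read from pair 0).
    """
    pairs = _pair_bits(k)
    nbits = len(pairs)
    perms = list(itertools.permutations(range(k)))
    # position of each (i,j) pair in the bit order
    pos = {p: i for i, p in enumerate(pairs)}

    # Precompute, per permutation, where each bit moves.
    perm_maps = []
    for perm in perms:
        mapping = []
        for b, (i, j) in enumerate(pairs):
            a, c = perm[i], perm[j]
            mapping.append(pos[(a, c) if a < c else (c, a)])
        perm_maps.append(mapping)

    def _all_reached(adj: list[int], kk: int) -> bool:
        seen = 1
        stack = [0]
        while stack:
            v = stack.pop()
            m = adj[v] & ~seen
            while m:
                w = (m & -m).bit_length() - 1
                m &= m - 1
                seen |= 1 << w
                stack.append(w)
        return seen == (1 << kk) - 1

    canon: dict[int, int] = {}
    connected_set: set[int] = set()
    for mask in range(1 << nbits):
        if mask in canon:
            continue
        orbit = set()
        best = mask
        for mapping in perm_maps:
            out = 0
            for b in range(nbits):
                if mask >> b & 1:
                    out |= 1 << mapping[b]
            orbit.add(out)
            if out < best:
                best = out
        for m in orbit:
            canon[m] = best
        adj = [0] * k
        for b, (i, j) in enumerate(pairs):
            if mask >> b & 1:
                adj[i] |= 1 << j
                adj[j] |= 1 << i
        if _all_reached(adj, k):
            connected_set.add(best)
    return canon, tuple(sorted(connected_set))


def _mask_to_bitstring(mask: int, k: int) -> str:
    nbits = k * (k - 1) // 2
    return "".join("1" if mask >> b & 1 else "0" for b in range(nbits))


@dataclass(frozen=True, order=True)
class MotifClassId:
    """Isomorphism class of a connected k-node graph.

    ``canon`` is the canonical upper-triangular adjacency bit-string
    (row-major pair order); equal ids mean isomorphic induced subgraphs.
    """

    k: int
    canon: str


@dataclass(frozen=True)
class MotifOccurrence:
    """One connected k-node induced subgraph, identified by its node set."""

    node_set: frozenset
    class_id: MotifClassId


def _check_k(k: int) -> None:
    if not (MIN_K <= k <= MAX_K):
        raise GraphDomainError(f"motif size must be in [{MIN_K},{MAX_K}], got {k}")


def connected_classes(k: int) -> list[MotifClassId]:
    """All isomorphism classes of connected k-node graphs, in fixed
    (canonical bit-string) order.  2 classes for k=3, 6 for k=4, 21 for k=5."""
    _check_k(k)
    _, canons = _canon_tables(k)
    return [MotifClassId(k, _mask_to_bitstring(c, k)) for c in canons]


def n_connected_classes(k: int) -> int:
    _check_k(k)
    return len(_canon_tables(k)[1])


def canonical_class(g: nx.Graph) -> MotifClassId:
    """Canonical isomorphism class of a connected graph on k <= 5 nodes."""
    k = g.number_of_nodes()
    _check_k(k)
    if not nx.is_connected(g):
        raise GraphDomainError("canonical_class requires a connected graph")
    nodes = list(g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    mask = 0
    pos = {p: b for b, p in enumerate(_pair_bits(k))}
    for u, v in g.edges:
        i, j = idx[u], idx[v]
        mask |= 1 << pos[(i, j) if i < j else (j, i)]
    canon, _ = _canon_tables(k)
    return MotifClassId(k, _mask_to_bitstring(canon[mask], k))


# --------------------------------------------------------------------------
# ESU enumeration


def _index_graph(g: nx.Graph) -> tuple[list, list[int]]:
    """Sorted node list plus adjacency bitmasks over node indices."""
    nodes = sorted(g.nodes, key=str)
    idx = {n: i for i, n in enumerate(nodes)}
    adj = [0] * len(nodes)
    for u, v in g.edges:
        i, j = idx[u], idx[v]
        adj[i] |= 1 << j
        adj[j] |= 1 << i
    return nodes, adj


def _esu_enumerate(adj: list[int], k: int):
    """Yield each connected k-subset of 0..n-1 exactly once, as a bitmask.

    Classic ESU: from every root v, extend only with exclusive neighbours of
    index greater than v.
    """
    n = len(adj)
    above = [~((1 << (v + 1)) - 1) for v in range(n)]  # indices > v

    def extend(sub: int, sub_nbrs: int, ext: int, root_above: int, depth: int):
        if depth == k:
            yield sub
            return
        while ext:
            wbit = ext & -ext
            ext &= ~wbit
            w = wbit.bit_length() - 1
            new_sub = sub | wbit
            new_nbrs = sub_nbrs | adj[w]
            # exclusive neighbours of w: not in sub and not adjacent to sub
            excl = adj[w] & ~sub_nbrs & ~sub & root_above
            yield from extend(new_sub, new_nbrs, ext | excl, root_above, depth + 1)

    for v in range(n):
        vbit = 1 << v
        ra = above[v]
        ext0 = adj[v] & ra
        yield from extend(vbit, adj[v] | vbit, ext0, ra, 1)


def _mask_nodes(mask: int) -> list[int]:
    out = []
    while mask:
        b = mask & -mask
        out.append(b.bit_length() - 1)
        mask &= mask - 1
    return out


def _class_of_subset(adj: list[int], members: list[int], pos: dict, canon: dict[int, int]) -> int:
    mask = 0
    kk = len(members)
    for a in range(kk):
        ia = members[a]
        row = adj[ia]
        for b in range(a + 1, kk):
            if row >> members[b] & 1:
                mask |= 1 << pos[(a, b)]
    return canon[mask]


def _enumerate_indexed(g: nx.Graph, k: int):
    """Internal fast path: (nodes, adj, list of (member-tuple, canon-mask))."""
    _check_k(k)
    if g.number_of_nodes() < k:
        raise GraphDomainError(f"graph has fewer than k={k} nodes")
    nodes, adj = _index_graph(g)
    canon, _ = _canon_tables(k)
    pos = {p: b for b, p in enumerate(_pair_bits(k))}
    occs = []
    for mask in _esu_enumerate(adj, k):
        members = _mask_nodes(mask)  # ascending
        occs.append((tuple(members), _class_of_subset(adj, members, pos, canon)))
    return nodes, adj, occs


def enumerate_connected_subgraphs(g: nx.Graph, k: int) -> list[MotifOccurrence]:
    """All connected k-node induced subgraphs of ``g``, each exactly once."""
    nodes, _, occs = _enumerate_indexed(g, k)
    return [
        MotifOccurrence(
            node_set=frozenset(nodes[i] for i in members),
            class_id=MotifClassId(k, _mask_to_bitstring(cmask, k)),
        )
        for members, cmask in occs
    ]


# --------------------------------------------------------------------------
# greedy disjoint selection and census


def _greedy_disjoint_indices(
    occs: list[tuple[tuple, int]], adj: list[int], policy: OverlapPolicy, seed: int
) -> list[int]:
    """Indices (into occs) of a maximal set of pairwise non-overlapping
    occurrences, built by seeded shuffle + greedy filtering."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(occs))
    kept: list[int] = []
    if policy is OverlapPolicy.NODE_DISJOINT:
        used = 0
        for i in order:
            members, _ = occs[i]
            m = 0
            for v in members:
                m |= 1 << v
            if not (m & used):
                used |= m
                kept.append(int(i))
    else:
        used_edges: set[tuple[int, int]] = set()
        for i in order:
            members, _ = occs[i]
            edges = [
                (members[a], members[b])
                for a in range(len(members))
                for b in range(a + 1, len(members))
                if adj[members[a]] >> members[b] & 1
            ]
            if not any(e in used_edges for e in edges):
                used_edges.update(edges)
                kept.append(int(i))
    return kept


def greedy_disjoint_set(
    occurrences: list[MotifOccurrence],
    g: nx.Graph,
    policy: OverlapPolicy = OverlapPolicy.EDGE_DISJOINT,
    seed: int = 0,
) -> list[MotifOccurrence]:
    """Maximal set of pairwise non-overlapping occurrences (greedy, shuffled).

    Overlap means a shared induced edge (``EDGE_DISJOINT``) or a shared node
    (``NODE_DISJOINT``).  The shuffle order is drawn from ``seed``, which
    makes the heuristic reproducible; the result is maximal — every dropped
    occurrence overlaps a kept one.
    """
    nodes, adj = _index_graph(g)
    idx = {n: i for i, n in enumerate(nodes)}
    occs = [(tuple(sorted(idx[n] for n in o.node_set)), 0) for o in occurrences]
    kept = _greedy_disjoint_indices(occs, adj, policy, seed)
    return [occurrences[i] for i in kept]


@dataclass
class MotifCensus:
    """Joint and disjoint per-class occurrence counts at motif size k."""

    k: int
    joint_counts: dict[MotifClassId, int]
    disjoint_counts: dict[MotifClassId, int]
    overlap_policy: OverlapPolicy
    mis_seed: int
    total_joint: int = field(init=False)
    total_disjoint: int = field(init=False)

    def __post_init__(self) -> None:
        self.total_joint = sum(self.joint_counts.values())
        self.total_disjoint = sum(self.disjoint_counts.values())

    @property
    def class_order(self) -> list[MotifClassId]:
        return connected_classes(self.k)


def build_census(
    g: nx.Graph,
    k: int = 4,
    policy: OverlapPolicy = OverlapPolicy.EDGE_DISJOINT,
    seed: int = 0,
) -> MotifCensus:
    """Full joint census plus greedy disjoint census of ``g`` at size k."""
    _check_k(k)
    classes = connected_classes(k)
    by_canon = {c.canon: c for c in classes}
    joint = {c: 0 for c in classes}
    disjoint = {c: 0 for c in classes}
    if g.number_of_nodes() >= k:
        _, adj, occs = _enumerate_indexed(g, k)
        for _, cmask in occs:
            joint[by_canon[_mask_to_bitstring(cmask, k)]] += 1
        for i in _greedy_disjoint_indices(occs, adj, policy, seed):
            disjoint[by_canon[_mask_to_bitstring(occs[i][1], k)]] += 1
    return MotifCensus(k=k, joint_counts=joint, disjoint_counts=disjoint,
                       overlap_policy=policy, mis_seed=seed)


def motif_frequencies(census: MotifCensus, variant: FrequencyVariant):
    """Frequency vector (fixed class order) or scalar for the given variant.

    Both disjoint variants are normalised by the *joint* total, i.e. by the
    number of all size-k motifs; an all-zero census yields zeros with a
    logged warning.
    """
    variant = FrequencyVariant(variant)
    order = census.class_order
    total = census.total_joint
    if total == 0:
        logger.warning("census at k=%d has no occurrences; frequencies are zero", census.k)
        if variant is FrequencyVariant.DISJOINT_TOTAL_RATIO:
            return 0.0
        return np.zeros(len(order))
    if variant is FrequencyVariant.JOINT_RATIO:
        return np.array([census.joint_counts[c] / total for c in order])
    if variant is FrequencyVariant.DISJOINT_RATIO:
        return np.array([census.disjoint_counts[c] / total for c in order])
    return census.total_disjoint / total


def census_to_csv(census: MotifCensus, path: str | Path) -> None:
    """CSV of per-class counts/ratios plus a JSON sidecar with the totals."""
    import pandas as pd

    total = max(census.total_joint, 1)
    rows = [
        {
            "class_canon": c.canon,
            "k": census.k,
            "joint_count": census.joint_counts[c],
            "disjoint_count": census.disjoint_counts[c],
            "joint_ratio": census.joint_counts[c] / total,
            "disjoint_ratio": census.disjoint_counts[c] / total,
        }
        for c in census.class_order
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    sidecar = Path(str(path) + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "k": census.k,
                "overlap_policy": census.overlap_policy.value,
                "mis_seed": census.mis_seed,
                "total_joint": census.total_joint,
                "total_disjoint": census.total_disjoint,
            },
            indent=2,
            sort_keys=True,
        )
    )
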