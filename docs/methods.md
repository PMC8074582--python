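# Methods

`netblocks` searches for small "building block" subgraphs of a host network
that preserve two things at once: the host's motif composition (topology)
and its speed of epidemic spread (dynamics). This note records the models,
the numerical choices, and what the synthetic test corpus does and does not
establish.

## Problem setting

Given a simple undirected host graph *G*, a sampler extracts an *n*-node
subgraph *M*. Two criteria judge *M*:

* **Topological.** Let `mdist(G)` be the vector of motif-class frequencies
  of *G* (connected induced *k*-node subgraphs grouped by isomorphism).
  The deviation is the squared distance
  `delta(M, G) = sum_c (mdist(G)_c − mdist(M)_c)^2`, reported both raw and
  divided by the class count (the "MSE"). Smaller is better; `delta(G, G) = 0`.
* **Functional.** A regression predicts the host's SI transient time
  `tau(G)` from the sample's motif-frequency features. Prediction quality
  (fold-mean R²) measures how much of the host's dynamics the sample
  retains.

Samplers are ranked under both criteria; the recommended method is the
first to appear in both top lists, and the recommended sample size is the
smallest after which both criterion curves flatten (consecutive change
below 10% of the curve's range over the size grid — the threshold is
configurable).

## SI dynamics and the transient time

Dynamics are discrete-time susceptible-infected (SI) with synchronous
updates: at each step a susceptible node with *m* infected neighbours
becomes infected with probability `1 − (1−r)^m`, i.e. independent
per-edge Bernoulli transmission at rate *r* per step. Infected nodes never
recover. One uniformly chosen node is infected at *t = 0* (a fixed seed
node is supported for tests).

The transient time `tau` is the first step at which the infected count
reaches `theta·N` of the simulated (connected) graph. The default
`theta = 1.0` — full activation — is the only parameter-free choice; runs
that do not reach the target within `max_steps` (default 10^4) are
censored and excluded from the mean, with the censored count reported.
Transient estimates average `n_runs = 10` runs with consecutive seeds.

The mean-field reference is logistic growth `dI/dt = C·r·I·(N−I)`, whose
closed-form solution the module exposes together with its continuous
transient time. The conductance *C* absorbs the topology; it is recovered
from simulated curves by least squares (log-spaced grid over `[1e-6, 1]`,
100 points, then bounded local refinement). On complete graphs the fit
agrees with an independent brute-force Monte-Carlo oracle
(`tests/oracle_si_reference.py`) to well within 25%.

The proposition that transient times scale linearly with subgraph size,
`tau(M) ≈ (#M/#G)·tau(G)`, conflicts with the logistic solution itself
(there `tau ~ ln N / (C r N)`), so the package only *reports* the ratio
`tau(M)·#G / (tau(G)·#M)` as a diagnostic and never asserts it.

## Motif census

Connected *k*-node induced subgraphs (`k` in {3, 4, 5}, default 4) are
enumerated exhaustively with the ESU tree scheme: a subgraph grows from
its lowest-ordered root by adding only *exclusive* neighbours with higher
node order, which visits every occurrence exactly once. Enumeration is
validated against brute-force subset enumeration in the test suite.

Isomorphism classes are identified by the lexicographically smallest
upper-triangular adjacency bit-string over all k! relabellings. Exhaustive
permutation was chosen over partition-refinement canonisation because
k ≤ 5 keeps k! ≤ 120 and the whole table (2^10 masks at k = 5) is
precomputed once; the code stays auditable. There are 2 / 6 / 21 connected
classes at k = 3 / 4 / 5.

Three frequency variants are computed: the per-class share of all
occurrences (joint, F1-style); the per-class count of a maximal set of
pairwise non-overlapping occurrences divided by the *joint* total
(disjoint, F2/F3-style); and the scalar share of occurrences surviving the
disjointness filter. Overlap means a shared edge (default) or a shared
node. The independent set is greedy: occurrences are shuffled with a
recorded seed and kept unless they overlap an already-kept occurrence,
yielding a maximal set. Per class, a census's disjoint count never exceeds
its joint count; the edge-disjoint total never falls below the
node-disjoint total under a common shuffle seed. Because the two
selections are independent runs of the heuristic, *per-class* counts may
cross between policies — only the totals are ordered.

## Samplers

Eleven fixed-size samplers, all deterministic given a seed, all operating
on the host's largest connected component:

| family | methods | notes |
|---|---|---|
| node-based | RN, DEGREE, PRN | draw *n* nodes without replacement (uniform / degree-proportional / PageRank-proportional, damping 0.85), return the induced subgraph |
| edge-based | RE | uniform edges accumulated until the endpoint set reaches *n*; returns the sampled edges themselves (not induced), so the node count may overshoot by one |
| exploration | SB, CSE, SP | snowball BFS keeping at most k = 10 random unvisited neighbours per node; community-structure expansion adds the boundary node reaching the most unknown nodes (ties uniform); shortest-path sampling accumulates BFS paths between uniform node pairs |
| random walks | RW, MHRW, RWJ, NBRW | distinct visited nodes counted toward *n*; induced subgraph returned; MHRW accepts a proposed move u→v with min(1, deg(u)/deg(v)) (uniform stationary distribution); RWJ teleports with p = 0.1; NBRW never revisits the previous node except at degree-1 dead ends |

Design points the method names leave open, fixed here:

* Walk samplers count *distinct visited nodes*, not steps; Metropolis
  rejections add no node but count against a stall guard (1000·#V steps
  without a new node aborts the walk and restarts from a fresh uniform
  seed on the same RNG stream, at most 10 times).
* SB's branching cap can permanently strand nodes, so if its queue drains
  early the BFS re-seeds at a uniform unvisited node.
* SP as a bare "paths between uniform pairs" procedure can produce a
  disconnected union of paths. Because a connected sample is a stated
  contract of the exploration family, a drawn path that does not touch the
  already-collected set is redrawn, and surplus nodes of the final path
  are truncated inward from the ends not attached to the collected set.
  This preserves both the uniform-pair flavour and connectivity.

## Regression protocol

Transient-time prediction uses gradient-boosted regression trees
(LightGBM) with 100 boosting iterations and otherwise library defaults,
scored by R² on 5 seeded shuffle splits with a 30% test fraction, the five
scores averaged. One model is fitted per (method, sample size, frequency
variant) cell; features are the per-class frequency vector plus the
disjoint-total scalar, and the target is the host's mean `tau`. A linear
baseline is available behind the `model="linear"` switch. Note that the
default minimum leaf size of boosted trees (20 rows) bounds the resolution
of any fit; cells need on the order of a few hundred rows before a strong
signal saturates the score.

## Synthetic corpus

The generator emulates monthly discussion networks of topic communities:
per topic, 11 graphs with a target node count (jittered ±10% per month),
density, global clustering and degree assortativity. The bundled six
topics span the observed ranges of those statistics in public discussion
data: very sparse and nearly clustering-free (counterstrike), strongly
disassortative (freedonuts, −0.38), and relatively dense/clustered
(stopsmoking, clustering 0.05).

Construction is three-phase, each phase controlling one statistic:

1. **Density.** A degree-heterogeneous random graph with power-law-like
   expected degrees (exponent 2.5) and *exactly* the implied edge count
   `m = round(density·n(n−1)/2)`.
2. **Clustering.** Edge-count-preserving rewiring toward the target global
   clustering from either side: closing a wedge at a random node (raise)
   or scattering an edge to a random non-adjacent pair (lower), with
   incremental triangle/triple bookkeeping; moves must strictly reduce the
   gap.
3. **Assortativity.** Degree-preserving double-edge swaps; of the two
   rewiring orientations the one moving the endpoint-degree product sum
   closest to target is taken, and swaps that would push clustering below
   its tolerance band are rejected. Since disassortative rewiring erodes
   triangles, phases 2 and 3 alternate (up to 4 rounds) until both are in
   band.

Tolerances: density 20% relative (met exactly by construction), clustering
the larger of ±0.01 and 50% relative (sparse graphs have very few
triangles, so small absolute slack is unavoidable), assortativity ±0.07.
A graph outside tolerance raises a generation error reporting the achieved
statistics; corpus generation records such failures in the manifest
without aborting.

These graphs emulate the *aggregate statistics* of real discussion
networks, not their mechanism: there are no timestamps, no shared users
across months, no reply semantics, and the degree heterogeneity is a
generic power law. Passing tests on this corpus therefore demonstrate that
the pipeline's machinery is correct and internally consistent — they do
not establish which sampler is best on real social data, and the method
ranking obtained on the synthetic corpus can legitimately differ from
rankings on real corpora.

## Problem sizes and determinism

Default pipeline settings: motif size k = 4, edge-disjoint policy, size
grid 10–50 step 10, 3 sample replicates per cell, SI rate r = 0.3 with 10
runs per host. The bundled corpus (66 graphs of roughly 150–550-node
largest components) runs end-to-end in a few minutes on one CPU; the
dominating cost is the exhaustive k = 4 census of the hosts. All stage
seeds derive from a single master seed via CRC-32 of stage tokens, so a
rerun with the same configuration produces a byte-identical JSON report
(LightGBM is pinned to single-threaded deterministic mode).

## Known limitations

* Exhaustive enumeration scales with the number of connected k-subgraphs
  (hub-dominated for heavy-tailed graphs: a degree-d hub alone contributes
  C(d,3) stars at k = 4); hosts beyond ~10^4 nodes call for sampling-based
  census variants, which are out of scope.
* The greedy independent set is a heuristic; its size varies a few percent
  across shuffle seeds (bounded in tests), and the recorded seed is part
  of the census for that reason.
* Whole-graph statistics of disconnected hosts are computed on the whole
  graph, while sampling and diffusion operate on the largest component;
  for very sparse graphs the component's local statistics can differ from
  the whole-graph targets.
* `theta = 1` makes `tau` the full-activation time, which is sensitive to
  the last few stragglers on chain-like peripheries; the logistic
  reference diverges there, so conductance fits use the whole curve, not
  the tail.
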