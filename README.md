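# netblocks

**netblocks** finds small "building-block" subgraphs of a network that
preserve both its *topology* (motif composition) and its *dynamics* (the
speed of epidemic spread), and ranks subgraph-sampling techniques by how
well their samples do so. It is aimed at researchers studying diffusion on
social and communication networks who want a subgraph small enough to
inspect — tens of nodes — yet still representative of the host graph's
behaviour.

## The two criteria

For a host graph *G* and an *n*-node sample *M ⊂ G*:

* **Topological.** Both graphs get a motif census: every connected
  *k*-node induced subgraph (k ∈ {3,4,5}, default 4), enumerated
  exhaustively with the ESU scheme and grouped into isomorphism classes,
  with joint (overlapping) and disjoint (greedy maximal-independent-set)
  frequency variants. The deviation is

  δ(M, G) = Σ_c ( mdist(G)_c − mdist(M)_c )²,

  the squared distance between the motif frequency vectors.
* **Functional.** Discrete-time SI dynamics (per-edge infection rate *r*,
  synchronous updates) define the transient time τ(G) — the number of
  steps to full activation, averaged over 10 runs. A gradient-boosted
  regression (100 iterations, 5 shuffle splits, 30% test, fold-mean R²)
  predicts τ(G) from the sample's motif features; high R² means the sample
  carries the host's dynamical signature. The mean-field reference is
  logistic growth dI/dt = C·r·I·(N−I) with fitted conductance C(G).

Eleven samplers are compared: uniform / degree-proportional /
PageRank-proportional node sampling, random edge sampling, snowball BFS,
community-structure expansion, shortest-path sampling, and four random
walks (plain, Metropolis-Hastings, with jumps, non-backtracking). Methods
are ranked under both criteria; the recommendation is the first method in
both top lists, at the smallest sample size where both criterion curves
flatten.

## Worked example

```python
import networkx as nx
from netblocks import (SamplerSpec, draw_sample, build_census,
                       FrequencyVariant, SIParams, estimate_transient_time,
                       compute_stats, largest_component,
                       generate_topic_graph, TopicSpec)
from netblocks.evaluation import motif_mse, feature_vector

# a synthetic discussion network: 447 nodes, density 0.0025,
# clustering 0.0086, assortativity -0.0668
spec = TopicSpec("demo", 447, 0.0025, 0.0086, -0.0668)
g = generate_topic_graph(spec, seed=7)
host = largest_component(g)

tau = estimate_transient_time(host, SIParams(r=0.3), n_runs=10, base_seed=0)
sample = draw_sample(host, SamplerSpec(method="NBRW", target_size=30, rng_seed=1))

host_freq = feature_vector(build_census(host, 4, seed=0),
                           FrequencyVariant.JOINT_RATIO)[:-1]
samp_freq = feature_vector(build_census(sample.subgraph, 4, seed=0),
                           FrequencyVariant.JOINT_RATIO)[:-1]
delta = motif_mse(host_freq, samp_freq)
```

This prints (via the obvious `print` statements):

```
generated: 447 nodes, 249 edges, clustering 0.0077, assortativity -0.0805
largest component: 187 nodes
host transient time: 30.1 +/- 5.2 steps (0 censored)
sample: 30 nodes, 32 edges
delta(M, G) = 0.1092 (per-class mean 0.0182)
```

The generated graph meets the requested statistics within tolerance; SI at
r = 0.3 fully activates the 187-node component in ~30 steps; and a 30-node
non-backtracking-walk sample reproduces the host's 4-node motif mix to a
per-class squared deviation of 0.018.

## Command line

```bash
netblocks synth --seed 0 --out corpus/            # bundled 6-topic corpus
netblocks stats corpus/pizza_m00.edges
netblocks sample corpus/pizza_m00.edges --method nbrw --size 30 --out m.edges
netblocks motifs m.edges --k 4 --out census.csv
netblocks simulate corpus/pizza_m00.edges -r 0.3
netblocks pipeline --seed 0 --out run/            # full evaluation
netblocks extract --report run/report.json --out best/
```

`pipeline` writes `report.json` (per-cell δ and R² tables, method
rankings, the recommended method and size, and the full configuration
echo), plus flat CSV tables. All randomness derives from the single master
seed; reruns are byte-identical.

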