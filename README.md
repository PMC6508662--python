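# hiercomm

Hierarchical community structure in weighted graphs via **multi-scale
modularity maximization** — with the statistics needed to trust what it
finds: node stability across scales, ensemble allegiance, permutation-null
consensus, inter-scale reliability, and cross-graph comparison.

## The problem

Community detection by modularity maximization scores a partition
$\{g_i\}$ of a weighted graph $A$ by

$$Q=\sum_{ij}\bigl(A_{ij}-\gamma P_{ij}\bigr)\,\delta(g_i,g_j),$$

where $P_{ij}$ is a null expectation and the structural resolution
parameter $\gamma$ sets the topological scale: small $\gamma$ yields few
large communities, large $\gamma$ many small ones.  Sweeping $\gamma$ and
optimizing independently at each value reveals structure at every scale —
but the community labels at different $\gamma$ are unrelated (the
*correspondence problem*), so nothing says whether a community at one
scale is the parent, child, or stranger of a community at another.

`hiercomm` instead couples all scales into one problem.  Duplicates of the
graph, one per $\gamma$ value, are chained into a multilayer network in
which every node is linked to itself in the two neighboring layers with
weight $\tau$, and the joint quality

$$Q=\frac{1}{2\mu}\sum_{ijxy}\Bigl\{\bigl(A_{ij}-\gamma_x
P_{ij}\bigr)\delta_{xy}+\delta_{ij}\,\tau\Bigr\}\,\delta(g_{ix},g_{jy})$$

is maximized once, by a generalized Louvain heuristic.  Community labels
are then meaningful *across* scales: a community that persists over many
layers is a stable feature of the graph's hierarchy, and a community that
branches reveals nesting directly.  A uniform ("geographic" /
constant-Potts) null $P_{ij}=\text{const}$ keeps the scale axis
interpretable — each $\gamma$ corresponds to an edge-weight threshold —
while the Newman–Girvan null $P_{ij}=k_ik_j/2m$ is also available.  Two
extensions reuse the same machinery: a **multiplex** pairing of two graphs
over the same nodes (inter-modality coupling $\kappa$) and a
**multi-slice** chain of time slices (inter-slice coupling $\omega$).

Because the modularity landscape is degenerate, the optimizer is run many
times and the ensemble summarized by allegiance matrices (how often two
nodes share a community; how often a node keeps its community across
adjacent layers).  Entries that do not beat a label-permutation null are
removed, and the surviving allegiance graph is re-partitioned at
$\gamma=1,\ \omega=1$ to give a single **consensus** multi-scale
partition.

## Worked example

The package ships a planted benchmark: 81 nodes, every node inside a triad,
every triad inside a block of 9, every block of 9 inside a block of 27,
with within-block weight decreasing outward and a weight gradient across
sibling blocks so that equal-sized blocks differ in strength.

```python
import numpy as np
from hiercomm import (
    ConsensusConfig, MultiScaleSpec, NullModel, build_multiscale,
    consensus_partition, make_gamma_grid, nested_benchmark,
    null_constant, run_ensemble, scale_plateaus, stability_matrix,
    heterogeneity_pca,
)

graph, planted = nested_benchmark()          # 81 nodes, triads in 9s in 27s
grid = make_gamma_grid(0.0, 12.0, 0.1)       # 121 resolution layers
spec = MultiScaleSpec(
    graph=graph,
    gamma_grid=grid,
    tau=0.05,
    null=NullModel("uniform", constant=null_constant(graph, "min_positive")),
)
supra = build_multiscale(spec)
print(f"{supra.n_node_layers} node-layers over {len(grid)} resolution layers")

ensemble = run_ensemble(supra, n_runs=20, base_seed=0)
result = consensus_partition(
    ensemble, ConsensusConfig(n_runs=20, n_permutations=200, seed=1)
)

for plat in scale_plateaus(result.partition, min_length=5):
    lo, hi = grid[plat["start"]], grid[plat["stop"]]
    sizes = plat["sizes"]
    print(f"gamma {lo:5.2f} - {hi:5.2f}: "
          f"{len(sizes):2d} communities of sizes {sorted(set(sizes))}")

stab = stability_matrix(result.partition)
print("median node stability:", round(float(np.median(stab.values)), 3))
print("components for 95% of stability variance:", heterogeneity_pca(stab))
```

Output (about 15 s on one CPU):

```
9801 node-layers over 121 resolution layers
gamma  0.00 -  0.90:  1 communities of sizes [81]
gamma  1.00 -  2.90:  3 communities of sizes [27]
gamma  3.20 -  5.90:  9 communities of sizes [9]
gamma  6.90 - 12.00: 27 communities of sizes [3]
median node stability: 0.463
components for 95% of stability variance: 2
```

Reading it: the consensus partition holds one whole-graph community at low
resolution, then branches into exactly the three planted 27-blocks, the
nine 9-blocks, and the twenty-seven triads, each on a wide plateau of
$\gamma$ — the full planted hierarchy, with labels linked across scales.
The stability value of a node at a layer is the fraction of layers over
which it keeps that layer's community; the PCA component count summarizes
how heterogeneous those stability profiles are across nodes.

## Command line

```sh
hiercomm synth nested --out bench.tsv --labels-out planted.tsv
hiercomm detect --input bench.tsv --config config.json --runs 100 \
    --seed 0 --out-dir out/
hiercomm compare --allegiance-a out_a/allegiance --allegiance-b out_b/allegiance \
    --out cmap.tsv
```

`detect` writes the ensemble, best partition, allegiance matrices,
stability matrix, community number/size curves, the consensus partition,
and a provenance JSON (config hash + seeds); reruns with the same config
are byte-identical.  `synth null` emits the degree/weight/strength-matched
rewired null, `multiplex` runs the joint two-modality model, and `stats`
recomputes stability summaries from any stored partition.

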