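# Methods

This note records the model, the numerical choices, and the limits of what
the shipped tests demonstrate.

## The coupled quality function

A weighted symmetric graph $A$ (zero diagonal, nonnegative, validated on
construction; asymmetry beyond $10^{-10}$ is an error, smaller asymmetry is
averaged) is duplicated at each value of a strictly increasing resolution
grid $\gamma_1<\dots<\gamma_L$.  Layer $x$ carries the single-layer
modularity coefficients $A_{ij}-\gamma_x P_{ij}$ (off-diagonal only — the
diagonal terms are partition-invariant constants), and each node is coupled
to itself in the two adjacent layers with uniform weight $\tau$.  The joint
quality is

$$Q=\frac{1}{2\mu}\sum_{ijxy}\Bigl\{(A_{ij}-\gamma_x P_{ij})\delta_{xy}
+\delta_{ij}\tau\Bigr\}\delta(g_{ix},g_{jy}),\qquad
\mu=\tfrac12\sum_{jy}K_{jy},$$

with $K_{jy}$ the total (intra-layer plus coupling) strength of node $j$ in
layer $y$.  Coupling is adjacent-only (a chain): the point of the model is
dependence between *neighboring* topological scales, and an all-to-all
variant is deliberately not provided.  The multiplex extension adds a
second graph over the same nodes with its own grid and null, and couples a
node to itself across modalities at matching layers with weight $\kappa$;
the multi-slice extension arranges time slices along a second chain with
coupling $\omega$.  One builder underlies all three, so their decoupling
limits ($\tau=0$, $\kappa=0$, $\omega=0$ → block-diagonal problems whose
optima sum) are structural facts, and are asserted as such in the tests.

### Null models

* **Uniform (geographic / constant Potts):** $P_{ij}=c$ for all pairs.
  The constant can be supplied or derived from the graph: the smallest
  positive weight (natural for sparse count-like matrices, where it is one
  count unit and stable across datasets) or the mean weight — over positive
  entries or over all off-diagonal entries; both means are provided because
  dense similarity matrices admit either reading.  With this null the scale
  axis is interpretable: a community dissolves near $\gamma\approx w/c$
  where $w$ is its internal weight.
* **Newman–Girvan:** $P_{ij}=k_ik_j/2m$ from node strengths, recomputed
  per layer's graph.

Count-like weight matrices with heavy tails should be compressed first
with `log_transform_weights` ($w\mapsto\log(w{+}1)/\max\log(w{+}1)$),
which pins the largest weight at 1 and expands the low-weight range.

### Implicit supra-structure

The node-layer coefficient system $B$ is never materialized densely (for
the shipped benchmark sweep it would be a $19521^2$ matrix).  It is stored
as a sparse part (intra-layer adjacency entries plus all couplings) minus
a factorized null part $S\,\mathrm{diag}(w)\,S^{\mathsf T}$, where each
node-layer carries its null mass (1 for the uniform null, $k_i$ for
Newman–Girvan) in its layer's feature and $w$ folds in $\gamma_x$ and the
null normalization.  The factorization aggregates exactly under community
coarsening ($S\mapsto C^{\mathsf T}S$), which is what lets the Louvain
phase structure run without densification; the excluded diagonal null mass
is carried per super-node as an additive constant.  An element accessor
reproduces the dense coefficients for small problems and tests.

## Optimizer

Generalized Louvain: seeded random-order sweeps of single node-layer
moves, each accepted only if it improves the quality by more than
$10^{-12}$ (guarding against float cycling), with ties between
equally-improving targets broken by the lowest community id, a move to a
fresh singleton community taken only when strictly better than every
existing candidate, then aggregation of communities into super-nodes and
repetition until no level improves.  The inner sweep is a numba kernel;
the visiting order, tie-breaks and acceptance rule are identical to the
reference Python semantics.  Quality is asserted non-decreasing across
every phase and the aggregated problem's quality is asserted equal to the
fine partition's at every level; the recorded quality of a returned
partition is recomputed from its labels.

On problems small enough to enumerate (≤ 8 node-layers), 20 seeded
restarts reach the exhaustively enumerated optimum on the suite's
instances; a seed scan found roughly one random dense instance in twenty
where single-node-move local optima trap all 20 restarts — the known
limitation of move-based heuristics, and the reason ensembles rather than
single runs feed all downstream statistics.

## Statistics

* **Stability.**  The stability of node $i$ at layer $x$ is the number of
  layers on which $i$ holds the community label it holds at $x$, divided
  by $L$.  Layer-spans count all layers with that label, contiguous or
  not.  Per node, the spans of its distinct communities partition the
  layer set — an identity the tests assert.  The *stable-community count*
  at threshold $x\%$ counts distinct communities spanning strictly more
  than $x\%$ of layers; communities in which the node is alone at every
  layer it holds them can be excluded via a flag (both conventions are
  defensible; the default counts them).
* **Heterogeneity.**  The node × layer stability matrix is column-centered
  and its singular spectrum taken; the reported statistic is the smallest
  number of principal components whose cumulative explained variance
  reaches 95% (configurable).  A constant matrix returns 0 with a warning.
* **Allegiance.**  Over an ensemble of optimizations: per layer, the
  fraction of runs placing two nodes in the same community; per node, the
  fraction of runs keeping it in the same community across adjacent
  layers.  Because the multilayer labels are globally meaningful, no
  post-hoc label matching is involved anywhere.

## Consensus and the permutation null

The consensus pipeline is: (i) $n$ seeded optimizations (default 100);
(ii–iii) intra- and inter-layer allegiance; (iv) a label-permutation null —
within every run and layer the node→label assignment is permuted uniformly
(preserving each layer's community-size histogram), allegiance recomputed,
and entries pooled within a layer (permutation makes entries exchangeable,
so the pooled distribution *is* the per-entry null); (v) entries at or
below the null threshold are set to exactly zero; (vi) the surviving
allegiance graph — intra-layer weights = significant intra allegiance,
inter-layer couplings = $\omega\times$ significant inter allegiance — is
partitioned once by the same optimizer at $\gamma=1$, $\omega=1$, with a
Newman–Girvan null per layer.

Significance defaults: $\alpha=0.05$, Bonferroni over the entries tested,
threshold at the $(1-\alpha')$ pooled-null quantile (`method="higher"`),
1000 permutation replicates.  An entry is significant when it strictly
exceeds the threshold, with one deliberate exception: when the observed
allegiance is exactly 1 **and** the null quantile is also 1 — a layer
holding a single whole-graph community — the entry is retained.  A
permutation test has no power there (every relabelling reproduces the
observed value), and discarding perfectly consistent co-assignments would
dissolve the coarsest scale of any hierarchy; the exception also makes the
pipeline idempotent on ensembles of identical partitions.

Inter-layer **reliability** uses the same machinery: a node's $(x,x{+}1)$
edge is reliable when its persistence probability beats the null; reported
per node as the reliable fraction of its $L-1$ edges and per layer pair as
the percentage of reliable nodes.

## Synthetic benchmarks

* **Nested hierarchy** (default): 81 nodes; triads inside 9-blocks inside
  27-blocks; base within-block weights $\{0.45, 0.30, 0.15\}$ from
  innermost outward, background 0.05, additive gradient 0.005 per sibling
  block so equal-sized blocks differ in mean weight.  With the uniform
  null at the smallest positive weight (= background), the transitions sit
  at $\gamma\approx 3$–$3.2$ (27→9), $6$–$6.8$ (9→3) and $9$–$11.6$
  (3→singletons): all four scales fall inside the $\gamma\in[0,12]$ sweep
  with wide pure plateaus, and the gradients keep sibling transitions
  staggered by a few layers.  The generator is deterministic given its
  spec; the seed is reserved for optional jitter.
* **Rewired null:** degree-preserving double-edge swaps randomize a sparse
  topology (a complete graph admits no such swap and keeps its trivial
  topology); the weight multiset is then re-laid sequentially — a random
  edge receives the unassigned weight whose rank matches the edge's
  residual-strength-product rank — and a seeded error-driven pass swaps
  weight pairs whenever that reduces the squared strength error.  Degrees
  and the weight multiset are preserved exactly; strength preservation is
  approximate and *measured* (Pearson $r\approx0.9999$ on the default
  benchmark), never assumed.  Global rank-matching without the sequential
  residual step was tried and rejected: it concentrates the largest
  weights on the strongest nodes, planting a persistent core instead of a
  structureless null.
* **Dynamic benchmark:** slices switching among planted community
  structures at a fast period, with the active structure pair itself
  switching at a slower (nested) period — the test bed for the
  multi-slice model, where low $\omega$ tracks the fast switching and
  high $\omega$ merges slices into the slow-scale structure.

What the generators deliberately do **not** emulate: realistic
streamline-count or coherence weight distributions, spatial embedding, or
measurement noise.  Passing tests therefore certify the machinery —
assembly, optimization, statistics, consensus — on graphs whose ground
truth is known exactly, not performance on any particular empirical data
class.

## Problem sizes and defaults used in shipped runs

The acceptance script and the heaviest tests run the full published sweep
geometry (241 layers, $\tau=0.05$, uniform null at the smallest positive
weight) with 20 seeded optimizations and 200 permutation replicates; the
null-graph comparison uses a coarsened 49-layer grid with 10 runs and 150
replicates.  These are the package's desk-scale study conditions; the
`ConsensusConfig` defaults remain $n=100$ runs and 1000 replicates.
Plateau read-out: a *scale plateau* is a maximal run of at least 5
consecutive layers sharing an identical community-size multiset; the
coarse scale is the lowest-$\gamma$ multi-community layer, the
intermediate scale the next plateau with a different size structure, and
the finest scale the highest-$\gamma$ layer still holding non-singleton
communities.

## Known limitations and edge cases

* The arithmetic grid helper includes the endpoint within a relative slack
  of $10^{-9}\times$step; under this rule the printed protocol
  "$\gamma\in[0.95,1.7]$, step 0.01" yields 76 points, not 75 — an
  inclusive-endpoint convention cannot produce 75 there, and the rule is
  kept consistent rather than special-cased.
* Louvain is a heuristic: rare small instances exist where 20 restarts
  miss the global optimum (see above).  All shipped statistics consume
  ensembles.
* In very clean ensembles the consensus inter-layer edges of perfectly
  persistent singleton tails remain significant, so the consensus
  partition can express the finest scale as triad-labelled tails rather
  than per-layer singletons; the non-singleton scale read-outs are
  unaffected.
* The permutation null conditions on each layer's community-size
  histogram; it tests node identity, not size structure.
* `heterogeneity_pca` on matrices with fewer nodes than layers is limited
  by rank; the component count is capped accordingly.
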