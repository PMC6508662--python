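"""Seeded generators for planted-hierarchy benchmarks and matched nulls.

``nested_benchmark`` builds the three-level weighted hierarchy used
throughout the test suite: every node sits in a small, a medium and a large
nested block, with within-block weight decreasing outward and a
deterministic additive gradient across sibling blocks so that not all
blocks of a given size share the same average weight.  ``rewire_null``
produces the matched null — same weight multiset and degree sequence,
approximately the same strength sequence, but no planted hierarchy.
``dynamic_benchmark`` emits a slice sequence whose community structure
switches at two nested time scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graphs import WeightedGraph

__all__ = [
    "NestedBenchmarkSpec",
    "PlantedLabels",
    "nested_benchmark",
    "rewire_null",
    "dynamic_benchmark",
]


@dataclass(frozen=True)
class NestedBenchmarkSpec:
    """Parameters of the nested planted-hierarchy graph.

    ``level_sizes`` lists block sizes from innermost to outermost; each must
    divide the next and the largest must divide ``n_nodes``.
    ``level_weights`` are the base within-block weights, aligned with
    ``level_sizes`` and strictly decreasing outward; ``gradient`` is the
    additive ramp per sibling block (block index counted globally within a
    level), and pairs sharing no block get ``background_weight``.

    The defaults place the hierarchy's break-up scales well inside a
    resolution sweep γ ∈ [0, 12] against a uniform null whose constant is
    the smallest positive weight (= the background): blocks of 27 dissolve
    around γ ≈ 3, blocks of 9 around γ ≈ 6, triads around γ ≈ 9-11.6, with
    wide pure plateaus between.
    """

    level_sizes: tuple[int, ...] = (3, 9, 27)
    n_nodes: int = 81
    level_weights: tuple[float, ...] = (0.45, 0.30, 0.15)
    gradient: float = 0.005
    background_weight: float = 0.05
    seed: int = 0  # reserved for optional jitter; the ramps are deterministic

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.level_sizes)
        object.__setattr__(self, "level_sizes", sizes)
        object.__setattr__(self, "level_weights", tuple(float(w) for w in self.level_weights))
        if len(sizes) != len(self.level_weights):
            raise ValueError("one base weight per level required")
        if any(s < 1 for s in sizes) or any(b % a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("each level size must divide the next")
        if self.n_nodes % sizes[-1]:
            raise ValueError("n_nodes must be a multiple of the largest block")
        diffs = np.diff(self.level_weights)
        if not np.all(diffs < 0):
            raise ValueError("level weights must strictly decrease outward")
        if self.level_weights[-1] <= self.background_weight:
            raise ValueError("outermost level weight must exceed the background")
        if self.background_weight < 0 or self.gradient < 0:
            raise ValueError("weights and gradient must be nonnegative")


@dataclass(frozen=True)
class PlantedLabels:
    """Ground-truth block assignment per level, innermost first.

    ``levels[ℓ][i]`` is the block id of node ``i`` at level ``ℓ``; blocks
    are perfectly nested (every block at one level lies inside a single
    block of the next level).
    """

    levels: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "levels", tuple(np.asarray(l, dtype=np.int64) for l in self.levels)
        )
        for fine, coarse in zip(self.levels, self.levels[1:]):
            # nestedness: a fine block maps into exactly one coarse block
            for b in np.unique(fine):
                if np.unique(coarse[fine == b]).size != 1:
                    raise ValueError("planted levels are not nested")

    @property
    def n_levels(self) -> int:
        return len(self.levels)


def nested_benchmark(spec: NestedBenchmarkSpec = NestedBenchmarkSpec()) -> tuple[WeightedGraph, PlantedLabels]:
    """Planted nested-hierarchy graph plus its ground-truth level labels.

    The weight between two nodes is the base weight of their deepest shared
    block plus that block's gradient offset; nodes sharing no block get the
    background weight.
    """
    n = spec.n_nodes
    w = np.full((n, n), spec.background_weight)
    nodes = np.arange(n)
    levels = []
    # outermost -> innermost so deeper blocks overwrite shallower ones
    for size, base in zip(spec.level_sizes[::-1], spec.level_weights[::-1]):
        block = nodes // size
        for b in range(n // size):
            members = nodes[block == b]
            w[np.ix_(members, members)] = base + spec.gradient * b
        levels.append(block)
    np.fill_diagonal(w, 0.0)
    labels = PlantedLabels(levels=tuple(levels[::-1]))
    return WeightedGraph(w), labels


def rewire_null(g: WeightedGraph, n_swaps: int | None = None, seed: int = 0,
                n_refine: int | None = None) -> WeightedGraph:
    """Strength-aware rewired null: same weights and degrees, no hierarchy.

    Three seeded stages:

    1. The binary topology is randomized by double-edge swaps (degree
       sequence preserved exactly).  A complete graph admits no
       degree-preserving swap, so its topology is trivially preserved and
       only the weight placement is randomized.
    2. The original edge-weight multiset is reassigned to the edges one at
       a time: a random unassigned edge is drawn and receives the
       still-unassigned weight whose rank matches the rank of the edge's
       residual-strength product, the residuals then being decremented.
       This spreads weight mass without planting block structure while
       tracking the strength sequence.
    3. An error-driven refinement proposes random pairs of assigned edges
       and swaps their weights whenever that reduces the squared strength
       error, tightening strength preservation without systematic
       re-ordering.

    The weight multiset and degree sequence are preserved exactly;
    strength preservation is approximate (its quality is asserted
    empirically in the test suite, not assumed).
    """
    a = g.weights
    n = g.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    mask = a[iu, ju] > 0
    weights = np.sort(a[iu, ju][mask])[::-1].copy()  # descending
    n_edges = weights.size
    if n_edges < 2:
        raise ValueError("need at least 2 edges to rewire")
    rng = np.random.default_rng(seed)
    if n_edges == iu.size:
        edges = np.column_stack([iu, ju])
    else:
        G = nx.Graph()
        G.add_nodes_from(range(n))
        G.add_edges_from(zip(iu[mask].tolist(), ju[mask].tolist()))
        if n_swaps is None:
            n_swaps = 10 * n_edges
        try:
            nx.double_edge_swap(G, nswap=n_swaps, max_tries=100 * n_swaps, seed=seed)
        except nx.NetworkXAlgorithmError:
            pass  # dense graph: keep however many swaps were achieved
        except nx.NetworkXError as exc:
            raise ValueError(f"graph cannot be rewired: {exc}") from exc
        edges = np.array(sorted(tuple(sorted(e)) for e in G.edges()), dtype=np.int64)

    # stage 2: sequential residual rank-matching
    target = g.strengths()
    s_resid = target.copy()
    alive = np.arange(n_edges)
    w_alive = np.ones(n_edges, dtype=bool)
    assigned = np.zeros(n_edges)
    for _ in range(n_edges):
        pos = rng.integers(alive.size)
        pick = alive[pos]
        score = s_resid[edges[alive, 0]] * s_resid[edges[alive, 1]]
        rank = int((score > score[pos]).sum())
        w_idx = np.nonzero(w_alive)[0][rank]
        w = weights[w_idx]
        w_alive[w_idx] = False
        assigned[pick] = w
        s_resid[edges[pick, 0]] -= w
        s_resid[edges[pick, 1]] -= w
        alive = np.delete(alive, pos)

    # stage 3: seeded error-driven weight swaps
    cur = np.zeros(n)
    np.add.at(cur, edges[:, 0], assigned)
    np.add.at(cur, edges[:, 1], assigned)
    err = cur - target
    if n_refine is None:
        n_refine = min(60 * n_edges, 300_000)
    pairs = rng.integers(0, n_edges, size=(n_refine, 2))
    for e1, e2 in pairs:
        w1, w2 = assigned[e1], assigned[e2]
        if w1 == w2:
            continue
        a1, b1 = edges[e1]
        a2, b2 = edges[e2]
        if len({a1, b1, a2, b2}) < 4:
            continue
        d = w2 - w1
        de = (
            (err[a1] + d) ** 2 + (err[b1] + d) ** 2
            + (err[a2] - d) ** 2 + (err[b2] - d) ** 2
            - err[a1] ** 2 - err[b1] ** 2 - err[a2] ** 2 - err[b2] ** 2
        )
        if de < 0:
            assigned[e1], assigned[e2] = w2, w1
            err[a1] += d
            err[b1] += d
            err[a2] -= d
            err[b2] -= d

    new = np.zeros_like(a)
    new[edges[:, 0], edges[:, 1]] = assigned
    new += new.T
    return WeightedGraph(new, node_labels=g.node_labels)


def dynamic_benchmark(
    n_nodes: int,
    fast_states: int = 2,
    slow_states: int = 2,
    periods: tuple[int, int] = (1, 4),
    seed: int = 0,
    n_communities: int = 3,
    within_weight: float = 1.0,
    background_weight: float = 0.1,
) -> tuple[list[WeightedGraph], np.ndarray, list[np.ndarray]]:
    """Two-timescale switching benchmark for the multi-slice extension.

    The slice sequence cycles through ``slow_states`` groups of community
    structures; within the active group the structure alternates among
    ``fast_states`` members every ``periods[0]`` slices, and the active
    group itself advances every ``periods[1]`` slices (the slow period must
    be a multiple of the fast one).  One full slow cycle is emitted:
    ``slow_states * periods[1]`` slices.

    Returns (slices, per-slice state id, per-state planted node labels).
    """
    fast, slow = periods
    if fast < 1 or slow < 1 or slow % fast:
        raise ValueError("slow period must be a positive multiple of the fast period")
    if n_nodes % n_communities:
        raise ValueError("n_nodes must be a multiple of n_communities")
    rng = np.random.default_rng(seed)
    n_states = fast_states * slow_states
    structures = []
    for _ in range(n_states):
        perm = rng.permutation(n_nodes)
        labels = np.empty(n_nodes, dtype=np.int64)
        labels[perm] = np.arange(n_nodes) // (n_nodes // n_communities)
        structures.append(labels)
    n_slices = slow_states * slow
    state_ids = np.empty(n_slices, dtype=np.int64)
    slices = []
    for t in range(n_slices):
        group = (t // slow) % slow_states
        member = (t // fast) % fast_states
        sid = group * fast_states + member
        state_ids[t] = sid
        lab = structures[sid]
        w = np.where(lab[:, None] == lab[None, :], within_weight, background_weight)
        np.fill_diagonal(w, 0.0)
        slices.append(WeightedGraph(w))
    return slices, state_ids, structures
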