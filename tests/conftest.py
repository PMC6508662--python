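"""Shared fixtures: toy graphs, small planted benchmarks, and the
exhaustive set-partition oracle used to certify the Louvain heuristic."""

from __future__ import annotations


import numpy as np
import pytest

from hiercomm import (
    MultiScaleSpec,
    NestedBenchmarkSpec,
    NullModel,
    WeightedGraph,
    build_multiscale,
    nested_benchmark,
)
from hiercomm.louvain import evaluate_quality, louvain_optimize


def exhaustive_optimum(supra) -> tuple[float, np.ndarray]:
    """Global optimum of the quality over all set partitions (Bell-number scan).

    Independent of the Louvain path: enumerates restricted-growth strings
    and scores each labelling through the public quality evaluator.
    """
    n = supra.n_node_layers
    best_q, best_lab = -np.inf, None
    for labels in _set_partitions(n):
        q = evaluate_quality(supra, np.asarray(labels))
        if q > best_q:
            best_q, best_lab = q, np.asarray(labels)
    return best_q, best_lab


def _set_partitions(n: int):
    """All labellings of n items in restricted growth form (canonical)."""
    def rec(prefix, k):
        if len(prefix) == n:
            yield list(prefix)
            return
        for lab in range(k + 1):
            prefix.append(lab)
            yield from rec(prefix, max(k, lab + 1))
            prefix.pop()
    yield from rec([], 0)


def louvain_best(supra, restarts: int = 20):
    best = None
    for s in range(restarts):
        p = louvain_optimize(supra, seed=s)
        if best is None or p.quality > best.quality:
            best = p
    return best


@pytest.fixture(scope="session")
def two_cliques() -> WeightedGraph:
    """Two disjoint unit-weight 3-cliques on 6 nodes."""
    w = np.zeros((6, 6))
    for block in (slice(0, 3), slice(3, 6)):
        w[block, block] = 1.0
    np.fill_diagonal(w, 0.0)
    return WeightedGraph(w)


@pytest.fixture(scope="session")
def two_clique_supra(two_cliques) -> object:
    spec = MultiScaleSpec(
        graph=two_cliques, gamma_grid=[1.0], tau=0.0,
        null=NullModel("uniform", constant=0.5),
    )
    return build_multiscale(spec)


@pytest.fixture(scope="session")
def pair_supra() -> object:
    """2-node graph (weight 1), uniform null 0.5, grid {1, 2}, τ = 0.3.

    The fully hand-enumerable worked example: layer-0 off-diagonal
    coefficient 0.5, layer-1 coefficient 0.0, four τ couplings of 0.3, and
    2μ = 5.2.
    """
    g = WeightedGraph(np.array([[0.0, 1.0], [1.0, 0.0]]))
    spec = MultiScaleSpec(
        graph=g, gamma_grid=[1.0, 2.0], tau=0.3,
        null=NullModel("uniform", constant=0.5),
    )
    return build_multiscale(spec)


@pytest.fixture(scope="session")
def small_benchmark():
    """Two-level nested benchmark on 8 nodes (blocks of 2 inside blocks of 4)."""
    spec = NestedBenchmarkSpec(
        level_sizes=(2, 4), n_nodes=8, level_weights=(0.6, 0.3),
        gradient=0.01, background_weight=0.05,
    )
    return nested_benchmark(spec)


def random_graph(n: int, seed: int, density: float = 1.0) -> WeightedGraph:
    rng = np.random.default_rng(seed)
    w = rng.random((n, n))
    if density < 1.0:
        w[rng.random((n, n)) > density] = 0.0
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return WeightedGraph(w)
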