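"""Node-level stability across scales, community curves, and allegiance.

Because the multi-scale model links a node to itself across neighboring
resolution layers, community labels are globally meaningful across layers
and a node's *stability* in a community is simply the fraction of layers
it spends there — no post-hoc label matching is involved.  The stability
matrix replaces each (node, layer) label by that fraction; its principal
components measure how topologically heterogeneous the graph is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .louvain import MultiScalePartition, PartitionEnsemble

__all__ = [
    "StabilityMatrix",
    "AllegianceSet",
    "stability_matrix",
    "community_spans",
    "count_stable_communities",
    "community_size_curves",
    "layer_community_sizes",
    "scale_plateaus",
    "allegiance",
    "heterogeneity_pca",
]


@dataclass(frozen=True)
class StabilityMatrix:
    """Node × layer fractions of layer-span of the community held there.

    ``values[i, x] = (# layers where node i holds the community it holds at
    layer x) / n_layers`` — so every value lies in {1/L, ..., 1} and, per
    node, summing each distinct community's value once gives exactly 1.
    """

    values: np.ndarray
    partition: MultiScalePartition = field(compare=False)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_layers(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class AllegianceSet:
    """Ensemble co-classification fractions.

    ``intra[x, i, j]`` — fraction of optimizations placing nodes i and j in
    the same community at layer x (diagonal 1, symmetric).
    ``inter[i, x]`` — fraction of optimizations keeping node i in the same
    community across layers x and x+1.
    """

    intra: np.ndarray
    inter: np.ndarray

    @property
    def n_layers(self) -> int:
        return self.intra.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.intra.shape[1]


def _require_single_slice(p: MultiScalePartition) -> np.ndarray:
    if p.labels.ndim != 2:
        raise ValueError(
            "statistics are defined per slice/modality; use "
            "partition.select_slice(s) first"
        )
    return p.labels


def community_spans(p: MultiScalePartition) -> list[dict[int, int]]:
    """Per node: mapping community label -> number of layers holding it."""
    labels = _require_single_slice(p)
    out = []
    for row in labels:
        uniq, counts = np.unique(row, return_counts=True)
        out.append(dict(zip(uniq.tolist(), counts.tolist())))
    return out


def stability_matrix(p: MultiScalePartition) -> StabilityMatrix:
    """Replace each (node, layer) label by its layer-span fraction."""
    labels = _require_single_slice(p)
    n, L = labels.shape
    values = np.empty((n, L))
    for i, row in enumerate(labels):
        uniq, inv, counts = np.unique(row, return_inverse=True, return_counts=True)
        values[i] = counts[inv] / L
    return StabilityMatrix(values=values, partition=p)


def _singleton_only(labels: np.ndarray, i: int, comm: int) -> bool:
    """True if community `comm` is a singleton at every layer where node i holds it."""
    layers = np.nonzero(labels[i] == comm)[0]
    sizes = (labels[:, layers] == comm).sum(axis=0)
    return bool(np.all(sizes == 1))


def count_stable_communities(
    s: StabilityMatrix, threshold_pct: float, include_singletons: bool = True
) -> np.ndarray:
    """Per node, how many distinct communities span > threshold_pct% of layers.

    A *stable* community for a node is one whose layer-span exceeds the
    given percentage of the scale range; the count is monotone
    non-increasing in the threshold.  ``include_singletons=False`` skips
    communities in which the node is alone at every layer it holds them
    (both conventions are plausible readings of stable-community counting,
    so both are exposed).
    """
    if not 0 <= threshold_pct <= 100:
        raise ValueError("threshold_pct must lie in [0, 100]")
    labels = _require_single_slice(s.partition)
    L = labels.shape[1]
    cut = threshold_pct / 100.0 * L
    counts = np.zeros(labels.shape[0], dtype=np.int64)
    for i, row in enumerate(labels):
        uniq, span = np.unique(row, return_counts=True)
        for comm, sp_ in zip(uniq, span):
            if sp_ <= cut:
                continue
            if not include_singletons and _singleton_only(labels, i, int(comm)):
                continue
            counts[i] += 1
    return counts


def community_size_curves(p: MultiScalePartition) -> pd.DataFrame:
    """Per layer: number of non-singleton communities and their mean size (% of N).

    Layers consisting purely of singletons report (0, 0).
    """
    labels = _require_single_slice(p)
    n, L = labels.shape
    rows = []
    for x in range(L):
        _, sizes = np.unique(labels[:, x], return_counts=True)
        big = sizes[sizes >= 2]
        rows.append(
            {
                "layer": x,
                "n_nonsingleton": int(big.size),
                "mean_size_pct": float(big.mean() / n * 100.0) if big.size else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("layer")


def layer_community_sizes(p: MultiScalePartition) -> list[tuple[int, ...]]:
    """Per layer, the sorted (descending) multiset of community sizes."""
    labels = _require_single_slice(p)
    out = []
    for x in range(labels.shape[1]):
        _, sizes = np.unique(labels[:, x], return_counts=True)
        out.append(tuple(sorted(sizes.tolist(), reverse=True)))
    return out


def scale_plateaus(
    p: MultiScalePartition, min_length: int = 5
) -> list[dict]:
    """Maximal runs of layers sharing an identical community-size multiset.

    A *plateau* is a stretch of at least ``min_length`` consecutive layers
    over which the partition's size structure does not change; the recovered
    hierarchy of a graph reads off as the ordered sequence of plateau size
    multisets.  Returns dicts with ``start``, ``stop`` (inclusive) and
    ``sizes``.
    """
    states = layer_community_sizes(p)
    plateaus = []
    start = 0
    for x in range(1, len(states) + 1):
        if x == len(states) or states[x] != states[start]:
            if x - start >= min_length:
                plateaus.append(
                    {"start": start, "stop": x - 1, "sizes": states[start]}
                )
            start = x
    return plateaus


def allegiance(e: PartitionEnsemble, slice_: int | None = None) -> AllegianceSet:
    """Intra-/inter-layer co-classification fractions over an ensemble."""
    runs = e.runs
    if runs[0].labels.ndim == 3:
        if slice_ is None:
            raise ValueError("multi-slice ensemble: pass slice_ to pick a modality/slice")
        labels = np.stack([r.labels[:, :, slice_] for r in runs])
    else:
        labels = np.stack([r.labels for r in runs])
    n_runs, n, L = labels.shape
    intra = np.empty((L, n, n))
    for x in range(L):
        lab = labels[:, :, x]
        intra[x] = (lab[:, :, None] == lab[:, None, :]).mean(axis=0)
    inter = (labels[:, :, :-1] == labels[:, :, 1:]).mean(axis=0) if L > 1 else np.zeros((n, 0))
    return AllegianceSet(intra=intra, inter=inter)


def heterogeneity_pca(s: StabilityMatrix, variance_pct: float = 95.0) -> int:
    """Principal components needed to reach ``variance_pct`` of stability variance.

    Columns (layers) are centered and the covariance spectrum taken from
    squared singular values; a larger count means more diverse per-node
    stability profiles, i.e. greater topological heterogeneity.  A
    constant matrix has no variance to explain and returns 0 with a
    warning.
    """
    if s.n_layers < 2:
        raise ValueError("need at least 2 layers for a stability PCA")
    x = s.values - s.values.mean(axis=0, keepdims=True)
    sv = np.linalg.svd(x, compute_uv=False)
    total = float((sv**2).sum())
    if total <= 1e-24:
        warnings.warn("stability matrix is constant; zero components explain it")
        return 0
    explained = np.cumsum(sv**2) / total * 100.0
    k = int(np.searchsorted(explained, variance_pct - 1e-12) + 1)
    return min(k, sv.size)
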