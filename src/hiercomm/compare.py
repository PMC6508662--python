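"""Cross-graph allegiance correlation, spatial contiguity statistics, and
multi-scale node ordering.

The allegiance-correlation map aligns the resolution chains of two graphs
(e.g. two connectivity modalities) by correlating their per-layer
allegiance matrices over all layer pairs; reading its diagonals is
equivalent to shifting one chain against the other.  The multi-cluster
statistic counts communities whose members are spatially disconnected on a
caller-supplied neighbor graph, against a label-permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage, optimal_leaf_ordering
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist

from .graphs import WeightedGraph
from .louvain import MultiScalePartition
from .stability import AllegianceSet

__all__ = [
    "CorrelationMap",
    "allegiance_correlation_map",
    "multi_cluster_count",
    "leaf_order_nodes",
]


@dataclass(frozen=True)
class CorrelationMap:
    """Layer × layer Pearson correlations between two allegiance sets.

    ``values[x, y]`` correlates the upper triangles of the two intra-layer
    allegiance matrices; undefined pairs (zero-variance layers) are NaN and
    excluded from ``best_alignment = (layer_a, layer_b, r)``.
    """

    values: np.ndarray
    best_alignment: tuple[int, int, float] | None

    def shifted_diagonal(self, shift: int) -> np.ndarray:
        """Correlations of layer x in A against layer x+shift in B."""
        return np.diagonal(self.values, offset=shift)


def allegiance_correlation_map(a: AllegianceSet, b: AllegianceSet) -> CorrelationMap:
    """Pearson r between allegiance upper triangles for every layer pair."""
    if a.n_nodes != b.n_nodes:
        raise ValueError("allegiance sets cover different node sets")
    n = a.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    xa = a.intra[:, iu, ju]
    xb = b.intra[:, iu, ju]

    def _standardize(x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (x - mu) / sd
        z[sd.ravel() == 0] = np.nan
        return z

    za, zb = _standardize(xa), _standardize(xb)
    values = za @ zb.T / iu.size
    if np.all(np.isnan(values)):
        best = None
    else:
        flat = int(np.nanargmax(values))
        la, lb = divmod(flat, values.shape[1])
        best = (la, lb, float(values[la, lb]))
    return CorrelationMap(values=values, best_alignment=best)


def multi_cluster_count(
    layer_partition: np.ndarray,
    neighbor_graph: WeightedGraph,
    n_permutations: int = 1000,
    seed: int = 0,
) -> tuple[int, np.ndarray, float]:
    """Spatially disconnected communities at one layer, with permutation null.

    A non-singleton community is *multi-cluster* when its members form more
    than one connected component of the (binary) neighbor graph.  The null
    permutes node labels uniformly; the one-sided p-value is the fraction
    of null counts ≤ the observed count (testing for *fewer* disconnected
    communities than chance, i.e. spatial contiguity).
    """
    labels = np.asarray(layer_partition, dtype=np.int64).ravel()
    if labels.size != neighbor_graph.n_nodes:
        raise ValueError("partition and neighbor graph cover different node sets")
    adj = csr_matrix(neighbor_graph.weights > 0)

    def _count(lab: np.ndarray) -> int:
        count = 0
        for comm in np.unique(lab):
            members = np.nonzero(lab == comm)[0]
            if members.size < 2:
                continue
            sub = adj[np.ix_(members, members)]
            n_comp, _ = connected_components(sub, directed=False)
            if n_comp > 1:
                count += 1
        return count

    observed = _count(labels)
    rng = np.random.default_rng(seed)
    null = np.array(
        [_count(labels[rng.permutation(labels.size)]) for _ in range(n_permutations)]
    )
    p_value = float((null <= observed).mean())
    return observed, null, p_value


def leaf_order_nodes(p: MultiScalePartition) -> np.ndarray:
    """Node permutation grouping similar cross-scale assignment profiles.

    Pairwise distance is the normalized Hamming distance between label
    vectors across layers; average-linkage hierarchical clustering with
    optimal leaf ordering yields an ordering in which nodes sharing
    communities over many scales sit next to each other (used to sort
    adjacency and allegiance matrices for display).
    """
    labels = p.labels if p.labels.ndim == 2 else p.labels.reshape(p.n_nodes, -1)
    n = labels.shape[0]
    if n < 3:
        return np.arange(n)
    dist = pdist(labels, metric="hamming")
    z = linkage(dist, method="average")
    z = optimal_leaf_ordering(z, dist)
    return leaves_list(z)
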