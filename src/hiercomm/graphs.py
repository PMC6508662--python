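"""Weighted-graph data model, weight transforms, and null-model constants.

A :class:`WeightedGraph` holds a symmetric, nonnegative, zero-diagonal weight
matrix over labelled nodes — the single-layer adjacency ``A`` that every
modularity quality function in this package consumes.  Two null models are
supported: the Newman–Girvan expectation ``P_ij = k_i k_j / 2m`` built from
node strengths, and the uniform ("geographic" / constant-Potts) expectation
``P_ij = const`` for all node pairs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WeightedGraph",
    "NullModel",
    "log_transform_weights",
    "null_constant",
    "read_dense_matrix",
    "write_dense_matrix",
    "read_edge_list",
    "write_edge_list",
]

#: absolute tolerance within which asymmetric input is averaged instead of rejected
SYMMETRY_ATOL = 1e-10


@dataclass(frozen=True)
class WeightedGraph:
    """Symmetric nonnegative weighted graph with an explicitly zero diagonal.

    Parameters
    ----------
    weights
        ``(n, n)`` array of edge weights.  Must be symmetric (within
        ``symmetry_atol``, in which case it is averaged), nonnegative,
        finite, and have a zero diagonal.  Self-loops are rejected, not
        silently dropped.
    node_labels
        Optional node names; defaults to stringified indices.
    """

    weights: np.ndarray
    node_labels: tuple[str, ...] | None = None
    symmetry_atol: float = field(default=SYMMETRY_ATOL, compare=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be a square matrix, got shape {w.shape}")
        if w.shape[0] < 1:
            raise ValueError("graph must have at least one node")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights contain non-finite entries")
        asym = np.abs(w - w.T).max() if w.size else 0.0
        if asym > self.symmetry_atol:
            raise ValueError(
                f"weight matrix is asymmetric (max |A - A.T| = {asym:g} "
                f"> tolerance {self.symmetry_atol:g})"
            )
        w = (w + w.T) / 2.0
        if np.any(np.diag(w) != 0):
            raise ValueError("self-loops are not allowed (diagonal must be zero)")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        object.__setattr__(self, "weights", w)
        if self.node_labels is not None:
            labels = tuple(str(x) for x in self.node_labels)
            if len(labels) != w.shape[0]:
                raise ValueError(
                    f"{len(labels)} node labels for {w.shape[0]} nodes"
                )
            object.__setattr__(self, "node_labels", labels)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def labels_or_default(self) -> tuple[str, ...]:
        if self.node_labels is not None:
            return self.node_labels
        return tuple(f"n{i}" for i in range(self.n_nodes))

    def strengths(self) -> np.ndarray:
        """Node strengths ``k_i = sum_j A_ij``."""
        return self.weights.sum(axis=1)

    def total_weight(self) -> float:
        """``m = (1/2) sum_ij A_ij``."""
        return float(self.weights.sum()) / 2.0


@dataclass(frozen=True)
class NullModel:
    """Expected-weight model ``P`` entering ``A - γP``.

    ``kind="newman_girvan"`` uses ``P_ij = k_i k_j / (2m)`` derived from the
    graph it is applied to; ``kind="uniform"`` uses a constant expected
    weight for every off-diagonal pair (the geographic / constant Potts
    null), with the constant supplied explicitly or derived via
    :func:`null_constant`.
    """

    kind: Literal["newman_girvan", "uniform"]
    constant: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("newman_girvan", "uniform"):
            raise ValueError(f"unknown null model kind: {self.kind!r}")
        if self.kind == "uniform":
            if self.constant is None or not self.constant > 0:
                raise ValueError("uniform null requires a positive constant")
        elif self.constant is not None:
            raise ValueError("newman_girvan null takes no constant")

    def expected_matrix(self, g: WeightedGraph) -> np.ndarray:
        """Dense ``P`` with zero diagonal (the diagonal never enters Q)."""
        if self.kind == "uniform":
            p = np.full((g.n_nodes, g.n_nodes), float(self.constant))
        else:
            k = g.strengths()
            two_m = k.sum()
            if two_m == 0:
                p = np.zeros((g.n_nodes, g.n_nodes))
            else:
                p = np.outer(k, k) / two_m
        np.fill_diagonal(p, 0.0)
        return p


def log_transform_weights(g: WeightedGraph) -> WeightedGraph:
    """Compress a heavy-tailed weight distribution onto [0, 1].

    Each weight ``w`` becomes ``log(w + 1) / max(log(w + 1))``, the standard
    transform for streamline-count matrices: it expands the discriminability
    of small weights while pinning the largest weight to exactly 1.  Zeros
    stay zero and symmetry is preserved.
    """
    w = g.weights
    if not np.any(w > 0):
        raise ValueError("log transform undefined for an all-zero graph")
    logw = np.log1p(w)
    out = logw / logw.max()
    return WeightedGraph(out, node_labels=g.node_labels)


def null_constant(
    g: WeightedGraph,
    mode: Literal["min_positive", "mean_nonzero", "mean_all"],
) -> float:
    """Derive the uniform-null constant from a graph's off-diagonal weights.

    ``min_positive`` — smallest positive weight (the natural choice for
    sparse count-like matrices, where it is e.g. one streamline and hence
    comparable across subjects); ``mean_nonzero`` — mean of positive
    weights; ``mean_all`` — mean over all off-diagonal entries including
    zeros (the natural choice for dense coherence-like matrices).
    """
    n = g.n_nodes
    if n < 2:
        raise ValueError("null constant undefined for a single-node graph")
    off = g.weights[~np.eye(n, dtype=bool)]
    pos = off[off > 0]
    if mode == "min_positive":
        if pos.size == 0:
            raise ValueError("no positive weights; min_positive undefined")
        return float(pos.min())
    if mode == "mean_nonzero":
        if pos.size == 0:
            raise ValueError("no positive weights; mean_nonzero undefined")
        return float(pos.mean())
    if mode == "mean_all":
        return float(off.mean())
    raise ValueError(f"unknown null-constant mode: {mode!r}")


# ---------------------------------------------------------------------------
# readers / writers


def write_dense_matrix(
    g: WeightedGraph, path: str | Path, sep: str = "\t", header: bool = True
) -> None:
    """Write the weight matrix as delimited text, optionally with a label header."""
    df = pd.DataFrame(g.weights, columns=g.labels_or_default)
    df.to_csv(path, sep=sep, index=False, header=header)


def read_dense_matrix(
    path: str | Path, sep: str = "\t", header: bool | None = None
) -> WeightedGraph:
    """Read a dense weight matrix written by :func:`write_dense_matrix`.

    ``header=None`` autodetects a label row (any non-numeric token in the
    first line).  Malformed rows raise with the offending location named.
    """
    text = Path(path).read_text()
    first = text.splitlines()[0] if text.splitlines() else ""
    if header is None:
        tokens = first.split(sep)
        header = False
        for tok in tokens:
            try:
                float(tok)
            except ValueError:
                header = True
                break
    try:
        df = pd.read_csv(io.StringIO(text), sep=sep, header=0 if header else None,
                         float_precision="round_trip")
        mat = df.to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"malformed matrix file {path}: {exc}") from exc
    labels = tuple(map(str, df.columns)) if header else None
    return WeightedGraph(mat, node_labels=labels)


def write_edge_list(g: WeightedGraph, path: str | Path, sep: str = "\t") -> None:
    """Write positive upper-triangle edges as (node_a, node_b, weight) rows."""
    labels = g.labels_or_default
    iu, ju = np.triu_indices(g.n_nodes, k=1)
    mask = g.weights[iu, ju] > 0
    rows = [
        (labels[i], labels[j], g.weights[i, j])
        for i, j in zip(iu[mask], ju[mask])
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "weight"]).to_csv(
        path, sep=sep, index=False
    )


def read_edge_list(
    path: str | Path,
    sep: str = "\t",
    node_labels: Sequence[str] | None = None,
) -> WeightedGraph:
    """Read a 3-column weighted edge list into a :class:`WeightedGraph`.

    Node set defaults to the labels seen in the file, in order of first
    appearance; supply ``node_labels`` to fix the node set (e.g. to keep
    isolated nodes).
    """
    df = pd.read_csv(path, sep=sep, dtype={0: str, 1: str},
                     float_precision="round_trip")
    if df.shape[1] != 3:
        raise ValueError(f"edge list {path} must have 3 columns, got {df.shape[1]}")
    a, b, w = df.columns
    if node_labels is None:
        seen: dict[str, int] = {}
        for name in pd.concat([df[a], df[b]]):
            seen.setdefault(str(name), len(seen))
        labels = list(seen)
    else:
        labels = [str(x) for x in node_labels]
    index = {name: i for i, name in enumerate(labels)}
    mat = np.zeros((len(labels), len(labels)))
    for row_no, (na, nb, wt) in enumerate(zip(df[a], df[b], df[w]), start=2):
        try:
            i, j = index[str(na)], index[str(nb)]
        except KeyError as exc:
            raise ValueError(f"edge list {path} row {row_no}: unknown node {exc}")
        mat[i, j] = mat[j, i] = float(wt)
    return WeightedGraph(mat, node_labels=tuple(labels))
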