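"""Assembly of the multi-scale (multilayer) modularity coefficient structure.

The multi-scale quality function couples duplicates of one graph across a
chain of resolution layers: layer ``x`` carries the single-layer modularity
coefficients ``A_ij - γ_x P_ij`` and each node is linked to itself in the
two adjacent layers with weight ``τ``::

    Q = (1/2μ) Σ_{ijxy} { (A_ij - γ_x P_ij) δ_xy + δ_ij τ_jxy } δ(g_ix, g_jy)

with ``μ`` half the total node-layer strength (intra-layer strength plus
coupling strength).  Two extensions share the same machinery: a *multiplex*
pairing of two graphs over the same nodes, with an extra coupling ``κ``
between a node and itself across modalities at matching scale layers, and a
*multi-slice* chain of time slices with inter-slice coupling ``ω``.

The supra-coefficient system ``B((i,x),(j,y))`` is never materialised
densely.  It is stored as a sparse part (intra-layer adjacency entries plus
all couplings) minus a factorised null part ``S·diag(w)·Sᵀ``, where row
``p`` of ``S`` carries the node's null "mass" (1 for the uniform null, the
node strength for Newman–Girvan) in the feature of its layer and ``w``
folds in ``γ_x`` and the null normalisation.  The factorisation aggregates
exactly under community coarsening, which is what makes a Louvain phase
structure possible without a dense matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .graphs import NullModel, WeightedGraph, null_constant

__all__ = [
    "make_gamma_grid",
    "MultiScaleSpec",
    "MultiplexSpec",
    "MultiSliceMultiScaleSpec",
    "SupraModularity",
    "build_multiscale",
    "build_multiplex",
    "build_multislice_multiscale",
    "spec_from_config",
    "config_from_spec",
]


def make_gamma_grid(start: float, stop: float, step: float) -> np.ndarray:
    """Arithmetic resolution grid ``start, start+step, ...`` up to ``stop``.

    The endpoint test uses a relative slack of ``step * 1e-9`` so that
    binary-float grids (e.g. step 0.0133) keep their intended point count.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if start > stop:
        raise ValueError("start must not exceed stop")
    n = int(np.floor((stop - start) / step + 1e-9)) + 1
    grid = start + step * np.arange(n)
    return grid


def _check_grid(grid: Sequence[float]) -> np.ndarray:
    g = np.asarray(grid, dtype=float)
    if g.ndim != 1 or g.size < 1:
        raise ValueError("gamma grid must be a non-empty 1-D sequence")
    if g.size > 1 and not np.all(np.diff(g) > 0):
        raise ValueError("gamma grid must be strictly increasing")
    return g


@dataclass(frozen=True)
class MultiScaleSpec:
    """One graph, a γ chain, uniform inter-layer coupling τ, and a null model."""

    graph: WeightedGraph
    gamma_grid: Sequence[float]
    tau: float
    null: NullModel

    def __post_init__(self) -> None:
        object.__setattr__(self, "gamma_grid", _check_grid(self.gamma_grid))
        if self.tau < 0:
            raise ValueError("tau must be nonnegative")

    @property
    def n_layers(self) -> int:
        return len(self.gamma_grid)


@dataclass(frozen=True)
class MultiplexSpec:
    """Two graphs over the same node set, γ chains of equal length, τ and κ."""

    graph_a: WeightedGraph
    graph_b: WeightedGraph
    gamma_grid_a: Sequence[float]
    gamma_grid_b: Sequence[float]
    tau: float
    kappa: float
    null_a: NullModel
    null_b: NullModel

    def __post_init__(self) -> None:
        object.__setattr__(self, "gamma_grid_a", _check_grid(self.gamma_grid_a))
        object.__setattr__(self, "gamma_grid_b", _check_grid(self.gamma_grid_b))
        if self.graph_a.n_nodes != self.graph_b.n_nodes:
            raise ValueError("multiplex graphs must share the node set")
        if len(self.gamma_grid_a) != len(self.gamma_grid_b):
            raise ValueError("per-modality gamma grids must have equal length")
        if self.tau < 0 or self.kappa < 0:
            raise ValueError("tau and kappa must be nonnegative")

    @property
    def n_layers(self) -> int:
        return len(self.gamma_grid_a)


@dataclass(frozen=True)
class MultiSliceMultiScaleSpec:
    """Ordered time slices, each expanded along a shared γ chain.

    ``omega`` couples a node to itself in adjacent slices at the same scale
    layer; ``tau`` couples a node to itself in adjacent scale layers within
    a slice.  The null model is evaluated per slice.
    """

    slices: Sequence[WeightedGraph]
    gamma_grid: Sequence[float]
    tau: float
    omega: float
    nulls: Sequence[NullModel]

    def __post_init__(self) -> None:
        object.__setattr__(self, "gamma_grid", _check_grid(self.gamma_grid))
        object.__setattr__(self, "slices", tuple(self.slices))
        object.__setattr__(self, "nulls", tuple(self.nulls))
        if len(self.slices) < 1:
            raise ValueError("need at least one slice")
        n = self.slices[0].n_nodes
        if any(g.n_nodes != n for g in self.slices):
            raise ValueError("all slices must share the node set")
        if len(self.nulls) != len(self.slices):
            raise ValueError("one null model per slice required")
        if self.tau < 0 or self.omega < 0:
            raise ValueError("tau and omega must be nonnegative")

    @property
    def n_layers(self) -> int:
        return len(self.gamma_grid)


@dataclass(frozen=True)
class SupraModularity:
    """Implicit node-layer × node-layer coefficient system of the quality function.

    ``B(p, q) = adj[p, q] - Σ_f w_f S[p, f] S[q, f]`` for ``p ≠ q`` and 0 on
    the diagonal; ``adj`` holds intra-layer adjacency entries and all
    couplings (τ, κ, ω), so ``μ = adj.sum() / 2`` is exactly half the total
    node-layer strength of the quality function.

    Flat node-layer indexing is ``(x * n_slices + s) * n_nodes + i`` for
    node ``i``, slice/modality ``s``, scale layer ``x``.
    """

    adj: sp.csr_matrix
    null_s: sp.csr_matrix
    null_w: np.ndarray
    n_nodes: int
    n_layers: int
    n_slices: int = 1
    slice_axis: str = "layer"  # "modality" for multiplex, "slice" for multi-slice
    gammas: np.ndarray = field(default=None, compare=False)  # type: ignore[assignment]

    @property
    def n_node_layers(self) -> int:
        return self.n_nodes * self.n_layers * self.n_slices

    @property
    def mu(self) -> float:
        return float(self.adj.sum()) / 2.0

    def flat_index(self, node: int, layer: int, slice_: int = 0) -> int:
        if not (0 <= node < self.n_nodes and 0 <= layer < self.n_layers
                and 0 <= slice_ < self.n_slices):
            raise IndexError("node/layer/slice out of range")
        return (layer * self.n_slices + slice_) * self.n_nodes + node

    def unflatten(self, p: int) -> tuple[int, int, int]:
        """Inverse of :meth:`flat_index`: returns (node, layer, slice)."""
        node = p % self.n_nodes
        rest = p // self.n_nodes
        return node, rest // self.n_slices, rest % self.n_slices

    def coefficient(self, p: int, q: int) -> float:
        """``B(p, q)`` as if the dense supra-matrix existed."""
        if p == q:
            return 0.0
        val = self.adj[p, q]
        sp_row = self.null_s.getrow(p)
        sq_row = self.null_s.getrow(q)
        null = float((sp_row.multiply(sq_row)).multiply(self.null_w).sum())
        return float(val) - null

    def dense(self) -> np.ndarray:
        """Dense ``B`` for small problems (tests and worked examples)."""
        n = self.n_node_layers
        if n > 4000:
            raise ValueError("refusing to densify a large supra structure")
        s = self.null_s.toarray()
        b = self.adj.toarray() - (s * self.null_w) @ s.T
        np.fill_diagonal(b, 0.0)
        return b

    def self_null(self) -> np.ndarray:
        """Per node-layer excluded diagonal null mass ``Σ_f w_f S[p,f]²``."""
        s2 = self.null_s.multiply(self.null_s)
        return np.asarray(s2 @ self.null_w).ravel()


def _null_feature(graph: WeightedGraph, null: NullModel) -> tuple[np.ndarray, float]:
    """Per-node null mass ``s_i`` and scale ``w0`` with ``P_ij = w0 s_i s_j``."""
    if null.kind == "uniform":
        return np.ones(graph.n_nodes), float(null.constant)
    k = graph.strengths()
    two_m = k.sum()
    if two_m == 0:
        return np.zeros(graph.n_nodes), 0.0
    return k, 1.0 / two_m


def _chain_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (x, x+1) of an adjacent-only chain."""
    idx = np.arange(n - 1)
    return idx, idx + 1


def _assemble(
    n_nodes: int,
    n_layers: int,
    n_slices: int,
    cells: list[tuple[int, int, sp.coo_matrix, float, np.ndarray, float]],
    couplings: list[tuple[np.ndarray, np.ndarray, float | np.ndarray]],
    slice_axis: str,
    gammas: np.ndarray,
) -> SupraModularity:
    """Shared builder.

    ``cells`` — one entry per (layer x, slice s): the sparse intra-cell
    adjacency, γ, the per-node null mass vector and its scale.
    ``couplings`` — (flat rows, flat cols, weight) one-directional pairs;
    symmetrised here.
    """
    nl = n_nodes * n_layers * n_slices
    rows, cols, vals = [], [], []
    s_rows, s_cols, s_vals = [], [], []
    w = np.zeros(len(cells))
    for f, (x, s, a_coo, gamma, mass, scale) in enumerate(cells):
        off = (x * n_slices + s) * n_nodes
        rows.append(a_coo.row + off)
        cols.append(a_coo.col + off)
        vals.append(a_coo.data)
        node_idx = np.arange(n_nodes) + off
        s_rows.append(node_idx)
        s_cols.append(np.full(n_nodes, f))
        s_vals.append(mass)
        w[f] = gamma * scale
    for r, c, weight in couplings:
        weight = np.broadcast_to(np.asarray(weight, dtype=float), r.shape)
        keep = weight != 0
        rows.extend([r[keep], c[keep]])
        cols.extend([c[keep], r[keep]])
        vals.extend([weight[keep], weight[keep]])
    adj = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(nl, nl),
    )
    adj.sum_duplicates()
    null_s = sp.csr_matrix(
        (np.concatenate(s_vals), (np.concatenate(s_rows), np.concatenate(s_cols))),
        shape=(nl, len(cells)),
    )
    return SupraModularity(
        adj=adj,
        null_s=null_s,
        null_w=w,
        n_nodes=n_nodes,
        n_layers=n_layers,
        n_slices=n_slices,
        slice_axis=slice_axis,
        gammas=gammas,
    )


def build_multiscale(spec: MultiScaleSpec) -> SupraModularity:
    """Supra coefficients for one graph along its γ chain (adjacent-only τ)."""
    g, grid = spec.graph, np.asarray(spec.gamma_grid)
    n, n_lay = g.n_nodes, len(grid)
    a_coo = sp.coo_matrix(g.weights)
    mass, scale = _null_feature(g, spec.null)
    cells = [(x, 0, a_coo, grid[x], mass, scale) for x in range(n_lay)]
    lo, hi = _chain_pairs(n_lay)
    node = np.arange(n)
    r = (lo[:, None] * n + node[None, :]).ravel()
    c = (hi[:, None] * n + node[None, :]).ravel()
    couplings = [(r, c, spec.tau)] if n_lay > 1 else []
    return _assemble(n, n_lay, 1, cells, couplings, "layer", grid)


def build_multiplex(spec: MultiplexSpec) -> SupraModularity:
    """Two τ-coupled γ chains, κ-linked across modalities at matching layers."""
    n = spec.graph_a.n_nodes
    n_lay = spec.n_layers
    cells = []
    for s, (graph, grid, null) in enumerate(
        [(spec.graph_a, spec.gamma_grid_a, spec.null_a),
         (spec.graph_b, spec.gamma_grid_b, spec.null_b)]
    ):
        a_coo = sp.coo_matrix(graph.weights)
        mass, scale = _null_feature(graph, null)
        for x in range(n_lay):
            cells.append((x, s, a_coo, np.asarray(grid)[x], mass, scale))
    node = np.arange(n)
    couplings = []
    if n_lay > 1 and spec.tau != 0:
        lo, hi = _chain_pairs(n_lay)
        for s in range(2):
            r = ((lo[:, None] * 2 + s) * n + node[None, :]).ravel()
            c = ((hi[:, None] * 2 + s) * n + node[None, :]).ravel()
            couplings.append((r, c, spec.tau))
    if spec.kappa != 0:
        x = np.arange(n_lay)
        r = ((x[:, None] * 2 + 0) * n + node[None, :]).ravel()
        c = ((x[:, None] * 2 + 1) * n + node[None, :]).ravel()
        couplings.append((r, c, spec.kappa))
    gammas = np.stack([np.asarray(spec.gamma_grid_a), np.asarray(spec.gamma_grid_b)])
    return _assemble(n, n_lay, 2, cells, couplings, "modality", gammas)


def build_multislice_multiscale(spec: MultiSliceMultiScaleSpec) -> SupraModularity:
    """Time-slice chain × γ chain: ω across slices, τ across scales."""
    n = spec.slices[0].n_nodes
    n_lay, n_sl = spec.n_layers, len(spec.slices)
    grid = np.asarray(spec.gamma_grid)
    cells = []
    for s, (graph, null) in enumerate(zip(spec.slices, spec.nulls)):
        a_coo = sp.coo_matrix(graph.weights)
        mass, scale = _null_feature(graph, null)
        for x in range(n_lay):
            cells.append((x, s, a_coo, grid[x], mass, scale))
    node = np.arange(n)
    couplings = []
    if n_sl > 1 and spec.omega != 0:
        lo, hi = _chain_pairs(n_sl)
        x = np.arange(n_lay)
        r = ((x[:, None, None] * n_sl + lo[None, :, None]) * n + node).ravel()
        c = ((x[:, None, None] * n_sl + hi[None, :, None]) * n + node).ravel()
        couplings.append((r, c, spec.omega))
    if n_lay > 1 and spec.tau != 0:
        lo, hi = _chain_pairs(n_lay)
        s = np.arange(n_sl)
        r = ((lo[:, None, None] * n_sl + s[None, :, None]) * n + node).ravel()
        c = ((hi[:, None, None] * n_sl + s[None, :, None]) * n + node).ravel()
        couplings.append((r, c, spec.tau))
    return _assemble(n, n_lay, n_sl, cells, couplings, "slice", grid)


# ---------------------------------------------------------------------------
# JSON config round-trip


def config_from_spec(spec: MultiScaleSpec | MultiplexSpec | MultiSliceMultiScaleSpec,
                     null_mode: str | None = None) -> dict:
    """Serialisable config block for a spec (grid assumed arithmetic)."""
    def _grid_block(grid: np.ndarray) -> dict:
        grid = np.asarray(grid)
        step = float(grid[1] - grid[0]) if grid.size > 1 else 1.0
        return {"start": float(grid[0]), "stop": float(grid[-1]), "step": step}

    def _null_block(null: NullModel) -> dict:
        block: dict = {"kind": null.kind}
        if null.kind == "uniform":
            if null_mode is not None:
                block["mode"] = null_mode
            else:
                block["constant"] = null.constant
        return block

    if isinstance(spec, MultiScaleSpec):
        return {"gamma": _grid_block(spec.gamma_grid), "tau": spec.tau,
                "null": _null_block(spec.null)}
    if isinstance(spec, MultiplexSpec):
        return {
            "gamma": _grid_block(spec.gamma_grid_a),
            "gamma_b": _grid_block(spec.gamma_grid_b),
            "tau": spec.tau,
            "kappa": spec.kappa,
            "null": _null_block(spec.null_a),
            "null_b": _null_block(spec.null_b),
        }
    return {"gamma": _grid_block(spec.gamma_grid), "tau": spec.tau,
            "omega": spec.omega, "null": _null_block(spec.nulls[0])}


def _null_from_block(block: dict, graph: WeightedGraph) -> NullModel:
    kind = block.get("kind", "uniform")
    if kind == "newman_girvan":
        return NullModel("newman_girvan")
    if "constant" in block:
        return NullModel("uniform", constant=float(block["constant"]))
    mode = block.get("mode", "min_positive")
    return NullModel("uniform", constant=null_constant(graph, mode))


def spec_from_config(graph: WeightedGraph, config: dict,
                     graph_b: WeightedGraph | None = None
                     ) -> MultiScaleSpec | MultiplexSpec:
    """Build a spec from ``{gamma: {start, stop, step}, tau, null, kappa?}``.

    With ``graph_b`` (and optionally ``kappa``/``gamma_b``/``null_b`` keys)
    a :class:`MultiplexSpec` is produced; otherwise a :class:`MultiScaleSpec`.
    """
    gb = config["gamma"]
    grid = make_gamma_grid(gb["start"], gb["stop"], gb["step"])
    tau = float(config.get("tau", 0.0))
    if graph_b is None:
        return MultiScaleSpec(
            graph=graph, gamma_grid=grid, tau=tau,
            null=_null_from_block(config.get("null", {}), graph),
        )
    gb2 = config.get("gamma_b", gb)
    grid_b = make_gamma_grid(gb2["start"], gb2["stop"], gb2["step"])
    return MultiplexSpec(
        graph_a=graph, graph_b=graph_b,
        gamma_grid_a=grid, gamma_grid_b=grid_b,
        tau=tau, kappa=float(config.get("kappa", 0.0)),
        null_a=_null_from_block(config.get("null", {}), graph),
        null_b=_null_from_block(config.get("null_b", config.get("null", {})), graph_b),
    )
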