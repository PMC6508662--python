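"""Permutation-null significance of allegiance and the consensus partition.

The representative partition of an ensemble is obtained by (i) many seeded
optimizations, (ii) intra-layer and (iii) inter-layer allegiance, (iv) a
label-permutation null for both, (v) removal of non-significant allegiance
edges, and (vi) one multilayer optimization of the surviving allegiance
graph at γ = 1, ω = 1.  The permutation null shuffles node→community
assignments independently within every (run, layer), preserving each
layer's community-size histogram while destroying node identity.

Significance rule: an entry is significant when the observed allegiance
strictly exceeds the (1 − α') pooled-null quantile for its layer, with
α' = α (no correction) or α / #entries (Bonferroni).  Entries at the
ceiling (observed allegiance exactly 1) are retained when the null
quantile is itself 1: in a layer holding a single whole-graph community
the permutation test has no power (any relabelling reproduces the
observed value), and discarding perfectly consistent co-assignments there
would dissolve the coarsest scale of the hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .louvain import (
    MultiScalePartition,
    PartitionEnsemble,
    louvain_optimize,
)
from .multiscale import SupraModularity, _assemble
from .stability import AllegianceSet, allegiance

__all__ = [
    "ConsensusConfig",
    "AllegianceNull",
    "ConsensusResult",
    "allegiance_null",
    "consensus_partition",
    "interlayer_reliability",
]


@dataclass(frozen=True)
class ConsensusConfig:
    """Knobs of the consensus procedure.

    ``n_runs`` optimizations feed the allegiance matrices;
    ``n_permutations`` label-permutation replicates build the null;
    ``alpha`` with ``correction`` sets the significance level, and the
    consensus graph is optimized at ``consensus_gamma``/``consensus_omega``
    (both 1 by default).  All randomness flows from ``seed``.
    """

    n_runs: int = 100
    n_permutations: int = 1000
    alpha: float = 0.05
    correction: str = "bonferroni"  # or "none"
    consensus_gamma: float = 1.0
    consensus_omega: float = 1.0
    seed: int = 0
    max_stored_null: int = 5000  # per-layer cap on retained null samples

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("need at least 100 permutation replicates")
        if self.correction not in ("none", "bonferroni"):
            raise ValueError(f"unknown correction {self.correction!r}")


@dataclass(frozen=True)
class AllegianceNull:
    """Empirical permutation-null of the allegiance statistics.

    ``intra_threshold[x]`` / ``inter_threshold[x]`` are the (1 − α')
    quantiles of permuted allegiance entries pooled within layer x (pair
    x, x+1 for inter); ``intra_dist`` / ``inter_dist`` retain a seeded
    subsample of each pooled distribution for inspection.
    """

    intra_threshold: np.ndarray
    inter_threshold: np.ndarray
    intra_dist: tuple[np.ndarray, ...]
    inter_dist: tuple[np.ndarray, ...]
    quantile_level: float


@dataclass(frozen=True)
class ConsensusResult:
    """Thresholded allegiance, the consensus partition, and reliability ratios."""

    sig_intra: np.ndarray  # (L, N, N); non-significant entries exactly 0
    sig_inter: np.ndarray  # (N, L-1)
    partition: MultiScalePartition
    reliability_ratio: np.ndarray  # per node: reliable inter-layer edges / (L-1)
    reliable_pct_per_pair: np.ndarray  # per layer pair: % of nodes reliable
    null: AllegianceNull = field(compare=False)
    config: ConsensusConfig = field(compare=False)


def _ensemble_layer_labels(e: PartitionEnsemble) -> np.ndarray:
    labels = e.labels_array()
    if labels.ndim == 4:
        raise ValueError("consensus operates per slice; select a slice first")
    return labels  # (runs, nodes, layers)


def _quantile_level(cfg: ConsensusConfig, n_entries: int) -> float:
    alpha = cfg.alpha / n_entries if cfg.correction == "bonferroni" else cfg.alpha
    return 1.0 - alpha


def allegiance_null(e: PartitionEnsemble, cfg: ConsensusConfig) -> AllegianceNull:
    """Label-permutation null distributions of intra- and inter-layer allegiance.

    For every replicate the node→label assignment of each (run, layer) is
    permuted uniformly (community sizes preserved) and the allegiance
    recomputed; entries are pooled within a layer, which is exact for the
    per-entry null because permutation makes entries exchangeable.
    """
    labels = _ensemble_layer_labels(e)
    n_runs, n, L = labels.shape
    rng = np.random.default_rng(cfg.seed)
    iu, ju = np.triu_indices(n, k=1)
    lvl_intra = _quantile_level(cfg, L * iu.size)
    lvl_inter = _quantile_level(cfg, n * max(L - 1, 1))
    perm_base = np.tile(np.arange(n), (n_runs, 1))

    intra_thr = np.empty(L)
    intra_dist = []
    for x in range(L):
        lab = labels[:, :, x]
        samples = np.empty((cfg.n_permutations, iu.size))
        for rep in range(cfg.n_permutations):
            perms = rng.permuted(perm_base, axis=1)
            pl = np.take_along_axis(lab, perms, axis=1)
            co = (pl[:, :, None] == pl[:, None, :]).mean(axis=0)
            samples[rep] = co[iu, ju]
        pool = samples.ravel()
        intra_thr[x] = np.quantile(pool, lvl_intra, method="higher")
        keep = min(cfg.max_stored_null, pool.size)
        intra_dist.append(rng.choice(pool, size=keep, replace=False))

    inter_thr = np.empty(max(L - 1, 0))
    inter_dist = []
    for x in range(L - 1):
        lab0, lab1 = labels[:, :, x], labels[:, :, x + 1]
        samples = np.empty((cfg.n_permutations, n))
        for rep in range(cfg.n_permutations):
            p0 = np.take_along_axis(lab0, rng.permuted(perm_base, axis=1), axis=1)
            p1 = np.take_along_axis(lab1, rng.permuted(perm_base, axis=1), axis=1)
            samples[rep] = (p0 == p1).mean(axis=0)
        pool = samples.ravel()
        inter_thr[x] = np.quantile(pool, lvl_inter, method="higher")
        keep = min(cfg.max_stored_null, pool.size)
        inter_dist.append(rng.choice(pool, size=keep, replace=False))

    return AllegianceNull(
        intra_threshold=intra_thr,
        inter_threshold=inter_thr,
        intra_dist=tuple(intra_dist),
        inter_dist=tuple(inter_dist),
        quantile_level=lvl_intra,
    )


def _significant(observed: np.ndarray, threshold: float) -> np.ndarray:
    sig = observed > threshold
    if threshold >= 1.0:  # degenerate null at the ceiling: keep perfect consistency
        sig |= observed >= 1.0
    return sig


def _consensus_supra(
    sig_intra: np.ndarray,
    sig_inter: np.ndarray,
    gamma: float,
    omega: float,
) -> SupraModularity:
    """Multilayer structure over the significant allegiance graph.

    Intra-layer coefficients use the Newman–Girvan null of each layer's
    surviving allegiance matrix; inter-layer coupling between a node and
    itself in adjacent layers is ω times its surviving inter allegiance.
    """
    L, n, _ = sig_intra.shape
    cells = []
    for x in range(L):
        a = sig_intra[x]
        k = a.sum(axis=1)
        two_m = k.sum()
        if two_m > 0:
            mass, scale = k, 1.0 / two_m
        else:
            mass, scale = np.zeros(n), 0.0
        cells.append((x, 0, sp.coo_matrix(a), gamma, mass, scale))
    couplings = []
    if L > 1:
        node = np.arange(n)
        x = np.arange(L - 1)
        r = (x[:, None] * n + node[None, :]).ravel()
        c = ((x[:, None] + 1) * n + node[None, :]).ravel()
        w = omega * sig_inter.T.ravel()
        couplings.append((r, c, w))
    return _assemble(n, L, 1, cells, couplings, "layer", np.full(L, gamma))


def consensus_partition(e: PartitionEnsemble, cfg: ConsensusConfig) -> ConsensusResult:
    """Steps (ii)-(vi): allegiance, permutation null, thresholding, re-optimization."""
    if e.n_runs < 2:
        raise ValueError("consensus needs an ensemble of at least 2 runs")
    labels = _ensemble_layer_labels(e)
    _, n, L = labels.shape
    obs = allegiance(e)
    null = allegiance_null(e, cfg)

    sig_intra = np.zeros_like(obs.intra)
    for x in range(L):
        mask = _significant(obs.intra[x], null.intra_threshold[x])
        np.fill_diagonal(mask, False)
        sig_intra[x][mask] = obs.intra[x][mask]
    sig_inter = np.zeros_like(obs.inter)
    for x in range(L - 1):
        mask = _significant(obs.inter[:, x], null.inter_threshold[x])
        sig_inter[mask, x] = obs.inter[mask, x]

    supra = _consensus_supra(sig_intra, sig_inter, cfg.consensus_gamma, cfg.consensus_omega)
    part = louvain_optimize(supra, cfg.seed + 1)

    reliable = sig_inter > 0
    ratio = reliable.sum(axis=1) / max(L - 1, 1)
    pct_per_pair = reliable.mean(axis=0) * 100.0 if L > 1 else np.zeros(0)
    return ConsensusResult(
        sig_intra=sig_intra,
        sig_inter=sig_inter,
        partition=part,
        reliability_ratio=ratio,
        reliable_pct_per_pair=pct_per_pair,
        null=null,
        config=cfg,
    )


def interlayer_reliability(
    e: PartitionEnsemble, cfg: ConsensusConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reliable inter-layer persistence per node against the permutation null.

    Returns (flags, ratio, pct_per_pair): ``flags[i, x]`` marks a reliable
    (x, x+1) edge for node i, ``ratio[i]`` is the node's reliable fraction
    of its L-1 inter-layer edges, and ``pct_per_pair[x]`` the percentage of
    nodes with a reliable edge at that layer pair (the summary curve).
    """
    labels = _ensemble_layer_labels(e)
    _, n, L = labels.shape
    if L < 2:
        raise ValueError("need at least 2 layers for inter-layer reliability")
    obs = allegiance(e)
    null = allegiance_null(e, cfg)
    flags = np.zeros((n, L - 1), dtype=bool)
    for x in range(L - 1):
        flags[:, x] = _significant(obs.inter[:, x], null.inter_threshold[x])
    ratio = flags.sum(axis=1) / (L - 1)
    pct_per_pair = flags.mean(axis=0) * 100.0
    return flags, ratio, pct_per_pair
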