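"""Artifact serialization: partitions, ensembles, allegiance, provenance.

Every artifact carries the hash of the run configuration that produced it,
so a downstream command can re-validate that two artifacts belong to the
same run.  All formats are plain text (TSV + JSON sidecars).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .louvain import MultiScalePartition, PartitionEnsemble
from .stability import AllegianceSet

__all__ = [
    "config_hash",
    "write_partition",
    "read_partition",
    "write_ensemble",
    "read_ensemble",
    "write_allegiance",
    "read_allegiance",
]


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _partition_frame(p: MultiScalePartition) -> pd.DataFrame:
    if p.labels.ndim == 2:
        node, layer = np.meshgrid(
            np.arange(p.n_nodes), np.arange(p.n_layers), indexing="ij"
        )
        return pd.DataFrame(
            {"node": node.ravel(), "layer": layer.ravel(),
             "community": p.labels.ravel()}
        )
    node, layer, sl = np.meshgrid(
        np.arange(p.n_nodes), np.arange(p.n_layers), np.arange(p.n_slices),
        indexing="ij",
    )
    return pd.DataFrame(
        {"node": node.ravel(), "layer": layer.ravel(), "slice": sl.ravel(),
         "community": p.labels.ravel()}
    )


def write_partition(path: str | Path, p: MultiScalePartition, config: dict | None = None) -> None:
    """Partition TSV (node, layer[, slice], community) + JSON sidecar."""
    path = Path(path)
    _partition_frame(p).to_csv(path, sep="\t", index=False)
    meta = {"quality": p.quality, "seed": p.seed}
    if config is not None:
        meta["config_hash"] = config_hash(config)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_partition(path: str | Path, expect_config: dict | None = None) -> MultiScalePartition:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = {}
    side = path.with_suffix(".json")
    if side.exists():
        meta = json.loads(side.read_text())
    if expect_config is not None:
        got = meta.get("config_hash")
        want = config_hash(expect_config)
        if got != want:
            raise ValueError(f"artifact {path} built from config {got}, expected {want}")
    n = int(df["node"].max()) + 1
    L = int(df["layer"].max()) + 1
    if "slice" in df.columns:
        s = int(df["slice"].max()) + 1
        labels = np.empty((n, L, s), dtype=np.int64)
        labels[df["node"], df["layer"], df["slice"]] = df["community"]
    else:
        labels = np.empty((n, L), dtype=np.int64)
        labels[df["node"], df["layer"]] = df["community"]
    return MultiScalePartition(
        labels=labels, quality=float(meta.get("quality", np.nan)),
        seed=meta.get("seed"),
    )


def write_ensemble(path: str | Path, e: PartitionEnsemble, config: dict | None = None) -> None:
    """All runs in one TSV with a leading ``run`` column + JSON sidecar."""
    path = Path(path)
    frames = []
    for r, part in enumerate(e.runs):
        df = _partition_frame(part)
        df.insert(0, "run", r)
        frames.append(df)
    pd.concat(frames).to_csv(path, sep="\t", index=False)
    meta = {
        "seeds": list(e.seeds),
        "qualities": [p.quality for p in e.runs],
    }
    if config is not None:
        meta["config_hash"] = config_hash(config)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_ensemble(path: str | Path, expect_config: dict | None = None) -> PartitionEnsemble:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = {}
    side = path.with_suffix(".json")
    if side.exists():
        meta = json.loads(side.read_text())
    if expect_config is not None and meta.get("config_hash") != config_hash(expect_config):
        raise ValueError(f"artifact {path} does not match the expected configuration")
    runs = []
    seeds = meta.get("seeds")
    qualities = meta.get("qualities", [])
    run_ids = sorted(df["run"].unique())
    for r in run_ids:
        sub = df[df["run"] == r]
        n = int(sub["node"].max()) + 1
        L = int(sub["layer"].max()) + 1
        labels = np.empty((n, L), dtype=np.int64)
        labels[sub["node"], sub["layer"]] = sub["community"]
        q = qualities[r] if r < len(qualities) else np.nan
        runs.append(MultiScalePartition(labels=labels, quality=float(q)))
    if seeds is None:
        seeds = list(range(len(runs)))
    return PartitionEnsemble(runs=tuple(runs), seeds=tuple(seeds), supra=None)


def write_allegiance(prefix: str | Path, a: AllegianceSet, config: dict | None = None) -> None:
    """Intra allegiance as one long TSV, inter as node × pair TSV, + JSON header."""
    prefix = Path(prefix)
    L, n, _ = a.intra.shape
    iu, ju = np.triu_indices(n, k=1)
    rows = []
    for x in range(L):
        vals = a.intra[x, iu, ju]
        rows.append(pd.DataFrame({"layer": x, "node_a": iu, "node_b": ju, "allegiance": vals}))
    pd.concat(rows).to_csv(prefix.with_suffix(".intra.tsv"), sep="\t", index=False)
    pd.DataFrame(
        a.inter, columns=[f"pair_{x}" for x in range(a.inter.shape[1])]
    ).to_csv(prefix.with_suffix(".inter.tsv"), sep="\t", index=False)
    meta = {"n_nodes": n, "n_layers": L}
    if config is not None:
        meta["config_hash"] = config_hash(config)
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_allegiance(prefix: str | Path, expect_config: dict | None = None) -> AllegianceSet:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    if expect_config is not None and meta.get("config_hash") != config_hash(expect_config):
        raise ValueError(f"artifact {prefix} does not match the expected configuration")
    n, L = meta["n_nodes"], meta["n_layers"]
    intra = np.zeros((L, n, n))
    df = pd.read_csv(prefix.with_suffix(".intra.tsv"), sep="\t")
    intra[df["layer"], df["node_a"], df["node_b"]] = df["allegiance"]
    intra += np.transpose(intra, (0, 2, 1))
    for x in range(L):
        np.fill_diagonal(intra[x], 1.0)
    inter_df = pd.read_csv(prefix.with_suffix(".inter.tsv"), sep="\t")
    inter = inter_df.to_numpy(dtype=float) if inter_df.shape[1] else np.zeros((n, 0))
    if inter.size == 0:
        inter = np.zeros((n, 0))
    return AllegianceSet(intra=intra, inter=inter)
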