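"""File formats: TCK tractograms, fixel tables, weight files, connectomes.

TCK reading/writing goes through nibabel's MRtrix track-file support;
streamline weights and delta coefficients follow the single-line
whitespace-separated convention of MRtrix weight files.  Fixel tables,
node tables and ground-truth connectomes are plain TSV/CSV via pandas.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .connectome import Connectome, NodeSet
from .grid import FixelSet, Tractogram, VoxelGrid
from .phantom import PhantomConfig, PhantomPair

__all__ = [
    "read_tck", "write_tck",
    "read_fixels_tsv", "write_fixels_tsv",
    "read_weights", "write_weights",
    "read_connectome_csv", "write_connectome_csv",
    "write_nodes_tsv", "read_nodes_tsv",
    "write_ground_truth_csv",
    "read_config", "write_config",
]


def write_tck(tractogram: Tractogram, path: str | Path) -> None:
    nib_tract = nib.streamlines.Tractogram(
        [np.asarray(s, dtype=np.float32) for s in tractogram.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    nib.streamlines.save(nib_tract, str(path))


def read_tck(path: str | Path) -> Tractogram:
    tck = nib.streamlines.load(str(path))
    return Tractogram(streamlines=[np.asarray(s, dtype=np.float64)
                                   for s in tck.streamlines])


_FIXEL_COLUMNS = ["fixel_id", "i", "j", "k", "dx", "dy", "dz", "w"]


def write_fixels_tsv(fixels: FixelSet, path: str | Path,
                     fd_columns: tuple[str, ...] = ("fd_tp1", "fd_tp2")) -> None:
    if len(fd_columns) != fixels.n_sessions:
        raise ValueError("one fd column name per session is required")
    df = pd.DataFrame({
        "fixel_id": np.arange(fixels.n_fixels),
        "i": fixels.voxels[:, 0], "j": fixels.voxels[:, 1], "k": fixels.voxels[:, 2],
        "dx": fixels.directions[:, 0], "dy": fixels.directions[:, 1],
        "dz": fixels.directions[:, 2],
        "w": fixels.weights,
    })
    for s, name in enumerate(fd_columns):
        df[name] = fixels.fd[:, s]
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_fixels_tsv(path: str | Path, grid: VoxelGrid,
                    fd_columns: tuple[str, ...] | None = None,
                    max_per_voxel: int = 3) -> FixelSet:
    df = pd.read_csv(path, sep="\t")
    if fd_columns is None:
        fd_columns = tuple(c for c in df.columns if c.startswith("fd"))
    fd = df[list(fd_columns)].to_numpy(dtype=float)
    return FixelSet(
        grid=grid,
        voxels=df[["i", "j", "k"]].to_numpy(dtype=np.int64),
        directions=df[["dx", "dy", "dz"]].to_numpy(dtype=float),
        weights=df["w"].to_numpy(dtype=float),
        fd=fd,
        max_per_voxel=max_per_voxel,
    )


def write_weights(values: np.ndarray, path: str | Path) -> None:
    """Single line of whitespace-separated decimals, tractogram order."""
    with open(path, "w") as fh:
        fh.write(" ".join(f"{v:.12g}" for v in np.asarray(values).ravel()))
        fh.write("\n")


def read_weights(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, ndmin=1)


def write_connectome_csv(connectome: Connectome, path: str | Path) -> None:
    df = pd.DataFrame(connectome.matrix, index=connectome.labels,
                      columns=connectome.labels)
    df.to_csv(path, float_format="%.10g")


def read_connectome_csv(path: str | Path, metric: str = "FBC") -> Connectome:
    df = pd.read_csv(path, index_col=0)
    return Connectome(labels=tuple(df.index), matrix=df.to_numpy(dtype=float),
                      metric=metric)


def write_nodes_tsv(nodes: NodeSet, path: str | Path) -> None:
    df = pd.DataFrame({
        "node_id": np.arange(nodes.n_nodes),
        "label": list(nodes.labels),
        "x": nodes.centres[:, 0], "y": nodes.centres[:, 1], "z": nodes.centres[:, 2],
        "radius": nodes.radii,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_nodes_tsv(path: str | Path) -> NodeSet:
    df = pd.read_csv(path, sep="\t")
    return NodeSet(centres=df[["x", "y", "z"]].to_numpy(dtype=float),
                   radii=df["radius"].to_numpy(dtype=float),
                   labels=tuple(df["label"].astype(str)))


def write_ground_truth_csv(pair: PhantomPair, path: str | Path) -> None:
    """Bundle-level ground truth: node pair and per-session fibre counts."""
    rows = []
    for b in pair.bundles:
        i, j = sorted(b.endpoints)
        rows.append({"node_i": i, "node_j": j,
                     "fc_tp1": b.fibre_count[0], "fc_tp2": b.fibre_count[1]})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_config(config: PhantomConfig, path: str | Path) -> None:
    data = {k: (list(v) if isinstance(v, tuple) else v)
            for k, v in config.__dict__.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def read_config(path: str | Path) -> PhantomConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "grid_shape" in data:
        data["grid_shape"] = tuple(data["grid_shape"])
    return PhantomConfig(**data)
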