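"""Readers and writers for the plain-text formats the pipeline consumes.

Connectomes travel as labeled square-matrix CSV/TSV (header row and
first column are node labels; symmetry is checked on read).
Coordinates are CSV with columns ``label, x, y, z`` and optionally
``sx, sy, sz, hemisphere``. State sets and annotation maps are
regions x columns tables keyed by node label.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .graph import Connectome

__all__ = [
    "read_connectome",
    "write_connectome",
    "read_maps",
    "write_maps",
]


def _sep(path: Path) -> str:
    return "\t" if Path(path).suffix.lower() in (".tsv", ".tab") else ","


def read_connectome(
    matrix_path: str | Path, coords_path: str | Path | None = None
) -> Connectome:
    """Load a connectome from a labeled square-matrix table.

    ``coords_path`` optionally supplies Euclidean (and spherical)
    coordinates plus hemisphere labels, matched by node label.
    """
    matrix_path = Path(matrix_path)
    df = pd.read_csv(matrix_path, sep=_sep(matrix_path), index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(
            f"{matrix_path}: row and column labels differ; not a labeled "
            "square matrix"
        )
    labels = [str(x) for x in df.index]
    kwargs: dict = {}
    if coords_path is not None:
        coords_path = Path(coords_path)
        cdf = pd.read_csv(coords_path, sep=_sep(coords_path))
        cdf["label"] = cdf["label"].astype(str)
        cdf = cdf.set_index("label")
        missing = [l for l in labels if l not in cdf.index]
        if missing:
            raise ValueError(f"{coords_path}: missing coordinates for {missing}")
        cdf = cdf.loc[labels]
        kwargs["coords_euclidean"] = cdf[["x", "y", "z"]].to_numpy(dtype=float)
        if {"sx", "sy", "sz"} <= set(cdf.columns):
            kwargs["coords_spherical"] = cdf[["sx", "sy", "sz"]].to_numpy(dtype=float)
        if "hemisphere" in cdf.columns:
            kwargs["hemisphere"] = cdf["hemisphere"].to_numpy(dtype=object)
    return Connectome(
        adjacency=df.to_numpy(dtype=float), node_labels=labels, **kwargs
    )


def write_connectome(
    connectome: Connectome,
    matrix_path: str | Path,
    coords_path: str | Path | None = None,
) -> None:
    """Write the weight matrix (and optionally coordinates) as CSV/TSV."""
    matrix_path = Path(matrix_path)
    pd.DataFrame(
        connectome.adjacency,
        index=connectome.node_labels,
        columns=connectome.node_labels,
    ).to_csv(matrix_path, sep=_sep(matrix_path))
    if coords_path is not None:
        if connectome.coords_euclidean is None:
            raise ValueError("connectome has no coordinates to write")
        coords_path = Path(coords_path)
        out = pd.DataFrame(
            connectome.coords_euclidean,
            columns=["x", "y", "z"],
            index=pd.Index(connectome.node_labels, name="label"),
        )
        if connectome.coords_spherical is not None:
            out[["sx", "sy", "sz"]] = connectome.coords_spherical
        if connectome.hemisphere is not None:
            out["hemisphere"] = connectome.hemisphere
        out.to_csv(coords_path, sep=_sep(coords_path))


def read_maps(path: str | Path, node_labels: list[str] | None = None) -> pd.DataFrame:
    """Load a regions x columns table keyed by node label.

    If ``node_labels`` is given, rows are checked and reordered to
    match the connectome's node order.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    df.index = df.index.astype(str)
    if node_labels is not None:
        missing = [l for l in node_labels if l not in df.index]
        if missing:
            raise ValueError(f"{path}: missing rows for nodes {missing}")
        df = df.loc[[str(l) for l in node_labels]]
    return df


def write_maps(maps: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    maps.to_csv(path, sep=_sep(path), index_label=maps.index.name or "node")


def matrix_to_csv(matrix: np.ndarray, labels: list[str], path: str | Path) -> None:
    """Write any labeled square matrix (e.g. transition energies)."""
    path = Path(path)
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(path, sep=_sep(path))
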