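"""Readers and writers for MatrixMarket count matrices with TSV sidecars.

A matrix directory holds ``matrix.mtx`` (cells x features, 1-based indices
per the MatrixMarket standard), ``cells.tsv`` (cell metadata, first column
cell_id) and ``features.tsv`` (feature metadata, first column the feature
id), plus optional per-layer ``<layer>.mtx`` files.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


class MatrixDimensionError(ValueError):
    """Matrix shape disagrees with its sidecar tables."""


class DuplicateIdError(ValueError):
    """Duplicate cell or feature identifiers in a sidecar."""


class MatrixFormatError(ValueError):
    """Malformed MatrixMarket file."""


def write_counts(adata: ad.AnnData, outdir: str | Path,
                 layers: tuple[str, ...] = ()) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    spio.mmwrite(outdir / "matrix.mtx", sparse.coo_matrix(X))
    for layer in layers:
        spio.mmwrite(outdir / f"{layer}.mtx",
                     sparse.coo_matrix(adata.layers[layer]))
    adata.obs.rename_axis("cell_id").to_csv(outdir / "cells.tsv", sep="\t")
    adata.var.rename_axis("feature_id").to_csv(outdir / "features.tsv", sep="\t")


def read_counts(indir: str | Path, layers: tuple[str, ...] = ()) -> ad.AnnData:
    """Read a matrix directory back into an AnnData.

    Dimension mismatches, duplicate identifiers and malformed headers each
    raise a named error.
    """
    indir = Path(indir)
    for fname in ("matrix.mtx", "cells.tsv", "features.tsv"):
        if not (indir / fname).exists():
            raise FileNotFoundError(indir / fname)
    try:
        X = spio.mmread(indir / "matrix.mtx")
    except ValueError as e:
        raise MatrixFormatError(f"malformed MatrixMarket file: {e}") from e
    X = sparse.csr_matrix(X)
    obs = pd.read_csv(indir / "cells.tsv", sep="\t", index_col=0)
    var = pd.read_csv(indir / "features.tsv", sep="\t", index_col=0)
    obs.index = obs.index.astype(str)
    var.index = var.index.astype(str)
    if obs.index.duplicated().any():
        raise DuplicateIdError("duplicate cell ids in cells.tsv")
    if var.index.duplicated().any():
        raise DuplicateIdError("duplicate feature ids in features.tsv")
    if X.shape != (len(obs), len(var)):
        raise MatrixDimensionError(
            f"matrix is {X.shape}, sidecars imply {(len(obs), len(var))}")
    adata = ad.AnnData(X=X, obs=obs, var=var)
    for layer in layers:
        path = indir / f"{layer}.mtx"
        if not path.exists():
            raise FileNotFoundError(path)
        try:
            L = sparse.csr_matrix(spio.mmread(path))
        except ValueError as e:
            raise MatrixFormatError(f"malformed layer {layer!r}: {e}") from e
        if L.shape != X.shape:
            raise MatrixDimensionError(
                f"layer {layer!r} is {L.shape}, matrix is {X.shape}")
        adata.layers[layer] = L
    return adata


def read_junctions(indir: str | Path) -> ad.AnnData:
    return read_counts(indir, layers=("canonical", "cryptic"))


def read_long_junctions(path) -> ad.AnnData:
    """Read junction counts from long-format TSV
    (cell, event, canonical, cryptic)."""
    df = pd.read_csv(path, sep="\t", dtype={"cell": str, "event": str})
    need = {"cell", "event", "canonical", "cryptic"}
    if not need <= set(df.columns):
        raise ValueError(f"long junction table needs columns {sorted(need)}")
    cells = pd.Index(pd.unique(df["cell"]), name="cell_id")
    events = pd.Index(pd.unique(df["event"]), name="event_id")
    ci = cells.get_indexer(df["cell"])
    ei = events.get_indexer(df["event"])
    shape = (len(cells), len(events))
    canonical = sparse.coo_matrix(
        (df["canonical"].to_numpy(np.int64), (ci, ei)), shape=shape).tocsr()
    cryptic = sparse.coo_matrix(
        (df["cryptic"].to_numpy(np.int64), (ci, ei)), shape=shape).tocsr()
    return ad.AnnData(
        X=canonical + cryptic,
        obs=pd.DataFrame(index=cells),
        var=pd.DataFrame(index=events),
        layers={"canonical": canonical, "cryptic": cryptic},
    )
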