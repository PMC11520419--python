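"""Reading and writing expression matrices and auxiliary tables.

Two on-disk layouts are supported: a 10x-style Matrix-Market directory
(``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv``) and a dense delimited
text file with a header row of cell ids and gene ids in the first column.
An ``orientation`` flag overrides the assumed genes-in-rows layout.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import ExpressionMatrix, OrthologMap

MTX_NAMES = ("matrix.mtx", "genes.tsv", "barcodes.tsv")


def read_expression(
    path: str | os.PathLike,
    format: str = "auto",
    orientation: str = "genes_by_cells",
    batch_id: Optional[str] = None,
) -> ExpressionMatrix:
    """Read a raw count matrix from ``path``.

    ``format`` is ``"mtx-dir"``, ``"delimited"`` or ``"auto"`` (directory →
    mtx-dir, file → delimited).  ``orientation`` names the on-disk layout;
    the returned matrix is always genes × cells.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input path does not exist: {path}")
    if format == "auto":
        format = "mtx-dir" if path.is_dir() else "delimited"
    if format == "mtx-dir":
        mat, genes, cells = _read_mtx_dir(path)
    elif format == "delimited":
        mat, genes, cells = _read_delimited(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if orientation == "cells_by_genes":
        mat = mat.T
        genes, cells = cells, genes
    elif orientation != "genes_by_cells":
        raise ValueError(f"unknown orientation {orientation!r}")
    if mat.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match {len(genes)} gene and "
            f"{len(cells)} cell names in {path}"
        )
    if mat.size and mat.min() < 0:
        raise ValueError(f"negative counts in {path}")
    if batch_id is None:
        batch_id = path.name if path.is_dir() else path.stem
    return ExpressionMatrix(mat, genes, cells, batch_id=batch_id, stage="raw")


def _read_mtx_dir(path: Path):
    missing = [n for n in MTX_NAMES if not (path / n).exists()]
    if missing:
        raise FileNotFoundError(f"mtx directory {path} missing files: {missing}")
    mat = spio.mmread(path / "matrix.mtx")
    if sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=np.float64)
    genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].astype(str).to_numpy()
    cells = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str).to_numpy()
    return mat, genes, cells


def _read_delimited(path: Path):
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    return df.to_numpy(dtype=np.float64), df.index.astype(str).to_numpy(), df.columns.astype(str).to_numpy()


def write_mtx_dir(x: ExpressionMatrix, path: str | os.PathLike) -> None:
    """Write ``x`` as a 10x-style Matrix-Market directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(path / "matrix.mtx"), sparse.coo_matrix(x.values))
    pd.Series(x.gene_ids).to_csv(path / "genes.tsv", sep="\t", header=False, index=False)
    pd.Series(x.cell_ids).to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)


def read_ortholog_map(path: str | os.PathLike) -> OrthologMap:
    """Read a 3-column TSV (source gene, target gene, relation class)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["source", "target", "relation"], dtype=str)
    if df.isna().any().any():
        raise ValueError(f"malformed ortholog map {path}: missing fields")
    return OrthologMap(
        pairs=list(zip(df["source"], df["target"])),
        relation=list(df["relation"]),
    )


def read_cell_labels(path: str | os.PathLike) -> pd.Series:
    """Read a 2-column TSV (cell id → label) into a Series indexed by cell."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cell", "label"], dtype=str)
    return df.set_index("cell")["label"]
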