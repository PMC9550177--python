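"""Reading, writing and validation of paired unspliced/spliced datasets.

The canonical in-memory container is an :class:`anndata.AnnData` with
layers ``"unspliced"`` and ``"spliced"`` (cells x genes), the convention
used by the velocity-counting pipelines upstream of this package.
Supported interchange formats are h5ad and a pair of MatrixMarket files
with TSV barcode/feature lists; matrices stored genes x cells are detected
from the barcode/feature counts and transposed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import anndata
from anndata import AnnData

__all__ = ["read_dataset", "read_mtx_pair", "write_dataset", "validate_dataset"]


def validate_dataset(adata: AnnData) -> AnnData:
    """Check layer presence, shape agreement and identifier uniqueness."""
    for name in ("unspliced", "spliced"):
        if name not in adata.layers:
            raise ValueError(f"dataset is missing required layer '{name}'")
        if adata.layers[name].shape != adata.shape:
            raise ValueError(f"layer '{name}' shape does not match the dataset")
    for axis, ids in (("cell", adata.obs_names), ("gene", adata.var_names)):
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate {axis} identifiers")
    U = adata.layers["unspliced"]
    S = adata.layers["spliced"]
    for name, X in (("unspliced", U), ("spliced", S)):
        mn = X.min() if not sp.issparse(X) else X.data.min() if X.nnz else 0.0
        if mn < 0:
            raise ValueError(f"negative entries in layer '{name}'")
    return adata


def read_mtx_pair(
    spliced_mtx: str | Path,
    unspliced_mtx: str | Path,
    barcodes_tsv: str | Path,
    features_tsv: str | Path,
) -> AnnData:
    """Build a dataset from two MatrixMarket matrices plus id lists.

    Orientation is auto-detected: a matrix whose shape is
    (n_features, n_barcodes) is transposed to cells x genes; shapes
    matching neither orientation are rejected.
    """
    barcodes = pd.read_csv(barcodes_tsv, header=None, sep="\t")[0].astype(str).tolist()
    features = pd.read_csv(features_tsv, header=None, sep="\t")[0].astype(str).tolist()
    n_cells, n_genes = len(barcodes), len(features)

    def load(path):
        X = scipy.io.mmread(str(path)).tocsr()
        if X.shape == (n_cells, n_genes):
            return X
        if X.shape == (n_genes, n_cells):
            return X.T.tocsr()
        raise ValueError(
            f"{path}: shape {X.shape} matches neither (cells={n_cells}, genes={n_genes}) "
            "nor its transpose"
        )

    S = load(spliced_mtx)
    U = load(unspliced_mtx)
    adata = AnnData(
        X=S.copy(),
        layers={"spliced": S, "unspliced": U},
        obs=pd.DataFrame(index=barcodes),
        var=pd.DataFrame(index=features),
    )
    return validate_dataset(adata)


def read_dataset(path: str | Path, fmt: str | None = None) -> AnnData:
    """Read an h5ad file (or an MTX-pair directory) into the canonical
    container.

    An MTX directory must contain ``spliced.mtx``, ``unspliced.mtx``,
    ``barcodes.tsv`` and ``features.tsv``.
    """
    path = Path(path)
    if fmt is None:
        fmt = "mtx-pair" if path.is_dir() else "h5ad"
    if fmt == "h5ad":
        adata = anndata.read_h5ad(path)
        return validate_dataset(adata)
    if fmt == "mtx-pair":
        return read_mtx_pair(
            path / "spliced.mtx",
            path / "unspliced.mtx",
            path / "barcodes.tsv",
            path / "features.tsv",
        )
    raise ValueError(f"unknown format '{fmt}' (expected 'h5ad' or 'mtx-pair')")


def write_dataset(adata: AnnData, path: str | Path) -> None:
    """Write the dataset to h5ad (validates first)."""
    validate_dataset(adata)
    adata.write_h5ad(Path(path))
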