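"""Loading spatial expression data and the standard preprocessing chain.

Raw counts come in as a spot-by-gene matrix with per-spot 2-D coordinates.
Preprocessing follows the usual spatial-transcriptomics recipe: drop genes
expressed in fewer than ``min_spots`` spots, library-size normalize,
log1p-transform, optionally keep the top highly variable genes, and
standardize each gene to zero mean / unit variance.  Coordinates are taken
as given (array or pixel units); only pairwise distances matter downstream.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
from scipy import sparse

from .errors import AlignmentError, EmptyMatrixError, ParameterError

__all__ = [
    "ExpressionBundle",
    "PreprocessedMatrix",
    "load_bundle",
    "save_bundle",
    "preprocess",
]


@dataclass
class ExpressionBundle:
    """Raw counts plus spatial coordinates for one tissue slice.

    Attributes
    ----------
    counts
        Non-negative integer matrix, spots x genes (dense or scipy sparse).
    gene_ids, spot_ids
        Unique identifiers for columns and rows.
    coords
        N x 2 spatial coordinates, one row per spot, aligned with ``spot_ids``.
    truth_labels
        Optional per-spot ground-truth domain annotation.
    slice_id
        Optional per-spot slice/batch identifier (used in joint analysis).
    """

    counts: np.ndarray | sparse.spmatrix
    gene_ids: np.ndarray
    spot_ids: np.ndarray
    coords: np.ndarray
    truth_labels: Optional[np.ndarray] = None
    slice_id: Optional[np.ndarray] = None

    def __post_init__(self):
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.spot_ids = np.asarray(self.spot_ids, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        n, g = self.counts.shape
        if self.coords.shape != (n, 2):
            raise AlignmentError(
                f"coords shape {self.coords.shape} does not match {n} spots"
            )
        if len(self.gene_ids) != g or len(self.spot_ids) != n:
            raise AlignmentError("id vectors do not match the count matrix")
        if len(set(self.gene_ids)) != g:
            raise ParameterError("gene_ids are not unique")
        if len(set(self.spot_ids)) != n:
            raise ParameterError("spot_ids are not unique")
        mn = self.counts.min() if not sparse.issparse(self.counts) else self.counts.min()
        if mn < 0:
            raise ParameterError("counts must be non-negative")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def counts_dense(self) -> np.ndarray:
        if sparse.issparse(self.counts):
            return np.asarray(self.counts.todense())
        return np.asarray(self.counts)


@dataclass
class PreprocessedMatrix:
    """Normalized, log-transformed, scaled expression ready for the model."""

    X: np.ndarray
    selected_genes: np.ndarray
    spot_ids: np.ndarray = field(default=None)

    @property
    def n_spots(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]


def _read_positions(path: str, barcodes: Sequence[str]) -> np.ndarray:
    """Read a 10x-style tissue_positions table and align it to barcodes."""
    # header style differs between Space Ranger versions; sniff it
    first = pd.read_csv(path, nrows=1, header=None)
    has_header = isinstance(first.iloc[0, 1], str) and not str(first.iloc[0, 0]).startswith(
        ("A", "C", "G", "T")
    )
    if has_header:
        pos = pd.read_csv(path)
        pos = pos.set_index(pos.columns[0])
    else:
        pos = pd.read_csv(path, header=None, index_col=0)
    missing = [b for b in barcodes if b not in pos.index]
    if missing:
        raise AlignmentError(
            f"{len(missing)} spot(s) missing from position table: {missing[:10]}",
            missing_ids=missing,
        )
    pos = pos.loc[list(barcodes)]
    # last two columns are pixel row/col in Space Ranger output
    return pos.iloc[:, -2:].to_numpy(dtype=float)


def load_bundle(path: str, format: str = "delimited") -> ExpressionBundle:
    """Read counts + coordinates from disk.

    Parameters
    ----------
    path
        Directory (``tenx_dir``, ``delimited``) or HDF5 file (``tenx_h5``).
    format
        ``tenx_dir``: matrix.mtx(.gz) + barcodes/features TSV + a
        tissue_positions CSV in the same directory.
        ``tenx_h5``: 10x HDF5 feature-barcode matrix + tissue_positions CSV
        next to it.
        ``delimited``: ``counts.tsv`` (spots x genes, first column spot id)
        and ``coords.csv`` with columns spot_id,x,y; optional ``truth.csv``
        with columns spot_id,label.
    """
    if format == "delimited":
        counts_path = os.path.join(path, "counts.tsv")
        coords_path = os.path.join(path, "coords.csv")
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        coords = pd.read_csv(coords_path).set_index("spot_id")
        missing = [s for s in counts.index if s not in coords.index]
        if missing:
            raise AlignmentError(
                f"{len(missing)} spot(s) missing coordinates: {missing[:10]}",
                missing_ids=missing,
            )
        coords = coords.loc[counts.index]
        truth = None
        truth_path = os.path.join(path, "truth.csv")
        if os.path.exists(truth_path):
            tr = pd.read_csv(truth_path).set_index("spot_id")
            truth = tr.loc[counts.index, "label"].to_numpy(dtype=object)
        return ExpressionBundle(
            counts=counts.to_numpy(),
            gene_ids=counts.columns.to_numpy(dtype=object),
            spot_ids=counts.index.to_numpy(dtype=object),
            coords=coords[["x", "y"]].to_numpy(dtype=float),
            truth_labels=truth,
        )
    if format == "tenx_dir":
        adata = sc.read_10x_mtx(path)
        pos_path = None
        for name in ("tissue_positions.csv", "tissue_positions_list.csv"):
            cand = os.path.join(path, name)
            if os.path.exists(cand):
                pos_path = cand
                break
        if pos_path is None:
            raise AlignmentError("no tissue_positions CSV found in directory")
        coords = _read_positions(pos_path, adata.obs_names)
        return ExpressionBundle(
            counts=adata.X.tocsr() if sparse.issparse(adata.X) else np.asarray(adata.X),
            gene_ids=adata.var_names.to_numpy(dtype=object),
            spot_ids=adata.obs_names.to_numpy(dtype=object),
            coords=coords,
        )
    if format == "tenx_h5":
        adata = sc.read_10x_h5(path)
        adata.var_names_make_unique()
        pos_path = os.path.join(os.path.dirname(path), "tissue_positions.csv")
        if not os.path.exists(pos_path):
            raise AlignmentError("no tissue_positions.csv next to the HDF5 file")
        coords = _read_positions(pos_path, adata.obs_names)
        return ExpressionBundle(
            counts=adata.X.tocsr() if sparse.issparse(adata.X) else np.asarray(adata.X),
            gene_ids=adata.var_names.to_numpy(dtype=object),
            spot_ids=adata.obs_names.to_numpy(dtype=object),
            coords=coords,
        )
    raise ParameterError(f"unknown format {format!r}")


def save_bundle(bundle: ExpressionBundle, path: str) -> None:
    """Write a bundle in the ``delimited`` layout ``load_bundle`` reads."""
    os.makedirs(path, exist_ok=True)
    counts = pd.DataFrame(
        bundle.counts_dense(), index=bundle.spot_ids, columns=bundle.gene_ids
    )
    counts.to_csv(os.path.join(path, "counts.tsv"), sep="\t", index_label="spot_id")
    pd.DataFrame(
        {"spot_id": bundle.spot_ids, "x": bundle.coords[:, 0], "y": bundle.coords[:, 1]}
    ).to_csv(os.path.join(path, "coords.csv"), index=False)
    if bundle.truth_labels is not None:
        pd.DataFrame({"spot_id": bundle.spot_ids, "label": bundle.truth_labels}).to_csv(
            os.path.join(path, "truth.csv"), index=False
        )


def preprocess(
    bundle: ExpressionBundle,
    n_hvg: int = 3000,
    *,
    min_spots: int = 3,
    target_sum: float = 1e4,
    hvg_flavor: str = "seurat",
    clip: Optional[float] = None,
) -> PreprocessedMatrix:
    """Filter, normalize, log-transform, select HVGs and scale.

    Genes expressed in fewer than ``min_spots`` spots are removed first.
    Counts are then normalized to ``target_sum`` per spot and log1p
    transformed.  If more than ``n_hvg`` genes survive filtering, the top
    ``n_hvg`` highly variable genes (dispersion-based selection on the
    log-normalized data) are kept; otherwise all surviving genes are used.
    Finally each gene is standardized to zero mean and unit variance;
    zero-variance genes become all-zero columns.
    """
    if n_hvg < 1:
        raise ParameterError("n_hvg must be >= 1")
    X = bundle.counts
    if not sparse.issparse(X):
        X = np.asarray(X, dtype=np.float64)
    adata = ad.AnnData(
        X=X.astype(np.float64) if not sparse.issparse(X) else X.astype(np.float64),
        obs=pd.DataFrame(index=pd.Index(bundle.spot_ids.astype(str), name="spot_id")),
        var=pd.DataFrame(index=pd.Index(bundle.gene_ids.astype(str), name="gene_id")),
    )
    sc.pp.filter_genes(adata, min_cells=min_spots)
    if adata.n_vars == 0:
        raise EmptyMatrixError("all genes removed by the min-spots filter")
    sc.pp.normalize_total(adata, target_sum=target_sum)
    sc.pp.log1p(adata)
    if adata.n_vars > n_hvg:
        sc.pp.highly_variable_genes(adata, flavor=hvg_flavor, n_top_genes=n_hvg)
        adata = adata[:, adata.var.highly_variable].copy()
    pre = np.asarray(adata.X, dtype=np.float64)
    degenerate = pre.std(axis=0) <= 1e-10 * (1.0 + np.abs(pre.mean(axis=0)))
    sc.pp.scale(adata, zero_center=True, max_value=clip)
    Xs = np.asarray(adata.X, dtype=np.float64)
    Xs[:, degenerate] = 0.0  # constant genes carry no signal
    return PreprocessedMatrix(
        X=Xs,
        selected_genes=adata.var_names.to_numpy(dtype=object),
        spot_ids=bundle.spot_ids.copy(),
    )
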