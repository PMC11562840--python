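"""Joint analysis of multiple slices with batch-effect correction.

Per-slice KNN graphs are placed on the block diagonal of one big adjacency
(no cross-slice edges), expression matrices are stacked row-wise over the
shared gene panel, and the auto-encoder is trained exactly as for a single
slice.  The joint embedding is then batch-corrected: the default corrector
aligns per-batch centroids (optionally within coarse clusters so that
composition differences between slices are respected); harmonypy is used
instead when it is importable and requested.
"""

from __future__ import annotations

import warnings
from typing import List, Optional, Tuple

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
from scipy import sparse

from .errors import ParameterError, SpagicError
from .graph import SpatialGraph, build_knn_graph
from .preprocess import ExpressionBundle, PreprocessedMatrix
from .synthetic import SliceBundle

__all__ = ["concat_slices", "correct_batches"]


def _filter_genes_per_slice(bundle: ExpressionBundle, min_spots: int) -> np.ndarray:
    counts = bundle.counts
    if sparse.issparse(counts):
        expressed = np.asarray((counts > 0).sum(axis=0)).ravel()
    else:
        expressed = (np.asarray(counts) > 0).sum(axis=0)
    return bundle.gene_ids[expressed >= min_spots]


def concat_slices(
    bundle: SliceBundle,
    k: int = 6,
    l: float = 1.0,
    n_hvg: int = 3000,
    *,
    min_spots: int = 3,
    target_sum: float = 1e4,
    norm_mode: str = "per_slice",
) -> Tuple[SpatialGraph, PreprocessedMatrix, np.ndarray]:
    """Block-diagonal graph + stacked expression + batch labels.

    Genes are harmonized by intersecting the per-slice filtered gene sets
    (ordered as in the first slice).  Normalization/log happen per slice by
    default (``norm_mode='joint'`` normalizes the stacked matrix instead);
    HVG selection and scaling always operate on the concatenated matrix.
    """
    if bundle.n_slices < 2:
        raise ParameterError("joint analysis needs at least two slices")
    if norm_mode not in ("per_slice", "joint"):
        raise ParameterError(f"unknown norm_mode {norm_mode!r}")
    kept = [set(_filter_genes_per_slice(b, min_spots)) for b in bundle.slices]
    shared = set.intersection(*kept)
    genes = np.array([g for g in bundle.slices[0].gene_ids if g in shared], dtype=object)
    if len(genes) == 0:
        raise ParameterError("no shared genes survive filtering across slices")

    adatas = []
    for i, b in enumerate(bundle.slices):
        col_idx = pd.Index(b.gene_ids).get_indexer(genes)
        counts = b.counts_dense()[:, col_idx].astype(np.float64)
        a = ad.AnnData(
            X=counts,
            obs=pd.DataFrame(index=pd.Index(b.spot_ids.astype(str))),
            var=pd.DataFrame(index=pd.Index(genes.astype(str))),
        )
        if norm_mode == "per_slice":
            sc.pp.normalize_total(a, target_sum=target_sum)
            sc.pp.log1p(a)
        adatas.append(a)
    joint = ad.concat(adatas, axis=0)
    if norm_mode == "joint":
        sc.pp.normalize_total(joint, target_sum=target_sum)
        sc.pp.log1p(joint)
    if joint.n_vars > n_hvg:
        sc.pp.highly_variable_genes(joint, flavor="seurat", n_top_genes=n_hvg)
        joint = joint[:, joint.var.highly_variable].copy()
    sc.pp.scale(joint, zero_center=True)

    graphs = [build_knn_graph(b.coords, k=k, l=l) for b in bundle.slices]
    A_block = sparse.block_diag([g.A for g in graphs], format="csr")
    graph = SpatialGraph.from_adjacency(A_block, k=k, l=l)

    batch = np.concatenate(
        [
            b.slice_id if b.slice_id is not None else np.array([f"slice{i}"] * b.n_spots, dtype=object)
            for i, b in enumerate(bundle.slices)
        ]
    )
    spot_ids = np.concatenate([b.spot_ids for b in bundle.slices])
    X = PreprocessedMatrix(
        X=np.asarray(joint.X, dtype=np.float64),
        selected_genes=joint.var_names.to_numpy(dtype=object),
        spot_ids=spot_ids,
    )
    return graph, X, batch


def _centroid_align(
    Z: np.ndarray, batch: np.ndarray, n_clusters: Optional[int], seed: int
) -> np.ndarray:
    """Shift each batch so its (per-cluster) centroid matches the pooled one."""
    Z = np.asarray(Z, dtype=float)
    out = Z.copy()
    if n_clusters is None or n_clusters <= 1:
        overall = Z.mean(axis=0)
        for b in np.unique(batch):
            mask = batch == b
            out[mask] += overall - Z[mask].mean(axis=0)
        return out
    from sklearn.cluster import KMeans

    assign = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10).fit_predict(Z)
    for c in np.unique(assign):
        cmask = assign == c
        target = Z[cmask].mean(axis=0)
        for b in np.unique(batch):
            mask = cmask & (batch == b)
            if mask.sum() > 0:
                out[mask] += target - Z[mask].mean(axis=0)
    return out


def correct_batches(
    Z: np.ndarray,
    batch: np.ndarray,
    method: str = "centroid",
    *,
    n_clusters: Optional[int] = None,
    seed: int = 0,
) -> np.ndarray:
    """Batch-corrected embedding Z_hm with the same shape as Z.

    ``centroid`` (default) performs per-batch centroid alignment in the
    embedding space; ``harmony`` calls the harmonypy package when
    installed; ``none`` returns a copy.  A single batch short-circuits to a
    pass-through with a warning.
    """
    Z = np.asarray(Z, dtype=float)
    batch = np.asarray(batch)
    if len(batch) != Z.shape[0]:
        raise ParameterError("batch labels must match embedding rows")
    if len(np.unique(batch)) < 2:
        warnings.warn("single batch: correction skipped", stacklevel=2)
        return Z.copy()
    if method == "none":
        return Z.copy()
    if method == "centroid":
        return _centroid_align(Z, batch, n_clusters, seed)
    if method == "harmony":
        try:
            import harmonypy
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise SpagicError(
                "harmony correction requires the harmonypy package"
            ) from exc
        meta = pd.DataFrame({"batch": batch.astype(str)})
        try:
            ho = harmonypy.run_harmony(Z, meta, ["batch"])
        except Exception as exc:  # pragma: no cover
            raise SpagicError(f"harmonypy failed: {exc}") from exc
        return np.asarray(ho.Z_corr.T, dtype=float)
    raise ParameterError(f"unknown correction method {method!r}")
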