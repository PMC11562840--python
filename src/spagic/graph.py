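"""Spatial KNN graph construction and the GCN propagation operator.

Spot-to-spot similarity is a Gaussian kernel of Euclidean distance,
S_ij = exp(-||p_i - p_j||^2 / (2 l^2)).  Each spot is linked to its k most
similar spots (the kernel is monotone in distance, so ranking by S equals
ranking by distance and the graph does not depend on the bandwidth l).  The
directed KNN relation is symmetrized by logical OR, a self-loop is added
(A~ = A + I) and the symmetric normalized adjacency D^{-1/2} A~ D^{-1/2}
is precomputed for the GCN layers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial.distance import cdist

from .errors import ParameterError

__all__ = [
    "SpatialGraph",
    "gaussian_similarity",
    "build_knn_graph",
    "mean_degree",
    "export_edge_list",
]


@dataclass
class SpatialGraph:
    """KNN adjacency and its self-looped, symmetric-normalized variants.

    ``A`` has zero diagonal; ``A_tilde = A + I``; ``degree`` holds the row
    sums of ``A_tilde``; ``A_norm = D^{-1/2} A_tilde D^{-1/2}``.
    """

    A: sparse.csr_matrix
    A_tilde: sparse.csr_matrix
    degree: np.ndarray
    A_norm: sparse.csr_matrix
    k: int
    l: float

    @property
    def n_spots(self) -> int:
        return self.A.shape[0]

    def neighbor_mask(self) -> np.ndarray:
        """Dense boolean adjacency without self-loops."""
        return np.asarray(self.A.todense()).astype(bool)

    @classmethod
    def from_adjacency(cls, A: sparse.spmatrix, k: int = 0, l: float = 1.0) -> "SpatialGraph":
        """Build the self-looped / normalized companions of a symmetric A."""
        A = sparse.csr_matrix(A, dtype=float)
        A.setdiag(0)
        A.eliminate_zeros()
        n = A.shape[0]
        A_tilde = (A + sparse.identity(n, format="csr")).tocsr()
        degree = np.asarray(A_tilde.sum(axis=1)).ravel()
        d_inv_sqrt = 1.0 / np.sqrt(degree)
        D = sparse.diags(d_inv_sqrt)
        A_norm = (D @ A_tilde @ D).tocsr()
        return cls(A=A, A_tilde=A_tilde, degree=degree, A_norm=A_norm, k=k, l=l)


def gaussian_similarity(coords: np.ndarray, l: float) -> np.ndarray:
    """Gaussian-kernel similarity S_ij = exp(-||p_i - p_j||^2 / (2 l^2)).

    Returns a dense symmetric matrix with unit diagonal, values in (0, 1].
    """
    if l <= 0:
        raise ParameterError("bandwidth l must be positive")
    coords = np.asarray(coords, dtype=float)
    d2 = cdist(coords, coords, metric="sqeuclidean")
    S = np.exp(-d2 / (2.0 * l * l))
    np.fill_diagonal(S, 1.0)
    return S


def build_knn_graph(coords: np.ndarray, k: int, l: float = 1.0) -> SpatialGraph:
    """KNN spatial graph with OR-symmetrization and self-loops.

    For each spot its ``k`` nearest spots (Euclidean distance, equivalently
    highest Gaussian similarity) become neighbors; A_ij = A_ji = 1 whenever
    either spot selects the other, so actual degrees fall in [k, 2k].
    Ties among equidistant candidates are broken by spot index, which makes
    the graph deterministic across runs and platforms.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if not 1 <= k < n:
        raise ParameterError(f"k must satisfy 1 <= k < N (got k={k}, N={n})")
    if l <= 0:
        raise ParameterError("bandwidth l must be positive")
    rows = np.empty(n * k, dtype=np.int64)
    cols = np.empty(n * k, dtype=np.int64)
    idx = np.arange(n)
    # chunked all-pairs distances; lexsort gives distance-then-index order
    chunk = max(1, int(2e7) // max(n, 1))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d2 = cdist(coords[start:stop], coords, metric="sqeuclidean")
        d2[np.arange(stop - start), np.arange(start, stop)] = np.inf
        for i in range(stop - start):
            order = np.lexsort((idx, d2[i]))
            rows[(start + i) * k : (start + i + 1) * k] = start + i
            cols[(start + i) * k : (start + i + 1) * k] = order[:k]
    A_dir = sparse.coo_matrix((np.ones(n * k), (rows, cols)), shape=(n, n)).tocsr()
    A = A_dir.maximum(A_dir.T)
    A.data[:] = 1.0
    return SpatialGraph.from_adjacency(A, k=k, l=l)


def mean_degree(graph: SpatialGraph) -> float:
    """Mean neighbor count per spot, self-loop excluded."""
    return float(np.asarray(graph.A.sum(axis=1)).ravel().mean())


def export_edge_list(graph: SpatialGraph, path: str) -> None:
    """Write the undirected edges (i <= j) of A as a TSV for inspection."""
    coo = sparse.triu(graph.A, k=1).tocoo()
    pd.DataFrame({"i": coo.row, "j": coo.col, "weight": coo.data}).to_csv(
        path, sep="\t", index=False
    )
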