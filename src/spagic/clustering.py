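"""Spatial-domain assignment from embeddings, refinement and scoring.

The default clustering mirrors the mclust usage common in spatial
transcriptomics: a Gaussian mixture with a shared ("EEE"-style) covariance
fitted by EM, initialized from ward hierarchical clustering of a PCA
projection, under a fixed seed.  k-means, Louvain (igraph multilevel) and
Leiden on an embedding KNN graph are available as alternatives.  An
optional bridge to the R mclust package (``mclust_r``) gives exact parity
with the reference implementation when Rscript is available.

Refinement reassigns each spot to the modal label among its 50 spatially
nearest neighbors (a single pass over the pre-refinement labels), which
smooths domain boundaries on datasets where that is appropriate.
"""

from __future__ import annotations

import subprocess
import tempfile
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import kneighbors_graph

from .errors import ParameterError

__all__ = [
    "DomainAssignment",
    "cluster",
    "refine_labels",
    "score",
    "denoised_expression",
    "mclust_r",
]

METHODS = ("gmm_mclust", "kmeans", "louvain", "leiden")


@dataclass
class DomainAssignment:
    """Cluster labels before/after refinement plus optional agreement scores."""

    labels_raw: np.ndarray
    n_domains: int
    method: str
    labels_refined: Optional[np.ndarray] = None
    ari: Optional[float] = None
    nmi: Optional[float] = None

    @property
    def labels(self) -> np.ndarray:
        return self.labels_refined if self.labels_refined is not None else self.labels_raw


def _gmm_mclust(Z: np.ndarray, n_domains: int, seed: int) -> np.ndarray:
    n, d = Z.shape
    n_comp = min(20, d, n - 1)
    proj = PCA(n_components=n_comp, random_state=seed).fit_transform(Z)
    init = AgglomerativeClustering(n_clusters=n_domains, linkage="ward").fit_predict(proj)
    means = np.vstack([Z[init == c].mean(axis=0) for c in range(n_domains)])
    weights = np.bincount(init, minlength=n_domains) / n
    gm = GaussianMixture(
        n_components=n_domains,
        covariance_type="tied",
        means_init=means,
        weights_init=weights,
        random_state=seed,
        max_iter=300,
        reg_covar=1e-6,
    )
    return gm.fit_predict(Z)


def _graph_community(Z: np.ndarray, method: str, resolution: float, seed: int) -> np.ndarray:
    import igraph as ig

    k = min(15, Z.shape[0] - 1)
    adj = kneighbors_graph(Z, n_neighbors=k, mode="connectivity")
    adj = adj.maximum(adj.T).tocoo()
    edges = [(int(i), int(j)) for i, j in zip(adj.row, adj.col) if i < j]
    g = ig.Graph(n=Z.shape[0], edges=edges)
    if method == "louvain":
        part = g.community_multilevel(resolution=resolution)
        return np.asarray(part.membership)
    import leidenalg

    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    return np.asarray(part.membership)


def cluster(
    Z: np.ndarray,
    n_domains: Optional[int] = None,
    method: str = "gmm_mclust",
    seed: int = 0,
    resolution: float = 1.0,
) -> DomainAssignment:
    """Assign every spot to a spatial domain.

    ``n_domains`` is required by the model-based methods (set it to the
    annotated domain count when ground truth exists); Louvain/Leiden ignore
    it and take ``resolution`` instead.
    """
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    if method not in METHODS:
        raise ParameterError(f"method must be one of {METHODS}")
    if method in ("gmm_mclust", "kmeans"):
        if n_domains is None:
            raise ParameterError(f"{method} requires n_domains")
        if not 1 <= n_domains <= n:
            raise ParameterError("n_domains must lie in [1, N]")
        if n_domains == 1:
            labels = np.zeros(n, dtype=int)
        elif method == "gmm_mclust":
            labels = _gmm_mclust(Z, n_domains, seed)
        else:
            labels = KMeans(n_clusters=n_domains, random_state=seed, n_init=10).fit_predict(Z)
    else:
        labels = _graph_community(Z, method, resolution, seed)
        n_domains = int(labels.max()) + 1
    return DomainAssignment(labels_raw=labels, n_domains=n_domains, method=method)


def mclust_r(Z: np.ndarray, n_domains: int, model: str = "EEE", seed: int = 0) -> np.ndarray:
    """Cluster with the R mclust package via Rscript (exact-parity bridge)."""
    with tempfile.TemporaryDirectory() as tmp:
        zpath, opath = f"{tmp}/z.csv", f"{tmp}/labels.csv"
        np.savetxt(zpath, np.asarray(Z, float), delimiter=",")
        script = (
            f"set.seed({seed}); suppressMessages(library(mclust));"
            f"z <- as.matrix(read.csv('{zpath}', header=FALSE));"
            f"fit <- Mclust(z, G={n_domains}, modelNames='{model}', verbose=FALSE);"
            f"write.csv(data.frame(label=fit$classification), '{opath}', row.names=FALSE)"
        )
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        return pd.read_csv(opath)["label"].to_numpy() - 1


def refine_labels(
    labels: np.ndarray, coords: np.ndarray, n_neighbors: int = 50
) -> np.ndarray:
    """Replace each label by the mode among the spot's nearest neighbors.

    Distances are spatial (not embedding) distances; the spot itself is
    excluded.  Ties keep the spot's current label when it participates in
    the tie, otherwise take the tied label with the lowest index — a
    conservative, deterministic rule.  One pass, all spots judged against
    the pre-refinement labels.
    """
    labels = np.asarray(labels)
    coords = np.asarray(coords, dtype=float)
    n = len(labels)
    if n_neighbors >= n:
        raise ParameterError("n_neighbors must be < N")
    uniq, codes = np.unique(labels, return_inverse=True)
    d2 = cdist(coords, coords, metric="sqeuclidean")
    np.fill_diagonal(d2, np.inf)
    idx = np.arange(n)
    out = np.empty(n, dtype=int)
    for i in range(n):
        order = np.lexsort((idx, d2[i]))[:n_neighbors]
        counts = np.bincount(codes[order], minlength=len(uniq))
        best = counts.max()
        tied = np.flatnonzero(counts == best)
        out[i] = codes[i] if codes[i] in tied else tied[0]
    return uniq[out]


def score(labels: np.ndarray, truth: np.ndarray) -> Tuple[float, float]:
    """Adjusted Rand index and normalized mutual information vs truth."""
    labels, truth = np.asarray(labels), np.asarray(truth)
    if len(labels) != len(truth):
        raise ParameterError("label and truth lengths differ")
    if len(np.unique(truth)) < 2:
        warnings.warn("truth has a single class; NMI is degenerate", stacklevel=2)
    ari = float(adjusted_rand_score(truth, labels))
    nmi = float(normalized_mutual_info_score(truth, labels))
    return ari, nmi


def denoised_expression(
    H: np.ndarray, selected_genes: np.ndarray, spot_ids: Optional[np.ndarray] = None
) -> pd.DataFrame:
    """Decoder reconstruction as a gene-by-spot table for export/markers."""
    H = np.asarray(H, dtype=float)
    cols = spot_ids if spot_ids is not None else np.arange(H.shape[0])
    return pd.DataFrame(H.T, index=np.asarray(selected_genes), columns=np.asarray(cols))
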