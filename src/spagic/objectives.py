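"""Training objectives: reconstruction, graph mutual-information, contrastive.

Four loss terms act on the auto-encoder outputs:

* ``loss_mse`` — mean per-spot squared reconstruction error between the
  preprocessed expression X and the decoder output H.
* ``loss_bce`` — edge-wise constraint: binary cross-entropy between the
  self-looped adjacency A~ and sigmoid(Z Z^T), averaged over all N^2
  ordered pairs, pushing embedding dot products to reconstruct edges.
* ``loss_kl`` — neighborhood-wise constraint: mean over spots of the KL
  divergence between the row-softmax of Z Z^T and a prior local-structure
  distribution obtained by row-normalizing an epsilon-floored A~.
* ``loss_contrastive`` — an InfoNCE-like term with cosine similarity and
  temperature tau: per anchor spot, the log-ratio of the summed exponential
  similarity to spatial neighbors over that to non-neighbors (the anchor
  itself excluded from both sums).

The total objective is lambda1 * L_mse + lambda2 * (L_bce + L_kl) +
lambda3 * L_con with defaults (60, 0.01, 0.01).  Each loss has an analytic
gradient with respect to Z (or H) used by the trainer; every formula here
is unit-tested against an independent double-loop reference and against
finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import sparse
from scipy.special import expit, log_softmax, softmax, xlogy

from .errors import ContractError, NumericError, ParameterError
from .graph import SpatialGraph

__all__ = [
    "ObjectiveState",
    "LossReport",
    "DEFAULT_LAMBDAS",
    "ABLATIONS",
    "edge_weights",
    "adjacency_prior",
    "loss_mse",
    "grad_mse",
    "loss_bce",
    "grad_bce",
    "loss_kl",
    "grad_kl",
    "loss_contrastive",
    "grad_contrastive",
    "total_loss",
]

DEFAULT_LAMBDAS: Tuple[float, float, float] = (60.0, 0.01, 0.01)

# which terms enter the total under each ablation variant
ABLATIONS = {
    "full": {"bce", "kl", "con"},
    "no_bce": {"kl", "con"},
    "no_kl": {"bce", "con"},
    "no_con": {"bce", "kl"},
    "no_G": {"con"},
    "only_mse": set(),
}

SIGMOID_CLAMP = 1e-7
PRIOR_EPS = 1e-12


@dataclass
class ObjectiveState:
    """Edge-weight matrix Z Z^T and its sigmoid / row-softmax views."""

    W_raw: np.ndarray
    W_sig: np.ndarray
    W_soft: np.ndarray
    tau: float = 1.0

    @property
    def n_spots(self) -> int:
        return self.W_raw.shape[0]


@dataclass
class LossReport:
    """Per-term loss values; ``l_g = l_bce + l_kl`` is always reported even
    when an ablation excludes terms from ``total``."""

    l_mse: float
    l_bce: float
    l_kl: float
    l_con: float
    total: float

    @property
    def l_g(self) -> float:
        return self.l_bce + self.l_kl

    def as_dict(self) -> dict:
        return {
            "l_mse": self.l_mse,
            "l_bce": self.l_bce,
            "l_kl": self.l_kl,
            "l_g": self.l_g,
            "l_con": self.l_con,
            "total": self.total,
        }


def edge_weights(Z: np.ndarray, tau: float = 1.0) -> ObjectiveState:
    """Expected edge weights W_ij = Z_i . Z_j with sigmoid/softmax views."""
    Z = np.asarray(Z, dtype=float)
    if not np.all(np.isfinite(Z)):
        raise NumericError("embedding contains non-finite values")
    W = Z @ Z.T
    return ObjectiveState(W_raw=W, W_sig=expit(W), W_soft=softmax(W, axis=1), tau=tau)


def adjacency_prior(A_tilde: np.ndarray, eps: float = PRIOR_EPS) -> np.ndarray:
    """Row-normalized, epsilon-floored self-looped adjacency.

    The floor keeps the KL divergence finite where A~_ij = 0 while leaving
    the local-structure semantics intact (neighbor mass >> eps).
    """
    A = np.asarray(A_tilde, dtype=float)
    A = np.maximum(A, eps)
    return A / A.sum(axis=1, keepdims=True)


def loss_mse(X: np.ndarray, H: np.ndarray) -> float:
    """Mean over spots of the squared Euclidean reconstruction error."""
    X, H = np.asarray(X, float), np.asarray(H, float)
    if X.shape != H.shape:
        raise ContractError(f"shape mismatch {X.shape} vs {H.shape}")
    return float(np.sum((X - H) ** 2) / X.shape[0])


def grad_mse(X: np.ndarray, H: np.ndarray) -> np.ndarray:
    """dL_mse/dH = 2 (H - X) / N."""
    return 2.0 * (np.asarray(H, float) - np.asarray(X, float)) / X.shape[0]


def loss_bce(
    A_tilde: np.ndarray, W_sig: np.ndarray, clamp: float = SIGMOID_CLAMP
) -> float:
    """BCE between A~ and sigmoid(Z Z^T), averaged over all N^2 pairs."""
    A = np.asarray(A_tilde, dtype=float)
    W = np.clip(np.asarray(W_sig, float), clamp, 1.0 - clamp)
    if A.shape != W.shape:
        raise ContractError("adjacency and edge-weight shapes differ")
    n = A.shape[0]
    return float(-np.sum(A * np.log(W) + (1.0 - A) * np.log1p(-W)) / (n * n))


def grad_bce(Z: np.ndarray, A_tilde: np.ndarray) -> np.ndarray:
    """dL_bce/dZ via dL/dW_raw = (sigmoid(W_raw) - A~) / N^2."""
    Z = np.asarray(Z, float)
    n = Z.shape[0]
    G = (expit(Z @ Z.T) - np.asarray(A_tilde, float)) / (n * n)
    return (G + G.T) @ Z


def loss_kl(
    A_tilde: np.ndarray, W_soft: np.ndarray, eps: float = PRIOR_EPS
) -> float:
    """Mean over spots of KL(row-softmax(Z Z^T) || floored prior from A~).

    Softmax entries that underflow to exactly zero contribute zero
    (xlogy convention), keeping the divergence finite.
    """
    P = np.asarray(W_soft, float)
    Q = adjacency_prior(A_tilde, eps)
    if P.shape != Q.shape:
        raise ContractError("adjacency and softmax shapes differ")
    n = P.shape[0]
    return float(np.sum(xlogy(P, P) - P * np.log(Q)) / n)


def grad_kl(Z: np.ndarray, A_tilde: np.ndarray, eps: float = PRIOR_EPS) -> np.ndarray:
    """dL_kl/dZ through the row softmax of W_raw = Z Z^T.

    With a = log(P/Q) and per-row value v_i = sum_j P_ij a_ij, the softmax
    Jacobian gives dL/dW_ij = P_ij (a_ij - v_i) / N.
    """
    Z = np.asarray(Z, float)
    n = Z.shape[0]
    logP = log_softmax(Z @ Z.T, axis=1)
    P = np.exp(logP)
    Q = adjacency_prior(A_tilde, eps)
    a = logP - np.log(Q)
    v = np.sum(P * a, axis=1, keepdims=True)
    G = P * (a - v) / n
    return (G + G.T) @ Z


def _cosine_matrix(Z: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-normalized Z, its norms, and the cosine-similarity matrix.

    Zero rows get cosine 0 against everything (and gradient 0), avoiding
    NaN on degenerate embeddings.
    """
    Z = np.asarray(Z, float)
    norms = np.linalg.norm(Z, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    U = Z / safe[:, None]
    C = U @ U.T
    return U, norms, C


def loss_contrastive(
    Z: np.ndarray,
    graph: SpatialGraph,
    tau: float = 1.0,
    *,
    canonical: bool = False,
) -> float:
    """InfoNCE-like contrast between spatial neighbors and non-neighbors.

    Per anchor i: -log( sum_{j in N_i} e^{cos(Z_i,Z_j)/tau} /
    sum_{j not in N_i, j != i} e^{cos(Z_i,Z_j)/tau} ), averaged over spots.
    ``canonical=True`` instead uses the standard InfoNCE denominator
    (positives + negatives).
    """
    if tau <= 0:
        raise ParameterError("temperature tau must be positive")
    _, _, C = _cosine_matrix(Z)
    n = C.shape[0]
    pos = graph.neighbor_mask()
    if pos.shape != (n, n):
        raise ContractError("graph size does not match embedding rows")
    off_diag = ~np.eye(n, dtype=bool)
    neg = off_diag & ~pos
    if not pos.any(axis=1).all():
        raise ContractError("every spot needs at least one neighbor")
    if not neg.any(axis=1).all():
        raise ContractError(
            "every spot needs at least one non-neighbor (graph is complete)"
        )
    E = np.exp(C / tau)
    num = np.sum(E * pos, axis=1)
    den = np.sum(E * neg, axis=1)
    if canonical:
        den = den + num
    return float(np.mean(np.log(den) - np.log(num)))


def grad_contrastive(
    Z: np.ndarray,
    graph: SpatialGraph,
    tau: float = 1.0,
    *,
    canonical: bool = False,
) -> np.ndarray:
    """Analytic dL_con/dZ (cosine similarity chain rule, zero rows fixed)."""
    if tau <= 0:
        raise ParameterError("temperature tau must be positive")
    U, norms, C = _cosine_matrix(Z)
    n = C.shape[0]
    pos = graph.neighbor_mask()
    off_diag = ~np.eye(n, dtype=bool)
    neg = off_diag & ~pos
    E = np.exp(C / tau)
    num = np.sum(E * pos, axis=1)
    den = np.sum(E * neg, axis=1)
    if canonical:
        den = den + num
        # d/dc of log(den) applies to every off-diagonal pair
        Gc = E * (off_diag / den[:, None] - pos / num[:, None]) / (n * tau)
    else:
        Gc = E * (neg / den[:, None] - pos / num[:, None]) / (n * tau)
    M = Gc + Gc.T
    row = np.sum(M * C, axis=1)
    dU = M @ U - row[:, None] * U
    safe = np.where(norms > 0, norms, 1.0)
    dZ = dU / safe[:, None]
    dZ[norms == 0] = 0.0
    return dZ


def total_loss(
    l_mse: float,
    l_bce: float,
    l_kl: float,
    l_con: float,
    lambdas: Tuple[float, float, float] = DEFAULT_LAMBDAS,
    ablation: str = "full",
) -> LossReport:
    """Weighted combination; ablations exclude terms from the total while
    all per-term values remain reported for logging."""
    if ablation not in ABLATIONS:
        raise ParameterError(f"unknown ablation {ablation!r}")
    if any(lam < 0 for lam in lambdas):
        raise ParameterError("lambdas must be non-negative")
    active = ABLATIONS[ablation]
    l1, l2, l3 = lambdas
    total = l1 * l_mse
    total += l2 * ((l_bce if "bce" in active else 0.0) + (l_kl if "kl" in active else 0.0))
    total += l3 * (l_con if "con" in active else 0.0)
    return LossReport(l_mse=l_mse, l_bce=l_bce, l_kl=l_kl, l_con=l_con, total=float(total))


def sampled_pair_losses(
    Z: np.ndarray,
    graph: SpatialGraph,
    n_negatives: int,
    rng: np.random.Generator,
    eps: float = PRIOR_EPS,
    clamp: float = SIGMOID_CLAMP,
) -> Tuple[float, float, np.ndarray]:
    """Subsampled edge/neighborhood losses for very large slices.

    For each spot the support is its positives (A~ row) plus ``n_negatives``
    random non-neighbors; BCE averages over the sampled ordered pairs and
    the KL row-softmax / prior are restricted to the support.  Returns
    (l_bce, l_kl, dZ) where dZ combines the two unweighted gradients as
    (grad_bce, grad_kl) stacked — callers weight them; see ``trainer``.
    """
    Z = np.asarray(Z, float)
    n = Z.shape[0]
    A_tilde = graph.A_tilde.tocsr()
    rows_idx = []
    cols_idx = []
    for i in range(n):
        pos_cols = A_tilde.indices[A_tilde.indptr[i] : A_tilde.indptr[i + 1]]
        pool = rng.choice(n, size=min(n, n_negatives + len(pos_cols)), replace=False)
        support = np.unique(np.concatenate([pos_cols, pool]))
        rows_idx.append(np.full(len(support), i))
        cols_idx.append(support)
    rows = np.concatenate(rows_idx)
    cols = np.concatenate(cols_idx)
    w = np.sum(Z[rows] * Z[cols], axis=1)
    a = np.asarray(A_tilde[rows, cols]).ravel()
    m = len(rows)
    # BCE over sampled ordered pairs
    sig = np.clip(expit(w), clamp, 1.0 - clamp)
    l_bce = float(-np.mean(a * np.log(sig) + (1 - a) * np.log1p(-sig)))
    g_bce_vals = (expit(w) - a) / m
    # per-row softmax over the sampled support
    order = np.argsort(rows, kind="stable")
    rows_s, cols_s, w_s, a_s = rows[order], cols[order], w[order], a[order]
    starts = np.searchsorted(rows_s, np.arange(n))
    ends = np.searchsorted(rows_s, np.arange(n), side="right")
    l_kl = 0.0
    g_kl_vals = np.empty(m)
    for i in range(n):
        sl = slice(starts[i], ends[i])
        wi = w_s[sl]
        logp = log_softmax(wi)
        p = np.exp(logp)
        q = np.maximum(a_s[sl], eps)
        q = q / q.sum()
        ai = logp - np.log(q)
        l_kl += float(np.sum(p * ai))
        g_kl_vals[sl] = p * (ai - np.sum(p * ai)) / n
    l_kl /= n
    G_bce = sparse.coo_matrix((g_bce_vals, (rows, cols)), shape=(n, n)).tocsr()
    G_kl = sparse.coo_matrix((g_kl_vals, (rows_s, cols_s)), shape=(n, n)).tocsr()
    dZ_bce = (G_bce + G_bce.T) @ Z
    dZ_kl = (G_kl + G_kl.T) @ Z
    return l_bce, l_kl, np.stack([dZ_bce, dZ_kl])
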