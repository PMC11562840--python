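"""GCN auto-encoder: two-layer encoder to a 64-d latent space, mirrored decoder.

One GCN layer computes sigma(A_norm @ features @ W) where A_norm is the
symmetric normalized self-looped adjacency.  The encoder maps the M-gene
expression matrix X through widths (512, 64) to the latent embedding Z; the
decoder mirrors it back, (64 -> 512 -> M), producing the reconstruction H.
The final layer of each half is linear by default: Z must take negative
values for cosine similarity and Gaussian-mixture clustering to be
meaningful, and H must reach the negative values present in standardized X.

Everything is plain numpy.  ``forward`` keeps the per-layer pre-activations
so ``backward`` can push loss gradients dL/dZ and dL/dH onto the weight
matrices analytically (A_norm is symmetric, which the backward pass relies
on).
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse

from .errors import ContractError
from .graph import SpatialGraph

__all__ = [
    "GcnParams",
    "ForwardCache",
    "init_params",
    "gcn_layer",
    "encode",
    "decode",
    "forward",
    "backward",
    "save_params",
    "load_params",
]


@dataclass
class GcnParams:
    """Trainable weights of the mirrored encoder/decoder stack.

    ``encoder_weights`` chain M -> hidden[0] -> ... -> hidden[-1]; the
    decoder reverses the widths back to M.  ``final_linear`` controls
    whether the last layer of each half skips the rectifier.
    """

    encoder_weights: List[np.ndarray]
    decoder_weights: List[np.ndarray]
    activation: str = "relu"
    final_linear: bool = True

    def all_weights(self) -> List[np.ndarray]:
        return self.encoder_weights + self.decoder_weights

    @property
    def latent_dim(self) -> int:
        return self.encoder_weights[-1].shape[1]

    @property
    def input_dim(self) -> int:
        return self.encoder_weights[0].shape[0]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_params(
    n_genes: int,
    hidden: Sequence[int] = (512, 64),
    seed: int = 0,
    final_linear: bool = True,
) -> GcnParams:
    """Glorot-uniform initialization of the mirrored stack, seeded."""
    rng = np.random.default_rng(seed)
    widths = [n_genes, *hidden]
    enc = [_glorot(rng, widths[i], widths[i + 1]) for i in range(len(widths) - 1)]
    rev = widths[::-1]
    dec = [_glorot(rng, rev[i], rev[i + 1]) for i in range(len(rev) - 1)]
    return GcnParams(encoder_weights=enc, decoder_weights=dec, final_linear=final_linear)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def gcn_layer(
    features: np.ndarray,
    A_norm: sparse.spmatrix | np.ndarray,
    W: np.ndarray,
    activate: bool = True,
) -> np.ndarray:
    """One graph-convolution step: sigma(A_norm @ features @ W)."""
    features = np.asarray(features, dtype=float)
    if features.shape[1] != W.shape[0]:
        raise ContractError(
            f"feature width {features.shape[1]} != weight rows {W.shape[0]}"
        )
    if A_norm.shape[0] != features.shape[0]:
        raise ContractError("adjacency and feature row counts differ")
    out = A_norm @ features @ W
    return _relu(out) if activate else np.asarray(out)


@dataclass
class ForwardCache:
    """Intermediate products of a forward pass, kept for backprop."""

    # encoder: P[i] = A @ (input of layer i), S[i] = P[i] @ W[i] (pre-activation)
    enc_P: List[np.ndarray] = field(default_factory=list)
    enc_S: List[np.ndarray] = field(default_factory=list)
    dec_P: List[np.ndarray] = field(default_factory=list)
    dec_S: List[np.ndarray] = field(default_factory=list)
    Z: Optional[np.ndarray] = None
    H: Optional[np.ndarray] = None


def _run_half(
    X: np.ndarray,
    A_norm,
    weights: List[np.ndarray],
    final_linear: bool,
) -> Tuple[np.ndarray, List[np.ndarray], List[np.ndarray]]:
    P_list, S_list = [], []
    h = X
    for i, W in enumerate(weights):
        P = A_norm @ h
        S = P @ W
        last = i == len(weights) - 1
        h = S if (last and final_linear) else _relu(S)
        P_list.append(np.asarray(P))
        S_list.append(np.asarray(S))
    return np.asarray(h), P_list, S_list


def encode(X: np.ndarray, graph: SpatialGraph, params: GcnParams) -> np.ndarray:
    """Latent embedding Z of the expression matrix (N x latent_dim)."""
    if X.shape[1] != params.input_dim:
        raise ContractError(
            f"X has {X.shape[1]} genes but encoder expects {params.input_dim}"
        )
    Z, _, _ = _run_half(np.asarray(X, float), graph.A_norm, params.encoder_weights, params.final_linear)
    return Z


def decode(Z: np.ndarray, graph: SpatialGraph, params: GcnParams) -> np.ndarray:
    """Reconstructed expression H from the latent embedding (N x M)."""
    if Z.shape[1] != params.latent_dim:
        raise ContractError(
            f"Z has width {Z.shape[1]} but decoder expects {params.latent_dim}"
        )
    H, _, _ = _run_half(np.asarray(Z, float), graph.A_norm, params.decoder_weights, params.final_linear)
    return H


def forward(X: np.ndarray, graph: SpatialGraph, params: GcnParams) -> ForwardCache:
    """Full auto-encoder pass, returning Z, H and all intermediates."""
    cache = ForwardCache()
    Z, cache.enc_P, cache.enc_S = _run_half(
        np.asarray(X, float), graph.A_norm, params.encoder_weights, params.final_linear
    )
    H, cache.dec_P, cache.dec_S = _run_half(
        Z, graph.A_norm, params.decoder_weights, params.final_linear
    )
    cache.Z, cache.H = Z, H
    return cache


def _backward_half(
    d_out: np.ndarray,
    A_norm,
    weights: List[np.ndarray],
    P_list: List[np.ndarray],
    S_list: List[np.ndarray],
    final_linear: bool,
) -> Tuple[List[np.ndarray], np.ndarray]:
    """Gradients of the weights of one half plus gradient w.r.t. its input."""
    grads: List[np.ndarray] = [None] * len(weights)
    d = d_out
    for i in range(len(weights) - 1, -1, -1):
        last = i == len(weights) - 1
        if not (last and final_linear):
            d = d * (S_list[i] > 0)
        grads[i] = P_list[i].T @ d
        dP = d @ weights[i].T
        d = np.asarray(A_norm @ dP)  # A_norm symmetric
    return grads, d


def backward(
    cache: ForwardCache,
    graph: SpatialGraph,
    params: GcnParams,
    dZ: Optional[np.ndarray],
    dH: Optional[np.ndarray],
) -> Tuple[List[np.ndarray], List[np.ndarray]]:
    """Backpropagate dL/dZ and dL/dH to encoder/decoder weight gradients.

    ``dZ`` collects loss terms acting directly on the embedding (the graph
    mutual-information and contrastive losses); ``dH`` the reconstruction
    loss.  The decoder contributes an extra dL/dZ through its input.
    """
    A = graph.A_norm
    dZ_total = np.zeros_like(cache.Z) if dZ is None else np.array(dZ, dtype=float)
    dec_grads = [np.zeros_like(W) for W in params.decoder_weights]
    if dH is not None:
        dec_grads, dZ_from_dec = _backward_half(
            np.asarray(dH, float), A, params.decoder_weights,
            cache.dec_P, cache.dec_S, params.final_linear,
        )
        dZ_total = dZ_total + dZ_from_dec
    enc_grads, _ = _backward_half(
        dZ_total, A, params.encoder_weights,
        cache.enc_P, cache.enc_S, params.final_linear,
    )
    return enc_grads, dec_grads


def save_params(params: GcnParams, path: str) -> None:
    with open(path, "wb") as fh:
        pickle.dump(params, fh)


def load_params(path: str) -> GcnParams:
    with open(path, "rb") as fh:
        return pickle.load(fh)
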