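"""Full-batch training of the GCN auto-encoder with Adam.

All spots participate in every step: the edge-wise and neighborhood-wise
losses are defined over the whole adjacency, so mini-batching would change
their semantics.  Gradients are the analytic ones from ``objectives`` and
``network``; Adam follows the standard update with L2-style weight decay
added to the raw gradient (learning rate 0.001, weight decay 0.0001 by
default).  Dense N x N loss matrices are used up to ``dense_threshold``
spots; beyond that the edge/neighborhood losses fall back to the seeded
positive + sampled-negative scheme in ``objectives.sampled_pair_losses``.

Runs are deterministic: a fixed seed fixes the weight initialization and
any negative sampling, so identical inputs reproduce identical loss traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import network, objectives
from .errors import ContractError, NumericError, ParameterError
from .graph import SpatialGraph
from .network import GcnParams
from .objectives import ABLATIONS, DEFAULT_LAMBDAS, LossReport
from .preprocess import PreprocessedMatrix

__all__ = ["TrainConfig", "EmbeddingSet", "TrainResult", "train"]


@dataclass
class TrainConfig:
    """Hyperparameters of a training run (defaults mirror the method)."""

    learning_rate: float = 0.001
    weight_decay: float = 0.0001
    epochs: int = 600
    seed: int = 0
    lambdas: Tuple[float, float, float] = DEFAULT_LAMBDAS
    tau: float = 1.0
    ablation: str = "full"
    hidden: Sequence[int] = (512, 64)
    final_linear: bool = True
    dense_threshold: int = 10_000
    n_negatives: int = 50
    canonical_infonce: bool = False

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be positive")
        if self.epochs < 1:
            raise ParameterError("epochs must be >= 1")
        if self.ablation not in ABLATIONS:
            raise ParameterError(f"unknown ablation {self.ablation!r}")


@dataclass
class EmbeddingSet:
    """Latent embedding Z, reconstruction H, optional batch-corrected Z_hm."""

    Z: np.ndarray
    H: np.ndarray
    Z_hm: Optional[np.ndarray] = None


@dataclass
class TrainResult:
    params: GcnParams
    embeddings: EmbeddingSet
    trace: pd.DataFrame


class _Adam:
    def __init__(self, shapes, lr: float, weight_decay: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, weights: List[np.ndarray], grads: List[np.ndarray]) -> None:
        self.t += 1
        for i, (w, g) in enumerate(zip(weights, grads)):
            g = g + self.wd * w
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            w -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _check_finite(report: LossReport, epoch: int) -> None:
    for name, val in report.as_dict().items():
        if not np.isfinite(val):
            raise NumericError(f"non-finite loss term {name} at epoch {epoch}")


def train(
    X: PreprocessedMatrix | np.ndarray,
    graph: SpatialGraph,
    config: TrainConfig = TrainConfig(),
) -> TrainResult:
    """Optimize the auto-encoder and return parameters, embeddings, trace.

    The trace has one row per epoch with every loss term (terms excluded by
    the ablation are still reported, just not part of ``total``).
    """
    Xm = X.X if isinstance(X, PreprocessedMatrix) else np.asarray(X, float)
    n, m = Xm.shape
    if graph.n_spots != n:
        raise ContractError("graph and expression matrix disagree on N")
    params = network.init_params(
        m, hidden=config.hidden, seed=config.seed, final_linear=config.final_linear
    )
    rng = np.random.default_rng(config.seed + 1)
    opt = _Adam(
        [w.shape for w in params.all_weights()],
        config.learning_rate,
        config.weight_decay,
    )
    active = ABLATIONS[config.ablation]
    l1, l2, l3 = config.lambdas
    dense = n <= config.dense_threshold
    A_tilde = np.asarray(graph.A_tilde.todense()) if dense else None

    rows = []
    cache = None
    for epoch in range(config.epochs):
        cache = network.forward(Xm, graph, params)
        Z, H = cache.Z, cache.H

        l_mse = objectives.loss_mse(Xm, H)
        dH = l1 * objectives.grad_mse(Xm, H)
        dZ = np.zeros_like(Z)

        if dense:
            state = objectives.edge_weights(Z, tau=config.tau)
            l_bce = objectives.loss_bce(A_tilde, state.W_sig)
            l_kl = objectives.loss_kl(A_tilde, state.W_soft)
            if "bce" in active and l2 > 0:
                dZ += l2 * objectives.grad_bce(Z, A_tilde)
            if "kl" in active and l2 > 0:
                dZ += l2 * objectives.grad_kl(Z, A_tilde)
        else:
            l_bce, l_kl, stacked = objectives.sampled_pair_losses(
                Z, graph, config.n_negatives, rng
            )
            if "bce" in active and l2 > 0:
                dZ += l2 * stacked[0]
            if "kl" in active and l2 > 0:
                dZ += l2 * stacked[1]

        l_con = objectives.loss_contrastive(
            Z, graph, config.tau, canonical=config.canonical_infonce
        )
        if "con" in active and l3 > 0:
            dZ += l3 * objectives.grad_contrastive(
                Z, graph, config.tau, canonical=config.canonical_infonce
            )

        report = objectives.total_loss(
            l_mse, l_bce, l_kl, l_con, config.lambdas, config.ablation
        )
        _check_finite(report, epoch)
        rows.append({"epoch": epoch, **report.as_dict()})

        enc_g, dec_g = network.backward(cache, graph, params, dZ, dH)
        opt.step(params.all_weights(), enc_g + dec_g)

    final = network.forward(Xm, graph, params)
    trace = pd.DataFrame(rows)
    return TrainResult(
        params=params,
        embeddings=EmbeddingSet(Z=final.Z, H=final.H),
        trace=trace,
    )
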