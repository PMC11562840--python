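import numpy as np
import pytest

from spagic.errors import ContractError, NumericError, ParameterError
from spagic.graph import build_knn_graph
from spagic.objectives import (
    ABLATIONS,
    adjacency_prior,
    edge_weights,
    grad_bce,
    grad_contrastive,
    grad_kl,
    grad_mse,
    loss_bce,
    loss_contrastive,
    loss_kl,
    loss_mse,
    sampled_pair_losses,
    total_loss,
)

# ---------------------------------------------------------------- references


def bce_oracle(A, W, clamp=1e-7):
    n = A.shape[0]
    acc = 0.0
    for i in range(n):
        for j in range(n):
            w = min(max(W[i, j], clamp), 1 - clamp)
            acc += A[i, j] * np.log(w) + (1 - A[i, j]) * np.log(1 - w)
    return -acc / (n * n)


def kl_oracle(A, P, eps=1e-12):
    n = A.shape[0]
    Q = np.maximum(A, eps)
    Q = Q / Q.sum(axis=1, keepdims=True)
    acc = 0.0
    for i in range(n):
        for j in range(n):
            if P[i, j] > 0:
                acc += P[i, j] * np.log(P[i, j] / Q[i, j])
    return acc / n


def con_oracle(Z, A, tau):
    n = Z.shape[0]

    def cos(a, b):
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        return 0.0 if na == 0 or nb == 0 else float(a @ b / (na * nb))

    acc = 0.0
    for i in range(n):
        num = sum(np.exp(cos(Z[i], Z[j]) / tau) for j in range(n) if A[i, j])
        den = sum(
            np.exp(cos(Z[i], Z[j]) / tau) for j in range(n) if j != i and not A[i, j]
        )
        acc += -np.log(num / den)
    return acc / n


def mse_oracle(X, H):
    acc = 0.0
    for i in range(X.shape[0]):
        for j in range(X.shape[1]):
            acc += (X[i, j] - H[i, j]) ** 2
    return acc / X.shape[0]


def finite_difference(f, Z, h=1e-6):
    G = np.zeros_like(Z)
    for i in range(Z.shape[0]):
        for j in range(Z.shape[1]):
            Zp, Zm = Z.copy(), Z.copy()
            Zp[i, j] += h
            Zm[i, j] -= h
            G[i, j] = (f(Zp) - f(Zm)) / (2 * h)
    return G


@pytest.fixture(scope="module")
def fixture6():
    rng = np.random.default_rng(42)
    coords = rng.normal(size=(6, 2)) * 3
    g = build_knn_graph(coords, k=2)
    Z = rng.normal(size=(6, 4))
    return g, Z, np.asarray(g.A_tilde.todense())


# ---------------------------------------------------------------- edge weights


class TestEdgeWeights:
    def test_orthonormal_rows_give_identity(self):
        Z = np.eye(4)[:3]
        np.testing.assert_allclose(edge_weights(Z).W_raw, np.eye(3))

    def test_zero_embedding_views(self):
        st = edge_weights(np.zeros((5, 3)))
        np.testing.assert_allclose(st.W_sig, 0.5)
        np.testing.assert_allclose(st.W_soft, 1 / 5)

    def test_matches_dot_product_loop(self, rng):
        Z = rng.normal(size=(5, 3))
        st = edge_weights(Z)
        for i in range(5):
            for j in range(5):
                assert st.W_raw[i, j] == pytest.approx(float(Z[i] @ Z[j]))
        assert np.allclose(st.W_soft.sum(axis=1), 1.0)
        np.testing.assert_allclose(st.W_raw, st.W_raw.T)

    def test_nonfinite_embedding_rejected(self):
        Z = np.zeros((3, 2))
        Z[0, 0] = np.nan
        with pytest.raises(NumericError):
            edge_weights(Z)


# ---------------------------------------------------------------- losses


class TestLossMse:
    def test_perfect_reconstruction_is_zero(self, rng):
        X = rng.normal(size=(4, 5))
        assert loss_mse(X, X) == 0.0

    def test_single_spot_analytic(self):
        assert loss_mse(np.array([[1.0, 2.0]]), np.array([[0.0, 0.0]])) == 5.0

    def test_matches_loop_oracle(self, rng):
        X, H = rng.normal(size=(8, 6)), rng.normal(size=(8, 6))
        assert loss_mse(X, H) == pytest.approx(mse_oracle(X, H), rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ContractError):
            loss_mse(np.zeros((3, 2)), np.zeros((2, 3)))


class TestLossBce:
    def test_constant_half_prediction_is_ln2(self, fixture6):
        _, _, A = fixture6
        assert loss_bce(A, np.full(A.shape, 0.5)) == pytest.approx(np.log(2))

    def test_perfect_prediction_tends_to_zero(self, fixture6):
        _, _, A = fixture6
        assert loss_bce(A, A) < 1e-5

    def test_matches_loop_oracle(self, rng):
        A = (rng.random((4, 4)) < 0.4).astype(float)
        np.fill_diagonal(A, 1.0)
        W = rng.random((4, 4))
        assert loss_bce(A, W) == pytest.approx(bce_oracle(A, W), rel=1e-12)

    def test_minimized_by_constant_at_adjacency_density(self, fixture6):
        """Over constant predictions p, BCE is minimized at p = density of A~."""
        _, _, A = fixture6
        density = A.mean()
        best = loss_bce(A, np.full(A.shape, density))
        for p in (0.1, 0.3, 0.7, 0.9):
            assert best <= loss_bce(A, np.full(A.shape, p)) + 1e-12


class TestLossKl:
    def test_zero_when_matching_prior(self, fixture6):
        _, _, A = fixture6
        prior = adjacency_prior(A)
        assert loss_kl(A, prior) == pytest.approx(0.0, abs=1e-9)

    def test_zero_for_uniform_vs_uniform(self):
        A = np.ones((4, 4))
        assert loss_kl(A, np.full((4, 4), 0.25)) == pytest.approx(0.0, abs=1e-12)

    def test_matches_loop_oracle(self, fixture6, rng):
        _, Z, A = fixture6
        P = edge_weights(Z).W_soft
        assert loss_kl(A, P) == pytest.approx(kl_oracle(A, P), rel=1e-9)

    def test_underflowed_softmax_entries_are_finite(self):
        Z = np.array([[40.0, 0.0], [-40.0, 0.0], [0.0, 40.0]])
        A = np.eye(3)
        A[0, 1] = A[1, 0] = 1
        val = loss_kl(A, edge_weights(Z).W_soft)
        assert np.isfinite(val)


class TestLossContrastive:
    def test_path_graph_analytic_terms(self):
        # path 0-1-2-3 with Z0=Z1 ⊥ Z2=Z3: each anchor term follows by hand.
        # anchor 0: neighbor {1} cos 1, non-neighbors {2,3} cos 0 -> -log(e/2)
        # anchor 1: neighbors {0,2} cos {1,0}, non-neighbor {3} -> -log(e+1)
        Z = np.array([[1.0, 0.0], [2.0, 0.0], [0.0, 1.0], [0.0, 3.0]])
        from spagic.graph import SpatialGraph
        from scipy import sparse

        A = np.zeros((4, 4))
        for i, j in [(0, 1), (1, 2), (2, 3)]:
            A[i, j] = A[j, i] = 1
        g = SpatialGraph.from_adjacency(sparse.csr_matrix(A))
        e = np.e
        expected = (
            -np.log(e / 2) - np.log(e + 1) - np.log(e + 1) - np.log(e / 2)
        ) / 4
        assert loss_contrastive(Z, g, 1.0) == pytest.approx(expected)
        assert loss_contrastive(Z, g, 1.0) == pytest.approx(con_oracle(Z, A, 1.0))

    def test_symmetric_construction_gives_zero(self):
        """Equal cosines and |N_i| = |non-neighbors| make every ratio 1."""
        from spagic.graph import SpatialGraph
        from scipy import sparse

        # 5 spots, identical embeddings, each with 2 neighbors / 2 non-neighbors
        Z = np.ones((5, 3))
        A = np.zeros((5, 5))
        for i in range(5):
            A[i, (i + 1) % 5] = A[(i + 1) % 5, i] = 1
            A[i, (i - 1) % 5] = A[(i - 1) % 5, i] = 1
        g = SpatialGraph.from_adjacency(sparse.csr_matrix(A))
        assert loss_contrastive(Z, g, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_matches_loop_oracle(self, rng):
        coords = rng.normal(size=(10, 2)) * 3
        g = build_knn_graph(coords, k=3)
        Z = rng.normal(size=(10, 5))
        A = np.asarray(g.A.todense())
        assert loss_contrastive(Z, g, 0.7) == pytest.approx(
            con_oracle(Z, A, 0.7), rel=1e-9
        )

    def test_invariant_to_row_rescaling(self, fixture6, rng):
        g, Z, _ = fixture6
        scales = rng.uniform(0.1, 10, size=Z.shape[0])
        assert loss_contrastive(Z * scales[:, None], g, 1.0) == pytest.approx(
            loss_contrastive(Z, g, 1.0)
        )

    def test_complete_graph_rejected(self):
        from spagic.graph import SpatialGraph
        from scipy import sparse

        A = np.ones((4, 4)) - np.eye(4)
        g = SpatialGraph.from_adjacency(sparse.csr_matrix(A))
        with pytest.raises(ContractError):
            loss_contrastive(np.random.default_rng(0).normal(size=(4, 2)), g, 1.0)

    def test_nonpositive_temperature_rejected(self, fixture6):
        g, Z, _ = fixture6
        with pytest.raises(ParameterError):
            loss_contrastive(Z, g, 0.0)


# ---------------------------------------------------------------- gradients


class TestGradients:
    def test_bce_gradient_matches_finite_differences(self, fixture6):
        g, Z, A = fixture6
        num = finite_difference(lambda z: loss_bce(A, edge_weights(z).W_sig), Z)
        ana = grad_bce(Z, A)
        assert np.abs(num - ana).max() / np.abs(num).max() < 1e-4

    def test_kl_gradient_matches_finite_differences(self, fixture6):
        g, Z, A = fixture6
        num = finite_difference(lambda z: loss_kl(A, edge_weights(z).W_soft), Z)
        ana = grad_kl(Z, A)
        assert np.abs(num - ana).max() / np.abs(num).max() < 1e-4

    @pytest.mark.parametrize("canonical", [False, True])
    def test_contrastive_gradient_matches_finite_differences(self, fixture6, canonical):
        g, Z, _ = fixture6
        num = finite_difference(
            lambda z: loss_contrastive(z, g, 0.8, canonical=canonical), Z
        )
        ana = grad_contrastive(Z, g, 0.8, canonical=canonical)
        assert np.abs(num - ana).max() / np.abs(num).max() < 1e-4

    def test_mse_gradient_matches_finite_differences(self, rng):
        X, H = rng.normal(size=(6, 4)), rng.normal(size=(6, 4))
        num = finite_difference(lambda h: loss_mse(X, h), H)
        assert np.abs(num - grad_mse(X, H)).max() < 1e-6

    def test_zero_row_embedding_has_zero_cosine_gradient(self, fixture6):
        g, Z, _ = fixture6
        Zd = Z.copy()
        Zd[2] = 0.0
        ana = grad_contrastive(Zd, g, 1.0)
        assert np.all(np.isfinite(ana))
        np.testing.assert_allclose(ana[2], 0.0)


# ---------------------------------------------------------------- combination


class TestTotalLoss:
    def test_weighted_sum_of_independent_terms(self):
        rep = total_loss(2.0, 0.5, 0.25, 3.0, lambdas=(60, 0.01, 0.01))
        assert rep.total == pytest.approx(60 * 2.0 + 0.01 * 0.75 + 0.01 * 3.0)
        assert rep.l_g == pytest.approx(0.75)

    def test_only_mse_ablation_keeps_reporting_terms(self):
        rep = total_loss(2.0, 0.5, 0.25, 3.0, lambdas=(60, 0.01, 0.01), ablation="only_mse")
        assert rep.total == pytest.approx(120.0)
        assert rep.l_bce == 0.5 and rep.l_kl == 0.25 and rep.l_con == 3.0

    def test_all_zero_terms_give_zero(self):
        assert total_loss(0, 0, 0, 0).total == 0.0

    @pytest.mark.parametrize(
        "ablation,active",
        [(name, terms) for name, terms in ABLATIONS.items()],
    )
    def test_ablation_variants_drop_exactly_their_terms(self, ablation, active):
        lmse, lbce, lkl, lcon = 1.0, 2.0, 4.0, 8.0
        rep = total_loss(lmse, lbce, lkl, lcon, lambdas=(1, 1, 1), ablation=ablation)
        expected = lmse
        expected += (lbce if "bce" in active else 0) + (lkl if "kl" in active else 0)
        expected += lcon if "con" in active else 0
        assert rep.total == pytest.approx(expected)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ParameterError):
            total_loss(1, 1, 1, 1, lambdas=(-1, 0, 0))


class TestSampledPairLosses:
    def test_full_sampling_equals_dense(self, fixture6):
        g, Z, A = fixture6
        st = edge_weights(Z)
        lb, lk, dZ = sampled_pair_losses(
            Z, g, n_negatives=6, rng=np.random.default_rng(0)
        )
        assert lb == pytest.approx(loss_bce(A, st.W_sig), rel=1e-9)
        assert lk == pytest.approx(loss_kl(A, st.W_soft), rel=1e-9)
        np.testing.assert_allclose(dZ[0], grad_bce(Z, A), atol=1e-12)
        np.testing.assert_allclose(dZ[1], grad_kl(Z, A), atol=1e-12)
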