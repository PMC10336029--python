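import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra.numpy import arrays

from mmdma import Hyperparams, ProjectionDual, ProjectionPrimal
from mmdma.losses import (
    GramFeatures,
    distortion_dual,
    distortion_dual_grad,
    distortion_primal,
    distortion_primal_grad,
    loss,
    loss_and_grad,
    mmd_linear_time,
    mmd_squared,
    mmd_squared_grad,
    penalty_dual,
    penalty_dual_grad,
    penalty_primal,
    penalty_primal_grad,
)
from mmdma.data_model import ModalityMatrix


def mmd_squared_bruteforce(U, V, sigma):
    """Independent oracle: explicit double loop over all pairs."""

    def k(a, b):
        return np.exp(-np.sum((a - b) ** 2) / (2 * sigma**2))

    n1, n2 = len(U), len(V)
    suu = sum(k(U[i], U[j]) for i in range(n1) for j in range(n1))
    svv = sum(k(V[i], V[j]) for i in range(n2) for j in range(n2))
    suv = sum(k(U[i], V[j]) for i in range(n1) for j in range(n2))
    return suu / n1**2 + svv / n2**2 - 2 * suv / (n1 * n2)


class TestMMDSquared:
    def test_identical_samples_give_zero(self, rng):
        U = rng.standard_normal((20, 3))
        assert mmd_squared(U, U.copy(), sigma=1.0) == pytest.approx(0.0, abs=1e-12)

    def test_two_singletons_hand_value(self):
        # 1 + 1 - 2 exp(-1/2) for points 0 and 1 at sigma 1
        got = mmd_squared(np.array([[0.0]]), np.array([[1.0]]), sigma=1.0)
        assert got == pytest.approx(2.0 - 2.0 * np.exp(-0.5), rel=1e-12)

    def test_matches_bruteforce_double_loop(self, rng):
        U = rng.standard_normal((13, 4))
        V = rng.standard_normal((9, 4))
        expected = mmd_squared_bruteforce(U, V, 0.9)
        assert mmd_squared(U, V, sigma=0.9) == pytest.approx(expected, rel=1e-10)
        assert expected >= 0

    @pytest.mark.parametrize("block_size", [1, 7, 57, 171])
    def test_streaming_equals_naive(self, rng, block_size):
        U = rng.standard_normal((57, 5))
        V = rng.standard_normal((43, 5))
        naive = mmd_squared(U, V, sigma=1.3, streaming=False)
        streamed = mmd_squared(U, V, sigma=1.3, streaming=True, block_size=block_size)
        assert streamed == pytest.approx(naive, rel=1e-10)

    def test_unbiased_estimator_excludes_diagonal(self, rng):
        U = rng.standard_normal((10, 2))
        V = rng.standard_normal((12, 2))
        biased = mmd_squared(U, V, 1.0, biased=True)
        unbiased = mmd_squared(U, V, 1.0, biased=False)

        def within(A):
            n = len(A)
            K = np.exp(-((A[:, None] - A[None]) ** 2).sum(-1) / 2.0)
            return (K.sum() - n) / (n * (n - 1))

        K_uv = np.exp(-((U[:, None] - V[None]) ** 2).sum(-1) / 2.0)
        expected = within(U) + within(V) - 2 * K_uv.mean()
        assert unbiased == pytest.approx(expected, rel=1e-10)
        assert biased != pytest.approx(unbiased, rel=1e-6)

    def test_sigma_and_shape_errors(self, rng):
        U = rng.standard_normal((5, 2))
        with pytest.raises(Exception, match="sigma"):
            mmd_squared(U, U, sigma=0.0)
        with pytest.raises(ValueError, match="equal width"):
            mmd_squared(U, rng.standard_normal((5, 3)))

    @given(
        U=arrays(np.float64, (6, 2), elements=st.floats(-3, 3)),
        V=arrays(np.float64, (4, 2), elements=st.floats(-3, 3)),
    )
    def test_nonnegative_and_streaming_consistent(self, U, V):
        val = mmd_squared(U, V, sigma=0.7)
        assert val >= -1e-9
        streamed = mmd_squared(U, V, sigma=0.7, streaming=True, block_size=3)
        assert streamed == pytest.approx(val, abs=1e-12, rel=1e-10)

    def test_invariant_under_joint_rotation(self, rng):
        U = rng.standard_normal((15, 3))
        V = rng.standard_normal((11, 3))
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        base = mmd_squared(U, V, 1.1)
        assert mmd_squared(U @ Q, V @ Q, 1.1) == pytest.approx(base, rel=1e-10)


class TestMMDGradient:
    def test_matches_finite_differences(self, rng):
        U = rng.standard_normal((5, 2))
        V = rng.standard_normal((4, 2))
        gU, gV = mmd_squared_grad(U, V, sigma=1.0)
        h = 1e-5
        for arr, grad, which in ((U, gU, 0), (V, gV, 1)):
            fd = np.zeros_like(arr)
            for i in range(arr.shape[0]):
                for j in range(arr.shape[1]):
                    for sgn in (1, -1):
                        pert = arr.copy()
                        pert[i, j] += sgn * h
                        args = (pert, V) if which == 0 else (U, pert)
                        fd[i, j] += sgn * mmd_squared(*args, sigma=1.0)
                    fd[i, j] /= 2 * h
            np.testing.assert_allclose(grad, fd, rtol=1e-5, atol=1e-8)

    @pytest.mark.parametrize("block_size", [1, 7, 50, 150])
    def test_streaming_gradient_equals_naive(self, rng, block_size):
        U = rng.standard_normal((50, 4))
        V = rng.standard_normal((31, 4))
        gU, gV = mmd_squared_grad(U, V, 1.2, streaming=False)
        sU, sV = mmd_squared_grad(U, V, 1.2, streaming=True, block_size=block_size)
        np.testing.assert_allclose(sU, gU, rtol=1e-10, atol=1e-15)
        np.testing.assert_allclose(sV, gV, rtol=1e-10, atol=1e-15)

    def test_gradient_vanishes_for_flat_kernel(self, rng):
        U = rng.standard_normal((6, 3))
        V = rng.standard_normal((6, 3))
        gU, gV = mmd_squared_grad(U, V, sigma=1e8)
        assert np.abs(gU).max() < 1e-12
        assert np.abs(gV).max() < 1e-12

    def test_zero_gradient_at_coincident_samples(self, rng):
        U = rng.standard_normal((8, 2))
        gU, gV = mmd_squared_grad(U, U.copy(), sigma=0.8)
        np.testing.assert_allclose(gU + gV, 0, atol=1e-12)


class TestLinearTimeMMD:
    def test_row_matched_samples_give_zero(self, rng):
        U = rng.standard_normal((10, 3))
        assert mmd_linear_time(U, U.copy(), 1.0) == 0.0

    def test_hand_summed_pairs_n6(self, rng):
        U = rng.standard_normal((6, 2))
        V = rng.standard_normal((6, 2))
        s = 1.1

        def k(a, b):
            return np.exp(-np.sum((a - b) ** 2) / (2 * s * s))

        terms = [
            k(U[2 * i], U[2 * i + 1]) + k(V[2 * i], V[2 * i + 1])
            - k(U[2 * i], V[2 * i + 1]) - k(U[2 * i + 1], V[2 * i])
            for i in range(3)
        ]
        assert mmd_linear_time(U, V, s) == pytest.approx(np.mean(terms), rel=1e-12)

    def test_odd_n_truncates_with_warning(self, rng):
        U = rng.standard_normal((7, 2))
        V = rng.standard_normal((7, 2))
        with pytest.warns(UserWarning, match="odd"):
            got = mmd_linear_time(U, V, 1.0)
        assert got == pytest.approx(mmd_linear_time(U[:6], V[:6], 1.0))

    def test_unequal_n_rejected(self, rng):
        with pytest.raises(ValueError, match="n1 == n2"):
            mmd_linear_time(rng.standard_normal((6, 2)), rng.standard_normal((4, 2)))

    def test_shuffle_mean_matches_unbiased_estimator(self, rng):
        # E over joint row shuffles of the linear-time statistic equals the
        # full U-statistic on the same sample
        n = 200
        U = rng.standard_normal((n, 3)) * 0.8
        V = rng.standard_normal((n, 3)) + 0.3
        vals = []
        for _ in range(200):
            perm = rng.permutation(n)
            vals.append(mmd_linear_time(U[perm], V[perm], 1.0))
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        target = mmd_squared(U, V, 1.0, biased=False)
        assert abs(vals.mean() - target) < 3 * se


class TestPenalty:
    def test_orthonormal_columns_give_zero(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((6, 3)))
        assert penalty_primal(Q) == pytest.approx(0.0, abs=1e-20)

    def test_scaled_orthonormal_value(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((7, 3)))
        # (4-1)^2 per diagonal entry, 3 entries
        assert penalty_primal(2.0 * Q) == pytest.approx(27.0, rel=1e-12)

    def test_zero_map_gives_d(self):
        assert penalty_primal(np.zeros((5, 3))) == pytest.approx(3.0)

    def test_gradient_matches_finite_differences(self, rng):
        W = rng.standard_normal((4, 2))
        g = penalty_primal_grad(W)
        h = 1e-6
        fd = np.zeros_like(W)
        for i in range(4):
            for j in range(2):
                Wp, Wm = W.copy(), W.copy()
                Wp[i, j] += h
                Wm[i, j] -= h
                fd[i, j] = (penalty_primal(Wp) - penalty_primal(Wm)) / (2 * h)
        np.testing.assert_allclose(g, fd, rtol=1e-6, atol=1e-9)


class TestDistortion:
    def test_identity_data_orthogonal_map_zero(self):
        X = np.eye(4)
        Q, _ = np.linalg.qr(np.random.default_rng(0).standard_normal((4, 4)))
        assert distortion_primal(X, Q) == pytest.approx(0.0, abs=1e-18)

    def test_zero_map_gives_gram_norm(self, rng):
        X = rng.standard_normal((20, 4))
        g = GramFeatures.from_matrix(X)
        assert distortion_primal(X, np.zeros((4, 2))) == pytest.approx(
            g.tr_C2, rel=1e-12
        )

    def test_efficient_equals_naive(self, rng):
        X = rng.standard_normal((20, 4))
        W = rng.standard_normal((4, 2))
        naive = distortion_primal(X, W, method="naive")
        eff = distortion_primal(X, W, method="efficient")
        assert eff == pytest.approx(naive, rel=1e-8)

    def test_gradient_matches_finite_differences(self, rng):
        X = rng.standard_normal((15, 4)) * 0.5
        W = rng.standard_normal((4, 2)) * 0.5
        g = distortion_primal_grad(X, W)
        h = 1e-6
        fd = np.zeros_like(W)
        for i in range(4):
            for j in range(2):
                Wp, Wm = W.copy(), W.copy()
                Wp[i, j] += h
                Wm[i, j] -= h
                fd[i, j] = (
                    distortion_primal(X, Wp) - distortion_primal(X, Wm)
                ) / (2 * h)
        np.testing.assert_allclose(g, fd, rtol=1e-5, atol=1e-8)


class TestDualForms:
    def test_dual_equals_primal_penalty_and_distortion(self, rng):
        X = rng.standard_normal((30, 5))
        alpha = rng.standard_normal((30, 3)) * 0.2
        K = X @ X.T
        W = X.T @ alpha
        assert penalty_dual(K, alpha) == pytest.approx(penalty_primal(W), rel=1e-8)
        assert distortion_dual(K, alpha) == pytest.approx(
            distortion_primal(X, W), rel=1e-8
        )

    def test_alpha_with_unit_gram_zero_penalty(self, rng):
        X = rng.standard_normal((10, 6))
        K = X @ X.T
        # whiten some alpha so that alpha^T K alpha = I
        A = rng.standard_normal((10, 3))
        L = np.linalg.cholesky(A.T @ K @ A)
        alpha = A @ np.linalg.inv(L).T
        assert penalty_dual(K, alpha) == pytest.approx(0.0, abs=1e-12)

    def test_asymmetric_kernel_rejected(self, rng):
        K = rng.standard_normal((5, 5))
        with pytest.raises(ValueError, match="symmetric"):
            penalty_dual(K, rng.standard_normal((5, 2)))

    def test_dual_gradients_match_finite_differences(self, rng):
        X = rng.standard_normal((8, 4)) * 0.6
        K = X @ X.T
        alpha = rng.standard_normal((8, 2)) * 0.3
        h = 1e-6
        for f, gf in ((penalty_dual, penalty_dual_grad),
                      (distortion_dual, distortion_dual_grad)):
            g = gf(K, alpha)
            fd = np.zeros_like(alpha)
            for i in range(8):
                for j in range(2):
                    ap, am = alpha.copy(), alpha.copy()
                    ap[i, j] += h
                    am[i, j] -= h
                    fd[i, j] = (f(K, ap) - f(K, am)) / (2 * h)
            np.testing.assert_allclose(g, fd, rtol=1e-5, atol=1e-8)


class TestFullLoss:
    def test_zero_lambdas_identical_embeddings_zero_total(self, rng):
        x = ModalityMatrix(rng.standard_normal((12, 3)))
        hp = Hyperparams(d=2, lambda1=0.0, lambda2=0.0, sigma=1.0, streaming=False)
        W = rng.standard_normal((3, 2))
        bd = loss(x, x, ProjectionPrimal(W), ProjectionPrimal(W.copy()), hp)
        assert bd.total == pytest.approx(0.0, abs=1e-12)

    def test_total_is_sum_of_components(self, small_pair, rng):
        x, y = small_pair
        hp = Hyperparams(d=3, lambda1=0.3, lambda2=0.07, sigma=1.2, streaming=False)
        Wx = rng.standard_normal((5, 3))
        Wy = rng.standard_normal((4, 3))
        bd = loss(x, y, ProjectionPrimal(Wx), ProjectionPrimal(Wy), hp)
        U, V = x.values @ Wx, y.values @ Wy
        assert bd.mmd2 == pytest.approx(mmd_squared(U, V, 1.2), rel=1e-12)
        assert bd.pen_x == pytest.approx(penalty_primal(Wx), rel=1e-12)
        assert bd.dis_y == pytest.approx(distortion_primal(y.values, Wy), rel=1e-12)
        expected = bd.mmd2 + 0.3 * (bd.pen_x + bd.pen_y) + 0.07 * (bd.dis_x + bd.dis_y)
        assert bd.total == pytest.approx(expected, abs=1e-15)

    def test_primal_dual_full_objective_identity(self, small_pair, rng):
        x, y = small_pair
        ax = rng.standard_normal((30, 3)) * 0.2
        ay = rng.standard_normal((30, 3)) * 0.2
        hp_d = Hyperparams(d=3, lambda1=0.5, lambda2=0.05, sigma=1.0,
                           mode="dual", streaming=False)
        hp_p = hp_d.with_(mode="primal")
        bd_dual = loss(x, y, ProjectionDual(ax), ProjectionDual(ay), hp_d)
        bd_primal = loss(
            x, y,
            ProjectionPrimal(x.values.T @ ax), ProjectionPrimal(y.values.T @ ay),
            hp_p,
        )
        for k in ("mmd2", "pen_x", "pen_y", "dis_x", "dis_y", "total"):
            a, b = getattr(bd_dual, k), getattr(bd_primal, k)
            assert a == pytest.approx(b, rel=1e-8, abs=1e-12), k

    def test_loss_and_grad_consistent_with_loss(self, small_pair, rng):
        x, y = small_pair
        hp = Hyperparams(d=2, lambda1=0.4, lambda2=0.02, sigma=1.1, streaming=False)
        Wx = rng.standard_normal((5, 2)) * 0.5
        Wy = rng.standard_normal((4, 2)) * 0.5
        bd, gx, gy = loss_and_grad(
            x, y, ProjectionPrimal(Wx), ProjectionPrimal(Wy), hp, 1.1
        )
        bd2 = loss(x, y, ProjectionPrimal(Wx), ProjectionPrimal(Wy), hp)
        assert bd.total == pytest.approx(bd2.total, rel=1e-12)
        assert gx.shape == Wx.shape and gy.shape == Wy.shape
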