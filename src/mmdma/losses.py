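"""Objective components in primal and dual form.

The full objective for a modality pair (X, Y) with linear maps is

    L = MMD(U, V)^2
        + lambda1 * (||Wx^T Wx - I||_F^2 + ||Wy^T Wy - I||_F^2)
        + lambda2 * (||XX^T - X Wx Wx^T X^T||_F^2 + (same for Y))

where U = X Wx and V = Y Wy are the embeddings and the MMD uses a
Gaussian RBF kernel k(a, b) = exp(-||a - b||^2 / (2 sigma^2)).  In the
dual parameterization W = X^T alpha, so U = X X^T alpha = K alpha.

Two computational contracts matter for large n:

* the MMD term (value and gradient) can be evaluated **streaming**, by
  row blocks, so that no array with n1*n2 entries is ever allocated;
* the distortion term is evaluated through the p x p Gram matrix
  C = X^T X via  ||XX^T - XWW^T X^T||_F^2
               = tr(C^2) - 2 tr(W^T C^2 W) + tr((W^T C W)^2),
  using only p x p and d x d intermediates.

Streaming code reports its largest temporary through
:data:`peak_block_elements`, which tests use to assert the memory
contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union
import warnings

import numpy as np

from .data_model import (
    ConfigError,
    Hyperparams,
    LossBreakdown,
    ModalityMatrix,
    ProjectionDual,
    ProjectionPrimal,
)

__all__ = [
    "GramFeatures",
    "mmd_squared",
    "mmd_squared_grad",
    "mmd_linear_time",
    "penalty_primal",
    "penalty_primal_grad",
    "distortion_primal",
    "distortion_primal_grad",
    "penalty_dual",
    "penalty_dual_grad",
    "distortion_dual",
    "distortion_dual_grad",
    "loss",
    "loss_and_grad",
    "median_heuristic_sigma",
]

# Largest number of elements in any single temporary allocated by the most
# recent streaming kernel reduction.  Reset at the start of each streaming
# call; tests compare it against block_size**2.
peak_block_elements: int = 0


def _check_embeddings(U: np.ndarray, V: np.ndarray, sigma: float) -> None:
    if U.ndim != 2 or V.ndim != 2 or U.shape[1] != V.shape[1]:
        raise ValueError(
            f"embeddings must be 2-D with equal width, got {U.shape} and {V.shape}"
        )
    if not sigma > 0:
        raise ConfigError(f"sigma must be > 0, got {sigma}")


def _sq_dists(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances, clipped at zero."""
    d2 = (
        np.sum(A * A, axis=1)[:, None]
        + np.sum(B * B, axis=1)[None, :]
        - 2.0 * (A @ B.T)
    )
    return np.maximum(d2, 0.0)


def _kernel_block(A: np.ndarray, B: np.ndarray, sigma: float) -> np.ndarray:
    return np.exp(_sq_dists(A, B) / (-2.0 * sigma * sigma))


def _stream_kernel(
    A: np.ndarray,
    B: np.ndarray,
    sigma: float,
    block_size: int,
    want_grad: bool,
) -> tuple[float, Optional[np.ndarray]]:
    """Blockwise sum_ij k(a_i, b_j) and, optionally, the row-wise
    gradient sums G[i] = sum_j dk(a_i, b_j)/da_i.

    Only (<= block_size) x (<= block_size) temporaries are allocated.
    """
    global peak_block_elements
    n1, n2 = A.shape[0], B.shape[0]
    total = 0.0
    grad = np.zeros_like(A) if want_grad else None
    inv_s2 = 1.0 / (sigma * sigma)
    for i0 in range(0, n1, block_size):
        Ai = A[i0 : i0 + block_size]
        for j0 in range(0, n2, block_size):
            Bj = B[j0 : j0 + block_size]
            K = _kernel_block(Ai, Bj, sigma)
            peak_block_elements = max(peak_block_elements, K.size)
            total += float(K.sum())
            if want_grad:
                # sum_j -((a_i - b_j)/sigma^2) k_ij
                row = K.sum(axis=1)
                grad[i0 : i0 + Ai.shape[0]] += (K @ Bj - Ai * row[:, None]) * inv_s2
    return total, grad


def _kernel_sums(
    U: np.ndarray, V: np.ndarray, sigma: float, streaming: bool, block_size: int
) -> tuple[float, float, float]:
    """(sum k(u,u'), sum k(v,v'), sum k(u,v)) over all pairs incl. self."""
    global peak_block_elements
    if streaming:
        peak_block_elements = 0
        suu, _ = _stream_kernel(U, U, sigma, block_size, want_grad=False)
        svv, _ = _stream_kernel(V, V, sigma, block_size, want_grad=False)
        suv, _ = _stream_kernel(U, V, sigma, block_size, want_grad=False)
    else:
        suu = float(_kernel_block(U, U, sigma).sum())
        svv = float(_kernel_block(V, V, sigma).sum())
        suv = float(_kernel_block(U, V, sigma).sum())
    return suu, svv, suv


def mmd_squared(
    U: np.ndarray,
    V: np.ndarray,
    sigma: float = 1.0,
    streaming: bool = False,
    block_size: int = 4096,
    biased: bool = True,
) -> float:
    """Squared maximum mean discrepancy between the two embedded samples.

    The default is the biased V-statistic (self-pairs included),

        MMD^2 = (1/n1^2) sum_ij k(u_i, u_j) + (1/n2^2) sum_ij k(v_i, v_j)
                - (2/(n1 n2)) sum_ij k(u_i, v_j),

    which is nonnegative by construction.  ``biased=False`` gives the
    unbiased U-statistic (self-pairs excluded from the within-sample
    sums, cross term unchanged).

    With ``streaming=True`` the kernel sums are accumulated over row
    blocks of at most ``block_size`` rows, so no n1 x n2 array is ever
    allocated.
    """
    U = np.asarray(U, dtype=np.float64)
    V = np.asarray(V, dtype=np.float64)
    _check_embeddings(U, V, sigma)
    n1, n2 = U.shape[0], V.shape[0]
    suu, svv, suv = _kernel_sums(U, V, sigma, streaming, block_size)
    if biased:
        return suu / n1**2 + svv / n2**2 - 2.0 * suv / (n1 * n2)
    if n1 < 2 or n2 < 2:
        raise ValueError("unbiased MMD^2 needs at least 2 samples per side")
    # diagonal k(a,a) = 1 for the RBF kernel
    return (
        (suu - n1) / (n1 * (n1 - 1))
        + (svv - n2) / (n2 * (n2 - 1))
        - 2.0 * suv / (n1 * n2)
    )


def mmd_squared_grad(
    U: np.ndarray,
    V: np.ndarray,
    sigma: float = 1.0,
    streaming: bool = False,
    block_size: int = 4096,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradient of the biased MMD^2 with respect to U and V.

    dMMD^2/du_i = (2/n1^2) sum_j dk(u_i,u_j)/du_i
                  - (2/(n1 n2)) sum_j dk(u_i,v_j)/du_i,
    with dk(a,b)/da = -((a-b)/sigma^2) k(a,b); symmetrically for V.
    Streaming obeys the same no-n1*n2-allocation contract as the value.
    """
    global peak_block_elements
    U = np.asarray(U, dtype=np.float64)
    V = np.asarray(V, dtype=np.float64)
    _check_embeddings(U, V, sigma)
    n1, n2 = U.shape[0], V.shape[0]
    if streaming:
        peak_block_elements = 0
        _, g_uu = _stream_kernel(U, U, sigma, block_size, want_grad=True)
        _, g_uv = _stream_kernel(U, V, sigma, block_size, want_grad=True)
        _, g_vv = _stream_kernel(V, V, sigma, block_size, want_grad=True)
        _, g_vu = _stream_kernel(V, U, sigma, block_size, want_grad=True)
    else:
        inv_s2 = 1.0 / (sigma * sigma)

        def dense_grad(A, B):
            K = _kernel_block(A, B, sigma)
            return (K @ B - A * K.sum(axis=1)[:, None]) * inv_s2

        g_uu = dense_grad(U, U)
        g_uv = dense_grad(U, V)
        g_vv = dense_grad(V, V)
        g_vu = dense_grad(V, U)
    gU = (2.0 / n1**2) * g_uu - (2.0 / (n1 * n2)) * g_uv
    gV = (2.0 / n2**2) * g_vv - (2.0 / (n1 * n2)) * g_vu
    return gU, gV


def _mmd_value_and_grad(
    U: np.ndarray, V: np.ndarray, sigma: float, streaming: bool, block_size: int
) -> tuple[float, np.ndarray, np.ndarray]:
    """Biased MMD^2 with gradients, sharing kernel passes where possible."""
    global peak_block_elements
    n1, n2 = U.shape[0], V.shape[0]
    if streaming:
        peak_block_elements = 0
        suu, g_uu = _stream_kernel(U, U, sigma, block_size, want_grad=True)
        svv, g_vv = _stream_kernel(V, V, sigma, block_size, want_grad=True)
        suv, g_uv = _stream_kernel(U, V, sigma, block_size, want_grad=True)
        _, g_vu = _stream_kernel(V, U, sigma, block_size, want_grad=True)
    else:
        inv_s2 = 1.0 / (sigma * sigma)
        Kuu = _kernel_block(U, U, sigma)
        Kvv = _kernel_block(V, V, sigma)
        Kuv = _kernel_block(U, V, sigma)
        suu, svv, suv = float(Kuu.sum()), float(Kvv.sum()), float(Kuv.sum())
        g_uu = (Kuu @ U - U * Kuu.sum(axis=1)[:, None]) * inv_s2
        g_vv = (Kvv @ V - V * Kvv.sum(axis=1)[:, None]) * inv_s2
        g_uv = (Kuv @ V - U * Kuv.sum(axis=1)[:, None]) * inv_s2
        g_vu = (Kuv.T @ U - V * Kuv.sum(axis=0)[:, None]) * inv_s2
    value = suu / n1**2 + svv / n2**2 - 2.0 * suv / (n1 * n2)
    gU = (2.0 / n1**2) * g_uu - (2.0 / (n1 * n2)) * g_uv
    gV = (2.0 / n2**2) * g_vv - (2.0 / (n1 * n2)) * g_vu
    return value, gU, gV


def mmd_linear_time(U: np.ndarray, V: np.ndarray, sigma: float = 1.0) -> float:
    """Linear-time MMD^2 estimator over consecutive disjoint pairs.

    Averages h((u_{2i}, v_{2i}), (u_{2i+1}, v_{2i+1})) with
    h = k(u,u') + k(v,v') - k(u,v') - k(u',v) over the n//2 pairs.  It is
    an unbiased estimator of the population MMD^2 when the row order is
    random; the caller is responsible for shuffling.  An odd trailing row
    is dropped with a warning.
    """
    U = np.asarray(U, dtype=np.float64)
    V = np.asarray(V, dtype=np.float64)
    _check_embeddings(U, V, sigma)
    if U.shape[0] != V.shape[0]:
        raise ValueError(
            f"linear-time estimator needs n1 == n2, got {U.shape[0]} != {V.shape[0]}"
        )
    n = U.shape[0]
    if n % 2:
        warnings.warn("odd number of rows; dropping the last row", UserWarning)
        n -= 1
    if n < 2:
        raise ValueError("need at least one pair of rows")
    u, up = U[0:n:2], U[1:n:2]
    v, vp = V[0:n:2], V[1:n:2]
    inv = -1.0 / (2.0 * sigma * sigma)

    def k(a, b):
        return np.exp(np.sum((a - b) ** 2, axis=1) * inv)

    h = k(u, up) + k(v, vp) - k(u, vp) - k(up, v)
    return float(h.mean())


# ---------------------------------------------------------------------------
# penalties and distortion


def penalty_primal(W: np.ndarray) -> float:
    """Non-collapsing penalty ||W^T W - I_d||_F^2."""
    W = np.asarray(W, dtype=np.float64)
    G = W.T @ W - np.eye(W.shape[1])
    return float(np.sum(G * G))


def penalty_primal_grad(W: np.ndarray) -> np.ndarray:
    """d/dW ||W^T W - I||_F^2 = 4 W (W^T W - I)."""
    W = np.asarray(W, dtype=np.float64)
    return 4.0 * W @ (W.T @ W - np.eye(W.shape[1]))


@dataclass
class GramFeatures:
    """Feature-space Gram summaries of one modality: C = X^T X (p x p),
    C2 = C @ C and tr(C^2).  Precomputed once; lets the distortion term
    avoid any n x n intermediate."""

    C: np.ndarray
    C2: np.ndarray
    tr_C2: float

    @classmethod
    def from_matrix(cls, X: np.ndarray) -> "GramFeatures":
        X = np.asarray(X, dtype=np.float64)
        C = X.T @ X
        C = 0.5 * (C + C.T)  # symmetrize against roundoff
        C2 = C @ C
        return cls(C=C, C2=C2, tr_C2=float(np.trace(C2)))


def distortion_primal(
    X: Union[np.ndarray, GramFeatures],
    W: np.ndarray,
    method: str = "efficient",
) -> float:
    """Distortion ||XX^T - X W W^T X^T||_F^2.

    ``method="efficient"`` uses the trace identity
    tr(C^2) - 2 tr(W^T C^2 W) + tr((W^T C W)^2) with C = X^T X, touching
    only p x p and d x d arrays.  ``method="naive"`` forms the n x n
    matrices explicitly (for testing on small inputs).
    """
    W = np.asarray(W, dtype=np.float64)
    if method == "naive":
        if isinstance(X, GramFeatures):
            raise ValueError("naive method needs the raw matrix X")
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != W.shape[0]:
            raise ValueError(f"shape mismatch: X {X.shape} vs W {W.shape}")
        Kx = X @ X.T
        E = X @ W
        R = Kx - E @ E.T
        return float(np.sum(R * R))
    if method != "efficient":
        raise ValueError(f"method must be 'naive' or 'efficient', got {method!r}")
    g = X if isinstance(X, GramFeatures) else GramFeatures.from_matrix(X)
    if g.C.shape[0] != W.shape[0]:
        raise ValueError(f"shape mismatch: C {g.C.shape} vs W {W.shape}")
    WtCW = W.T @ g.C @ W
    return float(g.tr_C2 - 2.0 * np.trace(W.T @ g.C2 @ W) + np.sum(WtCW * WtCW.T))


def distortion_primal_grad(
    X: Union[np.ndarray, GramFeatures], W: np.ndarray
) -> np.ndarray:
    """d/dW of the distortion: -4 C^2 W + 4 C W (W^T C W)."""
    W = np.asarray(W, dtype=np.float64)
    g = X if isinstance(X, GramFeatures) else GramFeatures.from_matrix(X)
    return -4.0 * g.C2 @ W + 4.0 * g.C @ W @ (W.T @ g.C @ W)


def _check_kernel(K: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    K = np.asarray(K, dtype=np.float64)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError(f"K must be square, got {K.shape}")
    scale = max(1.0, float(np.abs(K).max()))
    if np.abs(K - K.T).max() > tol * scale:
        raise ValueError("kernel matrix K is not symmetric")
    return K


def penalty_dual(K: np.ndarray, alpha: np.ndarray) -> float:
    """Dual non-collapsing penalty ||alpha^T K alpha - I_d||_F^2; equals
    the primal penalty at W = X^T alpha when K = XX^T."""
    K = _check_kernel(K)
    alpha = np.asarray(alpha, dtype=np.float64)
    G = alpha.T @ K @ alpha - np.eye(alpha.shape[1])
    return float(np.sum(G * G))


def penalty_dual_grad(K: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    K = _check_kernel(K)
    alpha = np.asarray(alpha, dtype=np.float64)
    return 4.0 * K @ alpha @ (alpha.T @ K @ alpha - np.eye(alpha.shape[1]))


def distortion_dual(K: np.ndarray, alpha: np.ndarray) -> float:
    """Dual distortion ||K - K alpha alpha^T K||_F^2."""
    K = _check_kernel(K)
    alpha = np.asarray(alpha, dtype=np.float64)
    Ka = K @ alpha
    R = K - Ka @ Ka.T
    return float(np.sum(R * R))


def distortion_dual_grad(K: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    K = _check_kernel(K)
    alpha = np.asarray(alpha, dtype=np.float64)
    Ka = K @ alpha
    R = K - Ka @ Ka.T
    return -4.0 * K @ R @ Ka


# ---------------------------------------------------------------------------
# full objective


def median_heuristic_sigma(
    U: np.ndarray, V: np.ndarray, max_rows: int = 2000, seed: int = 0
) -> float:
    """Median pairwise distance among pooled embedding rows, on a
    subsample of at most ``max_rows`` rows; falls back to 1.0 if the
    median is zero (all points coincident)."""
    pooled = np.vstack([np.asarray(U, dtype=np.float64), np.asarray(V, dtype=np.float64)])
    if pooled.shape[0] > max_rows:
        rng = np.random.default_rng(seed)
        pooled = pooled[rng.choice(pooled.shape[0], size=max_rows, replace=False)]
    d2 = _sq_dists(pooled, pooled)
    iu = np.triu_indices(pooled.shape[0], k=1)
    med = float(np.median(np.sqrt(d2[iu])))
    return med if med > 0 else 1.0


def _embeddings_and_grams(x, y, params_x, params_y, hp):
    X, Y = x.values, y.values
    if hp.mode == "primal":
        U = X @ params_x.W
        V = Y @ params_y.W
    else:
        Kx = X @ X.T
        Ky = Y @ Y.T
        U = Kx @ params_x.alpha
        V = Ky @ params_y.alpha
    return U, V


def loss(
    x: ModalityMatrix,
    y: ModalityMatrix,
    params_x: Union[ProjectionPrimal, ProjectionDual],
    params_y: Union[ProjectionPrimal, ProjectionDual],
    hp: Hyperparams,
    sigma: Optional[float] = None,
) -> LossBreakdown:
    """Evaluate all objective components at one parameter state.

    ``sigma`` overrides ``hp.sigma`` (used after the median heuristic has
    been resolved to a number); ``hp.sigma`` must then be numeric.
    """
    s = float(sigma if sigma is not None else hp.sigma)
    if hp.mode == "primal":
        U = x.values @ params_x.W
        V = y.values @ params_y.W
        pen_x = penalty_primal(params_x.W)
        pen_y = penalty_primal(params_y.W)
        dis_x = distortion_primal(x.values, params_x.W)
        dis_y = distortion_primal(y.values, params_y.W)
    else:
        Kx = x.values @ x.values.T
        Ky = y.values @ y.values.T
        U = Kx @ params_x.alpha
        V = Ky @ params_y.alpha
        pen_x = penalty_dual(Kx, params_x.alpha)
        pen_y = penalty_dual(Ky, params_y.alpha)
        dis_x = distortion_dual(Kx, params_x.alpha)
        dis_y = distortion_dual(Ky, params_y.alpha)
    m2 = mmd_squared(U, V, s, streaming=hp.streaming, block_size=hp.block_size,
                     biased=hp.biased_mmd)
    return LossBreakdown.from_components(
        m2, pen_x, pen_y, dis_x, dis_y, hp.lambda1, hp.lambda2
    )


def loss_and_grad(
    x: ModalityMatrix,
    y: ModalityMatrix,
    params_x,
    params_y,
    hp: Hyperparams,
    sigma: float,
    gram_x: Optional[GramFeatures] = None,
    gram_y: Optional[GramFeatures] = None,
    kernel_x: Optional[np.ndarray] = None,
    kernel_y: Optional[np.ndarray] = None,
) -> tuple[LossBreakdown, np.ndarray, np.ndarray]:
    """Objective value plus gradients with respect to the parameters of
    each modality (W's in primal mode, alpha's in dual mode).

    Gram/kernel caches may be passed in by the solver so they are built
    once per fit rather than once per iteration.
    """
    if hp.mode == "primal":
        gx = gram_x if gram_x is not None else GramFeatures.from_matrix(x.values)
        gy = gram_y if gram_y is not None else GramFeatures.from_matrix(y.values)
        Wx, Wy = params_x.W, params_y.W
        U = x.values @ Wx
        V = y.values @ Wy
        m2, gU, gV = _mmd_value_and_grad(U, V, sigma, hp.streaming, hp.block_size)
        pen_x, pen_y = penalty_primal(Wx), penalty_primal(Wy)
        dis_x = distortion_primal(gx, Wx)
        dis_y = distortion_primal(gy, Wy)
        grad_x = (
            x.values.T @ gU
            + hp.lambda1 * penalty_primal_grad(Wx)
            + hp.lambda2 * distortion_primal_grad(gx, Wx)
        )
        grad_y = (
            y.values.T @ gV
            + hp.lambda1 * penalty_primal_grad(Wy)
            + hp.lambda2 * distortion_primal_grad(gy, Wy)
        )
    else:
        Kx = kernel_x if kernel_x is not None else x.values @ x.values.T
        Ky = kernel_y if kernel_y is not None else y.values @ y.values.T
        ax, ay = params_x.alpha, params_y.alpha
        U = Kx @ ax
        V = Ky @ ay
        m2, gU, gV = _mmd_value_and_grad(U, V, sigma, hp.streaming, hp.block_size)
        pen_x, pen_y = penalty_dual(Kx, ax), penalty_dual(Ky, ay)
        dis_x, dis_y = distortion_dual(Kx, ax), distortion_dual(Ky, ay)
        grad_x = (
            Kx @ gU
            + hp.lambda1 * penalty_dual_grad(Kx, ax)
            + hp.lambda2 * distortion_dual_grad(Kx, ax)
        )
        grad_y = (
            Ky @ gV
            + hp.lambda1 * penalty_dual_grad(Ky, ay)
            + hp.lambda2 * distortion_dual_grad(Ky, ay)
        )
    bd = LossBreakdown.from_components(
        m2, pen_x, pen_y, dis_x, dis_y, hp.lambda1, hp.lambda2
    )
    return bd, grad_x, grad_y
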