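"""Full-batch first-order minimization of the alignment objective.

One "epoch" is one full-batch Adam step on the concatenated parameters
of both modalities (W's in primal mode, alpha's in dual mode).  The
fit is deterministic given the seed: initialization is the only random
ingredient, and every evaluation path (streaming or not) is pure numpy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .data_model import (
    Hyperparams,
    ModalityMatrix,
    ProjectionDual,
    ProjectionPrimal,
    TrainingTrace,
    validate_pair,
)
from .losses import (
    GramFeatures,
    loss_and_grad,
    median_heuristic_sigma,
)
from .metrics import foscttm

__all__ = ["FitResult", "init_params", "fit", "fit_restarts", "embed"]

# FOSCTTM during training is computed on at most this many cells; the
# final trace entry uses all cells.
FOSCTTM_SUBSAMPLE = 1000


@dataclass
class FitResult:
    """Fitted parameters, final embeddings and the training trace."""

    params_x: Union[ProjectionPrimal, ProjectionDual]
    params_y: Union[ProjectionPrimal, ProjectionDual]
    embedding_x: np.ndarray
    embedding_y: np.ndarray
    trace: TrainingTrace
    hp_used: Hyperparams
    sigma_used: float


def init_params(
    shape: tuple[int, int], seed, mode: str = "primal"
) -> Union[ProjectionPrimal, ProjectionDual]:
    """Random initial parameters.

    Entries are i.i.d. Normal(0, 1/p) for a primal W of shape (p, d) and
    Normal(0, 1/n) for a dual alpha of shape (n, d), so initial
    embeddings have comparable scale across feature counts.
    Deterministic given the seed.
    """
    rows, d = shape
    rng = np.random.default_rng(seed)
    M = rng.standard_normal((rows, d)) / np.sqrt(rows)
    if mode == "primal":
        return ProjectionPrimal(M)
    if mode == "dual":
        return ProjectionDual(M)
    raise ValueError(f"mode must be 'primal' or 'dual', got {mode!r}")


class _Adam:
    """Plain Adam over a list of arrays updated in place."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def embed(
    x: ModalityMatrix, params: Union[ProjectionPrimal, ProjectionDual]
) -> np.ndarray:
    """Embedding of a modality: X W (primal) or (XX^T) alpha (dual)."""
    if isinstance(params, ProjectionPrimal):
        if x.p != params.W.shape[0]:
            raise ValueError(
                f"feature mismatch: X has p={x.p}, W has {params.W.shape[0]} rows"
            )
        return x.values @ params.W
    if x.n != params.alpha.shape[0]:
        raise ValueError(
            f"cell mismatch: X has n={x.n}, alpha has {params.alpha.shape[0]} rows"
        )
    return x.values @ (x.values.T @ params.alpha)


def _subsample_foscttm(U: np.ndarray, V: np.ndarray, rng: np.random.Generator,
                       max_cells: int = FOSCTTM_SUBSAMPLE) -> float:
    n = U.shape[0]
    if n <= max_cells:
        return foscttm(U, V).mean
    idx = rng.choice(n, size=max_cells, replace=False)
    return foscttm(U[idx], V[idx]).mean


def fit(
    x: ModalityMatrix,
    y: ModalityMatrix,
    hp: Hyperparams,
    correspondence: Optional[bool] = None,
    init_x: Optional[Union[ProjectionPrimal, ProjectionDual]] = None,
    init_y: Optional[Union[ProjectionPrimal, ProjectionDual]] = None,
) -> FitResult:
    """Minimize the alignment objective over both modality maps.

    Runs ``hp.n_iter`` full-batch Adam steps, recording the loss
    breakdown (and FOSCTTM, when a row correspondence is available and
    not disabled via ``correspondence=False``) every ``hp.eval_interval``
    iterations, always including iteration 0 and the final state.
    ``init_x``/``init_y`` override the seeded random initialization
    (used e.g. to start primal and dual runs from equivalent points).
    """
    x, y, corr_possible = validate_pair(x, y, hp)
    track_corr = corr_possible if correspondence is None else (correspondence and corr_possible)

    seeds = np.random.SeedSequence(hp.seed).spawn(3)
    if init_x is None:
        rows = x.p if hp.mode == "primal" else x.n
        init_x = init_params((rows, hp.d), seeds[0], hp.mode)
    if init_y is None:
        rows = y.p if hp.mode == "primal" else y.n
        init_y = init_params((rows, hp.d), seeds[1], hp.mode)
    sub_rng = np.random.default_rng(seeds[2])

    if hp.mode == "primal":
        arrs = [init_x.W.copy(), init_y.W.copy()]
        wrap = ProjectionPrimal
        gram_x = GramFeatures.from_matrix(x.values)
        gram_y = GramFeatures.from_matrix(y.values)
        kernel_x = kernel_y = None
    else:
        arrs = [init_x.alpha.copy(), init_y.alpha.copy()]
        wrap = ProjectionDual
        gram_x = gram_y = None
        kernel_x = x.values @ x.values.T
        kernel_y = y.values @ y.values.T

    # resolve the bandwidth once, on the initial embeddings
    if hp.sigma == "median":
        U0 = embed(x, wrap(arrs[0]))
        V0 = embed(y, wrap(arrs[1]))
        sigma = median_heuristic_sigma(U0, V0, seed=int(seeds[2].generate_state(1)[0] % 2**31))
    else:
        sigma = float(hp.sigma)

    opt = _Adam(arrs, lr=hp.learning_rate)
    trace = TrainingTrace()

    def evaluate(iteration: int, bd) -> None:
        fos = None
        if track_corr:
            U = embed(x, wrap(arrs[0]))
            V = embed(y, wrap(arrs[1]))
            if iteration == hp.n_iter:
                fos = foscttm(U, V).mean
            else:
                fos = _subsample_foscttm(U, V, sub_rng)
        trace.record(iteration, bd, fos)

    for it in range(hp.n_iter + 1):
        bd, gx, gy = loss_and_grad(
            x, y, wrap(arrs[0]), wrap(arrs[1]), hp, sigma,
            gram_x=gram_x, gram_y=gram_y, kernel_x=kernel_x, kernel_y=kernel_y,
        )
        if not np.isfinite(bd.total):
            comps = {k: v for k, v in bd.as_dict().items() if not np.isfinite(v)}
            raise FloatingPointError(
                f"non-finite loss at iteration {it}: {comps} "
                f"(try a smaller learning rate or larger sigma)"
            )
        if it % hp.eval_interval == 0 or it == hp.n_iter:
            evaluate(it, bd)
        if it == hp.n_iter:
            break
        opt.step([gx, gy])

    params_x, params_y = wrap(arrs[0]), wrap(arrs[1])
    return FitResult(
        params_x=params_x,
        params_y=params_y,
        embedding_x=embed(x, params_x),
        embedding_y=embed(y, params_y),
        trace=trace,
        hp_used=hp,
        sigma_used=sigma,
    )


def fit_restarts(
    x: ModalityMatrix,
    y: ModalityMatrix,
    hp: Hyperparams,
    n_restarts: int = 8,
    correspondence: Optional[bool] = None,
) -> FitResult:
    """Run :func:`fit` from ``n_restarts`` random initializations and
    return the run with the lowest final total loss.

    The objective is non-convex: runs started in different basins can
    converge to distributionally similar but wrongly matched embeddings.
    Those runs end at a visibly higher objective, so selecting the best
    final loss is an unsupervised way to pick the aligned solution — no
    correspondence information is used for selection.  Deterministic
    given ``hp.seed``.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    seeds = np.random.SeedSequence(hp.seed).spawn(n_restarts)
    best: Optional[FitResult] = None
    for s in seeds:
        run_seed = int(s.generate_state(1)[0] % 2**31)
        res = fit(x, y, hp.with_(seed=run_seed), correspondence=correspondence)
        if best is None or res.trace.losses[-1].total < best.trace.losses[-1].total:
            best = res
    return best
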