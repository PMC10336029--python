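"""Core containers shared across the package.

The method operates on two cell-by-feature matrices, one per modality
(e.g. gene expression and surface-protein counts measured on overlapping
cell populations).  Rows are cells, columns are features.  The learnable
map into the shared d-dimensional space is stored either as a primal
weight matrix W (features x d) or as dual coefficients alpha (cells x d);
the two are related by W = X^T alpha for a linear kernel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "ModalityMatrix",
    "ProjectionPrimal",
    "ProjectionDual",
    "Hyperparams",
    "LossBreakdown",
    "TrainingTrace",
    "validate_pair",
    "ConfigError",
    "LoadError",
]

# Tolerance for the analytically-nonnegative biased MMD^2 estimator: float
# roundoff can push a true zero slightly negative.
MMD_NONNEG_TOL = 1e-9

# Densifying a sparse input above this many entries triggers a warning.
DENSIFY_WARN_ENTRIES = 50_000_000


class ConfigError(ValueError):
    """Invalid hyperparameter or generator configuration."""


class LoadError(ValueError):
    """Input matrix violates a structural invariant (NaN/Inf, bad ids)."""


def _as_id_array(ids: Sequence[str], n: int, prefix: str) -> np.ndarray:
    if ids is None:
        width = max(4, len(str(n)))
        return np.array([f"{prefix}_{i:0{width}d}" for i in range(n)], dtype=object)
    arr = np.asarray(ids, dtype=object)
    if arr.shape != (n,):
        raise LoadError(f"expected {n} {prefix} ids, got shape {arr.shape}")
    if len(set(arr.tolist())) != n:
        raise LoadError(f"{prefix} ids are not unique")
    return arr


@dataclass
class ModalityMatrix:
    """One modality's cell x feature matrix with row/column identifiers.

    Sparse inputs are densified up front: the solver's own scaling
    assumption is n >> p >> d, so the dense n x p array is the small
    object in the room (the thing that must never be materialized is
    anything n x n).
    """

    values: np.ndarray
    cell_ids: Optional[Sequence[str]] = None
    feature_ids: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        v = self.values
        if sp.issparse(v):
            if v.shape[0] * v.shape[1] > DENSIFY_WARN_ENTRIES:
                warnings.warn(
                    f"densifying a {v.shape[0]}x{v.shape[1]} sparse matrix "
                    f"(~{8 * v.shape[0] * v.shape[1] / 1e9:.1f} GB dense)",
                    ResourceWarning,
                )
            v = v.toarray()
        v = np.asarray(v, dtype=np.float64)
        if v.ndim != 2:
            raise LoadError(f"modality matrix must be 2-D, got ndim={v.ndim}")
        if v.shape[0] < 1 or v.shape[1] < 1:
            raise LoadError(f"modality matrix must be at least 1x1, got {v.shape}")
        if not np.isfinite(v).all():
            bad = int(np.size(v) - np.isfinite(v).sum())
            raise LoadError(f"modality matrix contains {bad} non-finite entries")
        self.values = v
        self.cell_ids = _as_id_array(self.cell_ids, v.shape[0], "cell")
        self.feature_ids = _as_id_array(self.feature_ids, v.shape[1], "feat")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def standardized(self) -> "ModalityMatrix":
        """Per-feature zero mean / unit variance copy (constant features
        are centered only)."""
        v = self.values
        mu = v.mean(axis=0)
        sd = v.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        return ModalityMatrix((v - mu) / sd, self.cell_ids, self.feature_ids)

    def kernel_normalized(self) -> "ModalityMatrix":
        """Copy rescaled so the linear kernel has unit Frobenius norm:
        X / sqrt(||X X^T||_F), computed via the p x p Gram matrix.

        With both modalities on this scale the matching, non-collapsing
        and distortion terms are commensurate, so one set of penalty
        weights transfers across datasets.
        """
        v = self.values
        s = float(np.sqrt(np.linalg.norm(v.T @ v)))
        if s == 0:
            raise LoadError("cannot kernel-normalize an all-zero matrix")
        return ModalityMatrix(v / s, self.cell_ids, self.feature_ids)


@dataclass
class ProjectionPrimal:
    """Primal map parameters W (p features x d latent dims)."""

    W: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=np.float64)
        if W.ndim != 2 or W.shape[1] < 1:
            raise ConfigError(f"W must be 2-D with d >= 1, got shape {W.shape}")
        if not np.isfinite(W).all():
            raise ConfigError("W contains non-finite entries")
        self.W = W

    @property
    def d(self) -> int:
        return self.W.shape[1]


@dataclass
class ProjectionDual:
    """Dual map parameters alpha (n cells x d latent dims); the implied
    primal map is W = X^T alpha."""

    alpha: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha, dtype=np.float64)
        if a.ndim != 2 or a.shape[1] < 1:
            raise ConfigError(f"alpha must be 2-D with d >= 1, got shape {a.shape}")
        if not np.isfinite(a).all():
            raise ConfigError("alpha contains non-finite entries")
        self.alpha = a

    @property
    def d(self) -> int:
        return self.alpha.shape[1]


@dataclass
class Hyperparams:
    """Training configuration.

    d              latent dimension of the shared space
    lambda1        weight of the non-collapsing penalty ||W^T W - I||_F^2
    lambda2        weight of the distortion penalty ||XX^T - XWW^T X^T||_F^2
                   (both penalties are unnormalized Frobenius norms; the
                   defaults assume kernel-normalized inputs, see
                   ModalityMatrix.kernel_normalized)
    sigma          RBF bandwidth, or "median" for the median-distance
                   heuristic evaluated on the initial embeddings
    n_iter         number of full-batch optimizer steps ("epochs")
    learning_rate  Adam step size
    mode           "primal" (parameters W) or "dual" (parameters alpha)
    streaming      compute MMD terms blockwise, never allocating n x n
    block_size     rows per block in streaming reductions
    eval_interval  iterations between trace records
    biased_mmd     V-statistic (includes self-pairs, nonnegative) if True,
                   else the unbiased U-statistic
    """

    d: int = 10
    lambda1: float = 1.0
    lambda2: float = 0.1
    sigma: float | str = 1.0
    n_iter: int = 500
    learning_rate: float = 1e-3
    seed: int = 0
    mode: str = "primal"
    streaming: bool = True
    block_size: int = 4096
    eval_interval: int = 50
    biased_mmd: bool = True

    def __post_init__(self) -> None:
        if int(self.d) < 1:
            raise ConfigError(f"latent dimension d must be >= 1, got {self.d}")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ConfigError("lambda1 and lambda2 must be nonnegative")
        if isinstance(self.sigma, str):
            if self.sigma != "median":
                raise ConfigError(f"sigma must be a positive number or 'median', got {self.sigma!r}")
        elif not self.sigma > 0:
            raise ConfigError(f"sigma must be > 0, got {self.sigma}")
        if int(self.n_iter) < 0:
            raise ConfigError("n_iter must be >= 0")
        if not self.learning_rate > 0:
            raise ConfigError("learning_rate must be > 0")
        if self.mode not in ("primal", "dual"):
            raise ConfigError(f"mode must be 'primal' or 'dual', got {self.mode!r}")
        if int(self.block_size) < 1:
            raise ConfigError("block_size must be >= 1")
        if int(self.eval_interval) < 1:
            raise ConfigError("eval_interval must be >= 1")

    def with_(self, **kwargs) -> "Hyperparams":
        return replace(self, **kwargs)


@dataclass
class LossBreakdown:
    """All components of the objective at one parameter state.

    total = mmd2 + lambda1*(pen_x + pen_y) + lambda2*(dis_x + dis_y)
    """

    mmd2: float
    pen_x: float
    pen_y: float
    dis_x: float
    dis_y: float
    total: float

    def __post_init__(self) -> None:
        if self.mmd2 < -MMD_NONNEG_TOL:
            raise ValueError(f"biased MMD^2 estimate is negative: {self.mmd2}")
        for name in ("pen_x", "pen_y", "dis_x", "dis_y"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    @classmethod
    def from_components(
        cls, mmd2: float, pen_x: float, pen_y: float, dis_x: float, dis_y: float,
        lambda1: float, lambda2: float,
    ) -> "LossBreakdown":
        total = mmd2 + lambda1 * (pen_x + pen_y) + lambda2 * (dis_x + dis_y)
        return cls(float(mmd2), float(pen_x), float(pen_y),
                   float(dis_x), float(dis_y), float(total))

    def as_dict(self) -> dict:
        return {
            "mmd2": self.mmd2, "pen_x": self.pen_x, "pen_y": self.pen_y,
            "dis_x": self.dis_x, "dis_y": self.dis_y, "total": self.total,
        }


@dataclass
class TrainingTrace:
    """Per-interval loss components (and FOSCTTM when a known 1-1
    correspondence allows it) recorded during optimization."""

    iterations: list[int] = field(default_factory=list)
    losses: list[LossBreakdown] = field(default_factory=list)
    foscttm: Optional[list[float]] = None

    def record(self, iteration: int, loss: LossBreakdown,
               foscttm: Optional[float] = None) -> None:
        if self.iterations and iteration <= self.iterations[-1]:
            raise ValueError("trace iterations must be strictly increasing")
        self.iterations.append(int(iteration))
        self.losses.append(loss)
        if foscttm is not None:
            if self.foscttm is None:
                self.foscttm = []
            self.foscttm.append(float(foscttm))

    def __len__(self) -> int:
        return len(self.iterations)


def validate_pair(
    x: ModalityMatrix, y: ModalityMatrix, hp: Hyperparams
) -> tuple[ModalityMatrix, ModalityMatrix, bool]:
    """Check a modality pair against the hyperparameters.

    Returns ``(x, y, correspondence_enabled)``: row-level evaluation of
    matching quality is only possible when both modalities have the same
    number of cells (row i of X assumed to match row i of Y).
    """
    if hp.d > min(x.p, y.p):
        warnings.warn(
            f"latent dimension d={hp.d} exceeds min(px, py)="
            f"{min(x.p, y.p)}; the maps cannot have full column rank",
            UserWarning,
        )
    return x, y, x.n == y.n
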