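"""Paired-modality simulator with a branch-shaped shared latent space.

The generator mimics the geometry of a branching differentiation
trajectory: cells live on a small number of line segments ("branches")
radiating from a common origin in a low-dimensional latent space, with
isotropic Gaussian jitter.  Each modality observes the same latent cells
through its own random linear map plus measurement noise, so the two
matrices share structure but not features, and row i of X is the same
cell as row i of Y — the ground-truth correspondence used by FOSCTTM.

What this emulates: a shared low-dimensional manifold seen through two
linear, noisy assays.  What it does not emulate: count statistics
(negative binomial noise, dropout), batch effects, or partially
overlapping cell populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .data_model import ConfigError, ModalityMatrix

__all__ = [
    "PairConfig",
    "SyntheticPair",
    "generate_branch_latent",
    "project_modality",
    "make_pair",
]


@dataclass
class PairConfig:
    """Knobs of the simulator.

    n               cells per modality (shared, correspondence is row order)
    d_latent        latent dimensionality
    n_branches      number of branches radiating from the origin
    latent_noise_sd isotropic jitter around the branch skeleton
    noise_sd_x/y    measurement noise added after each linear projection
    px, py          observed feature counts per modality
    branch_length   length of each branch segment
    """

    n: int = 300
    d_latent: int = 5
    n_branches: int = 3
    px: int = 50
    py: int = 40
    latent_noise_sd: float = 0.05
    noise_sd_x: float = 0.1
    noise_sd_y: float = 0.1
    branch_length: float = 1.0
    seed: int = 0


@dataclass
class SyntheticPair:
    """Two matched modality matrices plus the latent ground truth."""

    x: ModalityMatrix
    y: ModalityMatrix
    latent: np.ndarray
    branch_labels: np.ndarray
    gen_params: dict = field(default_factory=dict)


def generate_branch_latent(
    n: int,
    d_latent: int,
    n_branches: int = 3,
    noise_sd: float = 0.05,
    seed: int = 0,
    branch_length: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample n latent cells on a star of ``n_branches`` segments.

    Branch directions are fixed random unit vectors (drawn once from the
    seed); cells are assigned to branches round-robin so sizes differ by
    at most one; position along branch k is Uniform(0, L_k) with branch
    lengths L_k spread evenly over [0.6, 1.4] * branch_length; Gaussian
    jitter with sd ``noise_sd`` is added isotropically.  Distinct branch
    lengths keep the point-cloud distribution asymmetric under branch
    permutation, so the true cross-modality matching is identifiable —
    with equal lengths, a linear map permuting same-length branches
    would leave the embedding distribution (hence the matching term)
    unchanged.  Returns ``(latent, branch_labels)``.
    """
    if n < 1 or d_latent < 1 or n_branches < 1:
        raise ConfigError(
            f"n, d_latent, n_branches must be >= 1, got {n}, {d_latent}, {n_branches}"
        )
    if noise_sd < 0:
        raise ConfigError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = np.random.default_rng(seed)
    dirs = rng.standard_normal((n_branches, d_latent))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    if n_branches == 1:
        lengths = np.array([branch_length])
    else:
        lengths = branch_length * np.linspace(0.6, 1.4, n_branches)
    labels = np.arange(n) % n_branches
    t = rng.uniform(0.0, 1.0, size=n) * lengths[labels]
    latent = t[:, None] * dirs[labels]
    if noise_sd > 0:
        latent = latent + rng.normal(0.0, noise_sd, size=latent.shape)
    return latent, labels


def project_modality(
    latent: np.ndarray,
    p: int,
    noise_sd: float = 0.1,
    seed: int = 0,
    prefix: str = "feat",
) -> ModalityMatrix:
    """Observe the latent cells through a random linear map into R^p.

    Returns ``latent @ A.T + E`` with A a p x d_latent matrix of i.i.d.
    standard normals and E i.i.d. Normal(0, noise_sd^2).  Row order (and
    hence the cell correspondence) is preserved.
    """
    latent = np.asarray(latent, dtype=np.float64)
    d_latent = latent.shape[1]
    if p < d_latent:
        raise ConfigError(f"p={p} must be >= d_latent={d_latent}")
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((p, d_latent))
    values = latent @ A.T
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    feature_ids = [f"{prefix}_{j:04d}" for j in range(p)]
    return ModalityMatrix(values, feature_ids=feature_ids)


def make_pair(config: PairConfig | None = None, **overrides) -> SyntheticPair:
    """Generate a matched two-modality dataset from one config.

    The latent draw and the two modality projections use seeds derived
    from ``config.seed`` via independent spawns, so modality noise can be
    varied while holding the latent geometry fixed.
    """
    cfg = config if config is not None else PairConfig()
    if overrides:
        cfg = PairConfig(**{**asdict(cfg), **overrides})
    seeds = np.random.SeedSequence(cfg.seed).spawn(3)
    latent, labels = generate_branch_latent(
        cfg.n,
        cfg.d_latent,
        cfg.n_branches,
        noise_sd=cfg.latent_noise_sd,
        seed=seeds[0],
        branch_length=cfg.branch_length,
    )
    x = project_modality(latent, cfg.px, cfg.noise_sd_x, seed=seeds[1], prefix="fx")
    y = project_modality(latent, cfg.py, cfg.noise_sd_y, seed=seeds[2], prefix="fy")
    # both modalities describe the same cells: share the row identifiers
    y.cell_ids = x.cell_ids.copy()
    return SyntheticPair(
        x=x, y=y, latent=latent, branch_labels=labels, gen_params=asdict(cfg)
    )
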