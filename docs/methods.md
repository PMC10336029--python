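# Methods

## Objective

Given two cell × feature matrices `X` (nx×px) and `Y` (ny×py), the
package learns linear maps `Wx` (px×d), `Wy` (py×d) by full-batch
minimization of

```
L = MMD²(XWx, YWy) + λ₁(pen(Wx)+pen(Wy)) + λ₂(dis(X,Wx)+dis(Y,Wy))
```

with `pen(W) = ‖WᵀW − I_d‖²_F` and `dis(X,W) = ‖XXᵀ − XWWᵀXᵀ‖²_F`.
The matching term uses the Gaussian RBF kernel
`k(a,b) = exp(−‖a−b‖²/2σ²)` and, by default, the biased V-statistic

```
MMD² = n₁⁻²Σᵢⱼ k(uᵢ,uⱼ) + n₂⁻²Σᵢⱼ k(vᵢ,vⱼ) − 2(n₁n₂)⁻¹Σᵢⱼ k(uᵢ,vⱼ),
```

which is nonnegative by construction (the unbiased U-statistic is
available via `biased_mmd=False`). The assumption underlying the whole
design is `n ≫ p ≫ d`: many cells, moderately many informative
features, a small shared space.

### Primal and dual parameterizations

With a linear kernel the map can also be written `W = Xᵀα`,
`α ∈ R^{n×d}`, giving embeddings `XXᵀα = Kα`. Both modes are
implemented; at matched parameters (`W = Xᵀα`) every loss component is
identical, and the test suite asserts this to 1e−8 relative. The dual
mode materializes `K = XXᵀ` (it is inherently O(n²)) and exists for
cross-validation of the primal path and for small-n work; the primal
mode never forms an n×n matrix:

* penalties/distortion go through `C = XᵀX` (p×p) using
  `dis = tr(C²) − 2 tr(WᵀC²W) + tr((WᵀCW)²)`;
* the MMD value and gradient are accumulated over row blocks of at most
  `block_size` rows (default 4096), so the largest temporary is
  `block_size²` regardless of n. The streaming and dense paths agree to
  1e−10 relative; the streaming code records its largest temporary so
  tests can assert the contract.

Note the two parameterizations are *not* equivalent as optimization
trajectories: a first-order step in α-space corresponds to a
K-preconditioned step in W-space, so primal and dual runs from
equivalent starting points share the iteration-0 objective but then
follow different (both valid) descent paths.

### Gradients

All gradients are closed-form and tested against central finite
differences (h = 1e−5, 1e−5 relative):

```
∂MMD²/∂uᵢ  = (2/n₁²) Σⱼ ∂k(uᵢ,uⱼ)/∂uᵢ − (2/n₁n₂) Σⱼ ∂k(uᵢ,vⱼ)/∂uᵢ,
∂k(a,b)/∂a = −((a−b)/σ²) k(a,b)
∂pen/∂W    = 4W(WᵀW−I)
∂dis/∂W    = −4C²W + 4CW(WᵀCW)
```

with `∂MMD²/∂W = Xᵀ ∂MMD²/∂U` (primal) and `K ∂MMD²/∂U` (dual).

### Linear-time MMD estimator

`mmd_linear_time` averages
`h = k(u,u′)+k(v,v′)−k(u,v′)−k(u′,v)` over consecutive disjoint row
pairs. Over random joint shuffles of a fixed sample its expectation is
exactly the full U-statistic on that sample; the tests verify the mean
over 200 shuffles lands within 3 Monte-Carlo SE.

## Optimization

Full-batch Adam (β = 0.9/0.999, ε = 1e−8) over both modalities'
parameters jointly; one "epoch" = one full-batch step. Initialization
is i.i.d. Normal(0, 1/p) for W (1/n for α). No early stopping: the
iteration count is fixed (default 500). Runs are deterministic given
the seed; a non-finite objective aborts with the iteration and the
offending component named.

The objective is non-convex and has distributionally-plausible but
wrongly-matched local minima (e.g. branch-permuted embeddings).
`fit_restarts` runs several seeds and keeps the lowest **final total
loss** — an unsupervised criterion; in our experiments the lowest-loss
restart was always a correctly aligned one. Eight restarts are the
default in the acceptance pipeline.

### Bandwidth

σ defaults to 1.0; `sigma="median"` evaluates the median pairwise
distance of the pooled *initial* embeddings (subsampled to ≤2000 rows)
once, at iteration 0. The bandwidth is then fixed for the whole run.

### Preprocessing

`ModalityMatrix.kernel_normalized()` rescales a modality by
`sqrt(‖XXᵀ‖_F)` (computed via the p×p Gram matrix) so its linear kernel
has unit Frobenius norm. Because `pen` and `dis` are unnormalized
Frobenius norms, this puts MMD², penalty and distortion on commensurate
scales, which makes one set of weights (λ₁ = 1, λ₂ = 0.1) transfer
across datasets; without it λ₂ must be retuned per dataset to offset
`tr(C²)` being arbitrarily large. The CLI applies this normalization by
default (`--no-normalize` to disable); per-feature standardization is
available but not mandated.

## Synthetic data generator

`make_pair` emulates a branching differentiation geometry observed
through two assays:

1. **Latent**: `n_branches` (default 3) unit directions drawn once in
   `R^{d_latent}` (default 5); cells assigned round-robin; position
   along branch k is Uniform(0, L_k); isotropic Gaussian jitter
   (sd 0.05 by default).
2. **Branch lengths** L_k are spread over [0.6, 1.4] (× a global
   scale). This is deliberate: with equal lengths the latent point
   cloud is distribution-invariant under linear maps that permute
   branches, so the matching term cannot identify the true
   correspondence and wrongly matched solutions are near-global
   minima. Distinct lengths make the distribution asymmetric under
   permutation and the matching identifiable.
3. **Modalities**: `latent @ Aᵀ + E` with `A` a p×d_latent standard-
   normal map and `E` i.i.d. Normal(0, 0.1²) by default — px = 50,
   py = 40 at the defaults. Latent draw and the two projections use
   independently spawned seeds so noise can vary with geometry held
   fixed.

What the generator does **not** emulate: count statistics (negative
binomial noise, dropout), batch effects, nonlinear feature responses,
or partially overlapping populations. Passing tests on this generator
demonstrate that the optimization recovers a shared linear latent
structure; they do not certify performance on real assay data, where
preprocessing and feature selection dominate.

## Evaluation

FOSCTTM: for each cell, the fraction of opposite-modality cells
strictly closer (Euclidean) than its true match, denominator n−1,
averaged over cells and then over both directions. Strict "closer"
makes 0 attainable and leaves the continuous-case random baseline at
exactly 0.5. Distances are computed in row blocks (block × n, never
n×n). During training FOSCTTM is evaluated on a ≤1000-cell subsample;
the final trace entry uses all cells.

## Numerical choices

* float64 throughout; squared distances computed via the
  ‖a‖²+‖b‖²−2ab expansion and clipped at 0.
* In FOSCTTM the true-match column is excluded from the comparison
  explicitly, because comparing a distance against itself computed by a
  different summation order can differ by 1 ulp.
* Biased-MMD nonnegativity is asserted with a 1e−9 absolute tolerance.
* Gram matrices are symmetrized (`(C+Cᵀ)/2`) against roundoff; dual
  kernels must be symmetric within 1e−8 relative or are rejected.
* Streaming and dense reductions are held to 1e−10 relative agreement,
  primal/dual identities to 1e−8, in the tests.

## Default problem sizes

The shipped tests and the acceptance script run the end-to-end recovery
at n = 300 cells per modality (px = 50, py = 40, d = 5, 500
iterations, 6–8 restarts) and exercise the streaming memory contract at
n = 20 000 (p = 50, d = 10, two iterations, block 2048) — sizes chosen
so the full pipeline, including the O(n²/block) streamed kernel passes,
completes comfortably on a single CPU while still being two orders of
magnitude above the feature dimension. Larger n changes cost, not code
paths.

## Known limitations

* Linear maps only; no kernelized/nonlinear extension.
* Two modalities; no multi-way integration.
* Full-batch only; no minibatch MMD training.
* Hyperparameters (λ₁, λ₂, σ, learning rate) interact with data scale;
  the provided defaults assume kernel-normalized inputs.
* The restart heuristic selects by final loss; on data where a
  mismatched solution attains a genuinely lower objective (e.g. highly
  symmetric populations) it will select it — this is a property of the
  objective, not of the implementation.
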