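# Methods

## The factorization

Let `K1` (n1×n1) and `K2` (n2×n2) be symmetric positive semidefinite
kernels and `ID1`, `ID2` length-n label vectors mapping observations to
kernel rows (equivalently, incidence matrices `Z1`, `Z2`). The target is
the interaction kernel `K = (Z1 K1 Z1') ∘ (Z2 K2 Z2')`, an n×n submatrix of
`K1 ⊗ K2`. From `K1 = V1 D1 V1'` and `K2 = V2 D2 V2'`, every candidate
basis vector is

```
w_k = (Z1 v1_i) ∘ (Z2 v2_j),    d̃_k = d1_i d2_j,    k ↔ (i, j)
```

i.e. row-indexed factor eigenvectors multiplied elementwise. For balanced
full crossings the `w_k` are the Kronecker eigenvectors (orthonormal,
eigenvalues `d̃_k`). Under replication/unbalance they lose unit norm and
orthogonality but remain a spanning set for `K`.

**Eigenvalue rescaling.** Each vector is renormalized, `u_k = w_k/‖w_k‖`,
and its value rescaled to `d*_k = d̃_k ‖w_k‖²`. This is the only scaling
under which the identity `Σ_k d*_k u_k u_k' = K` holds exactly, and with it
`Σ_k d*_k = trace(K)`; both are verified to 1e-8/1e-10 relative tolerance in
the test suite. The raw Kronecker values `d̃_k` (whose sum does not equal
`trace(K)` under unbalance) remain available via `rescale=False`, and the
basis can be ordered by raw values via `order_by="raw"`; the rescaled form
is the default because replication genuinely reorders how much variance a
candidate carries.

**Truncation.** Candidates are generated lazily in blocks (default 512
vectors) in descending raw-value order and accumulated until the rescaled
sum reaches `α·trace(K)`, where `trace(K)` is computed in O(n) from the
kernel diagonals. Because rescaling can reorder candidates within the
materialized set, the set is re-sorted by `d*` before the final cut at the
smallest p meeting the target — so `alpha_achieved ≥ α` always holds for
α < 1 (at α = 1 the sum equals the trace up to roundoff). Candidates whose
unmaterialized raw value is small could in principle carry a large norm
under extreme replication; the contract is the variance target, not an
optimal-p guarantee. `α = 1` returns every candidate with positive value —
for unbalanced designs this can exceed `rank(K)`, since the basis is built
for the enclosing Kronecker space.

**Numerical conventions.**

- Factor eigenvalues in `[−clamp_tol·λmax, 0)` are clamped to zero
  (default `clamp_tol = 1e-8`); anything more negative raises a
  not-positive-semidefinite error. Nonnegative values at or below
  `clamp_tol·λmax` are also set to exact zero so that "positive eigenvalue"
  is meaningful for rank accounting.
- Eigenvector signs are fixed so each column's largest-magnitude entry is
  positive, making outputs reproducible across linear-algebra backends.
- Ties among equal values break by (value descending, i ascending,
  j ascending) with stable sorts; outputs are byte-stable given inputs.
- Zero-norm candidates (an eigenvector with zeros at every sampled
  position) are dropped with a debug log line; they span nothing.
- Label matching is exact, case-sensitive string equality through a
  label→index table built once per kernel.

## Metrics

`frobenius_distance(A, B) = ‖A − B‖_F` and the correlation matrix distance
`CMD(A, B) = 1 − tr(AB)/(‖A‖_F‖B‖_F)`, the standard scale-invariant
dissimilarity for covariance structures (0 iff proportional, 1 for
orthogonal supports). CMD is computed on the raw relationship matrices,
uncentered. When a comparison matrix is identically zero (empty basis), the
comparison report returns CMD = 1 with a `degenerate` flag instead of
raising, so parameter sweeps never crash. `rank_count` counts eigenvalues
above `rel_tol·λmax` with the dimension-aware default `rel_tol = 1e-10·n`,
since "positive eigenvalue" is numerically meaningless without a cutoff.

## Simulators

The generators emulate an unbalanced multi-environment trial:

- `simulate_grm`: biallelic dosages with per-marker allele frequencies
  uniform in (0.05, 0.5], centered by realized frequencies and scaled by
  `Σ 2p(1−p)` — the standard cross-product genomic relationship matrix.
  Genotypes are independent draws (no family structure); relatedness between
  individuals is therefore the finite-marker sampling covariance, which the
  MVN effect model treats as genuine. A useful consequence: genetic effects
  drawn as `G ~ MVN(0, σ² K_G)` are exactly an m-marker-effects model, so
  prediction accuracy for unseen genotypes follows the classic
  `R² ≈ n h²/(n h² + m)` relation. Real panels add family structure and
  linkage, which these simulations do not represent — passing tests show the
  machinery is correct, not that any particular accuracy is attainable in
  real data.
- `simulate_erm`: a Gaussian kernel over standard-normal environmental
  covariates, `exp(−‖x_i − x_j‖²/(2 h² q))` with bandwidth h and q
  covariates; unit diagonal, PSD.
- `sample_design`: samples `n_g` genotypes and `n_e` environments, covers
  every sampled level at least once by cycling both factors, then fills the
  remaining observations with uniformly drawn grid cells (replication
  allocation across cells in real trial networks is not uniform; uniform is
  the neutral choice here). `force_balanced` yields the exact full crossing
  for oracle tests.
- `simulate_phenotypes`: `y = μ + Z1 G + Z2 E + GE + ε` with each random
  term drawn through the eigen factor of its kernel — stable for (near-)
  singular kernels where a Cholesky factor fails — and the interaction drawn
  through the tensor-EVD basis at α = 1, so the n×n kernel is never formed.

All generators are pure functions of their seeds.

## The reaction-norm model

Each random term is fitted in its eigen-basis representation
`u_t = B_t θ_t`, `θ_tk ~ N(0, σ_t² d_tk)`, with `(B_t, d_t)` taken from an
`EVDResult` — exact for the main effects (α = 1 bases of `Z1 K_G Z1'` and
`Z2 K_E Z2'`) and truncated (tensor or direct eigen) for the interaction.
The Gibbs sampler uses:

- a flat-prior normal update for μ;
- scalar conjugate-normal updates for every basis coefficient against a
  running residual, in fixed index order (deterministic given the seed); the
  sweep is numba-compiled when numba is importable, with an identical
  pure-NumPy fallback;
- scaled-inverse-chi-square updates for each variance, prior degrees of
  freedom 5 and prior scales allocating a fixed partition of the sample
  phenotypic variance (default equal quarters across G, E, GE, error) so
  the prior mode of each variance sits at its partition share. These mirror
  common Bayesian mixed-model defaults; with few levels in a term (e.g. ten
  environments) the variance posterior is materially prior-influenced,
  which is inherent to the model, not to the basis used.

Default chain settings in the analyses here are 1,200 iterations, 400
burn-in, thinning 4. `variance_partition` reports posterior-mean variances
normalized to sum to one.

**CV1.** `cv1_folds` partitions genotypes — not records — into k nearly
equal folds; `cv_evaluate` refits per fold on the training rows (basis
columns keep their eigenvalues; row subsetting is handled by tracking
per-column squared norms) and predicts held-out records from the posterior
mean coefficients applied to their basis rows, which exist because bases
are observation-indexed. Accuracy is the within-environment Pearson
correlation pooled over all held-out records, n-weighted across
environments; environments with fewer than 3 held-out records (or zero
variance) are skipped and flagged. Pooling predictions from k fold-models
induces a small negative bias at small n (fold-specific intercept/
environment estimates anti-correlate with their held-out records); it
shrinks with n and is part of the scheme, not removed.

## Study designs used in the checks

Simulation sizes are desk-scale versions of a large trial network, chosen
so each quantity measures what it is meant to:

- Factorization oracles: kernels up to 8–16 rows, designs up to n = 300,
  against explicitly formed Kronecker/Hadamard matrices.
- Approximation/basis-size comparisons: 100 genotypes × 10 environments at
  n = 2,000–3,000 (direct-eigen comparator is O(n³), capped at n = 4,000 in
  the CLI benchmark), plus a 40×25 / n = 300 grid for the regime where the
  Kronecker dimension exceeds n.
- Truncation-effect and basis-equivalence model runs: 100×10, n = 3,000,
  comparing tensor and direct bases at α = 1 and the direction of change at
  α = 0.90.
- Variance recovery: 200 genotypes × 50 environments, n = 3,000, α = 0.98.
  The realized variance of a q-level random effect scatters around its
  parameter with sd ≈ σ²√(2/q), so recovery to ±0.1 requires q ≳ 50 per
  factor; smaller designs would test draw lottery rather than the sampler.
- CV1: 200 genotypes, 400 markers, 8 environments, n = 2,000, five folds —
  sized via `R² ≈ n h²/(n h² + m)` for a stable, clearly positive accuracy.

## Known limitations

- The tensor basis is not orthogonal for unbalanced designs; downstream
  code must treat it as a spanning set (the sampler does).
- In the regime `n1·n2 ≫ n` the basis needed for a given α can be several
  times larger than the direct-eigen basis — dimension reduction is the
  method's weak spot there, by construction; its advantage is avoiding the
  O(n³) factorization entirely.
- No out-of-core or distributed computation; explicit comparators are
  limited to desk scale.
- The sampler reports no convergence diagnostics beyond the stored draws;
  REML/frequentist fitting and multi-trait models are out of scope.
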