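# Methods

## Model class

`ltnflow` fits Bayesian multinomial logistic-normal (MLN) models: a D×N
table of counts Y (categories × samples, e.g. taxa × specimens) is modeled
as column-wise multinomial with composition π_j obtained from a latent
real-valued matrix η through the inverse additive log-ratio (ALR) transform,

    Y_·j ~ Multinomial(n_j, π_·j),    π_·j = ALR⁻¹(η_·j),

with the last category as ALR reference. Three latent structures are
supported for η (P = D−1 rows, N columns):

* **Linear (`fit_pibble`)** — η_·j ~ N(Λ X_·j, Σ), Λ ~ N(Θ, Σ, Γ),
  Σ ~ IW(Ξ, ν): multivariate regression with conjugate matrix-normal /
  inverse-Wishart priors.
* **Dynamic linear (`fit_gmdlm`)** — η_tᵀ = F_tᵀΘ_t + ν_t with a
  matrix-variate state path Θ_t = G_tΘ_{t−1} + Ω_t, Ω_t ~ N(0, W_t, Σ),
  Θ_0 ~ N(M0, C0, Σ), Σ ~ IW(Ξ, ν): a multivariate dynamic linear model
  with non-Gaussian observations.
* **Gaussian process (`fit_basset`)** — η_·j ~ N(Λ(x_j), Σ),
  Λ ~ GP(Θ, Σ, Γ), Σ ~ IW(Ξ, ν): nonlinear regression/smoothing over
  arbitrary covariate locations with a separable (row Σ ⊗ column Γ)
  covariance.

## Collapsed matrix-t representation

All three families share the property that integrating out the conjugate
layer Ψ (Λ and Σ, or the state path and Σ) leaves a marginal p(η, Y) in
which η follows a **matrix-t distribution** T(ν, B, K, A):

| family  | B                    | K | A                       |
|---------|----------------------|---|-------------------------|
| linear  | ΘX                   | Ξ | I_N + XᵀΓX              |
| dynamic | column t: M0ᵀ𝒢_{t:1}ᵀF_t | Ξ | state-recursion Gram (below) |
| GP      | Θ(x)                 | Ξ | I_N + Γ(x, x')          |

For the dynamic family the A matrix is assembled by propagating the state
prior covariance P_t = G_t P_{t−1} G_tᵀ + W_t (P_0 = C0):

    A[t,s] = γ_t δ_{ts} + F_tᵀ 𝒢_{t:s+1} P_s F_s   (t ≥ s),

with 𝒢_{t:ℓ} = G_t ⋯ G_ℓ and empty products equal to the identity. The
cost is O(T²Q³), fine at desk scale. The transpose-consistent column form
M0ᵀ𝒢ᵀF is used for B (the row/column orientation is fixed by requiring B
to be P×T); a forward-simulation oracle in the test suite confirms both B
and A against 10⁴ trajectories of the hierarchy.

In the GP family the identity term of A is the per-sample noise: it is
diagonal over sample indices, so duplicated locations remain valid inputs
(the off-diagonal entry between two samples at the same location is
Γ(x,x), not 1+Γ(x,x)).

**Degrees-of-freedom convention.** We parameterize the matrix-t by its
construction: Σ ~ IW(K, ν) in the standard (scipy) inverse-Wishart
parameterization (mean K/(ν−P−1)), X ~ N(0, I, A), η = B + chol(Σ)X. The
log density is the exact marginal of that construction,

    log T(η) = log Γ_P((ν+N)/2) − log Γ_P(ν/2) − (NP/2)log π
             − (N/2)log|K| − (P/2)log|A|
             − ((ν+N)/2) log|I_P + K⁻¹ΔA⁻¹Δᵀ|,    Δ = η−B,

computed entirely through Cholesky log-determinants. Textbook treatments
that attach the degrees of freedom to the multivariate-gamma arguments as
(ν+N+P−1)/2 correspond to the substitution ν → ν−P+1 in the inverse-Wishart
convention used here; the two coincide at P = 1. Our convention is the one
under which the conjugate updates below (ν_N = ν+N), the prior moment
identity cov(vec η) = A ⊗ K/(ν−P−1), and the Geweke joint test are all
mutually consistent, and it is validated against 1-D quadrature of the
scale-mixture at P=N=1. The propriety domain ν > P−1 is enforced (the
constructive definition requires it).

## Inference: collapse–uncollapse with a Laplace approximation

1. **Collapse** the family to T(ν, B, K, A).
2. **MAP**: minimize −log p(η|Y) = −log f(Y|ALR⁻¹η) − log T(η) by
   L-BFGS with the analytic gradient, then damped Newton steps with the
   analytic Hessian until the gradient sup-norm is below 1e-4
   (configurable). The default start is the ALR of (Y+0.5) column
   proportions — cheap and near the likelihood mode.
3. **Laplace**: q(η|Y) = N(vec η̂, H⁻¹) with H the PN×PN Hessian at η̂
   (multinomial part block-diagonal per sample; matrix-t part dense).
   S independent draws cost one triangular solve each.
4. **Uncollapse** each η draw through the family's conjugate conditional
   p(Ψ|η) (Ψ ⟂ Y | η):
   * linear: Γ_N = (XXᵀ+Γ⁻¹)⁻¹, Λ_N = (ηXᵀ+ΘΓ⁻¹)Γ_N,
     Ξ_N = Ξ + ηηᵀ + ΘΓ⁻¹Θᵀ − Λ_NΓ_N⁻¹Λ_Nᵀ, ν_N = ν+N;
     Σ ~ IW(Ξ_N, ν_N), Λ|Σ ~ N(Λ_N, Σ, Γ_N).
   * dynamic: because every covariance is left-factor ⊗ Σ, the Kalman
     gains are Σ-free; the one-step-ahead prediction decomposition gives
     Σ|η ~ IW(Ξ + Σ_t e_te_tᵀ/q_t, ν+T) exactly, then the state path is
     drawn by forward filtering / backward sampling given Σ.
   * GP: Σ|η ~ IW(Ξ + Δ(I+Γ)⁻¹Δᵀ, ν+N) with Δ = η−Θ(x), then Λ at the
     requested locations from the standard GP conditional with row
     covariance Σ.

Each (η, Ψ) pair is one joint posterior draw. Uncollapsing uses per-draw
RNG substreams spawned from the master seed, so results are bit-identical
regardless of execution order.

### Analytic derivatives

The matrix-t contribution to the negative log posterior has gradient
(ν+N) S⁻¹ΔA⁻¹ with S = K + ΔA⁻¹Δᵀ, and Hessian
(ν+N)[C ⊗ S⁻¹ − T] in column-major vec order, where
C = A⁻¹ − A⁻¹ΔᵀS⁻¹ΔA⁻¹ and T[(i,j),(k,l)] = M₁[i,l]M₁[k,j] with
M₁ = S⁻¹ΔA⁻¹. The multinomial contribution per sample j is the familiar
logit-multinomial pair: gradient Y_{1:P,j} − n_jπ̃_j, Hessian
n_j(diag π̃_j − π̃_jπ̃_jᵀ). Both are symmetrized after assembly and are
validated against central finite differences over randomized instances in
the test suite (< 1e-5 relative, typically ~1e-9).

### When the approximation is trustworthy

The logit-parameterized multinomial is globally log-concave and the
matrix-t is log-concave near its mode, so the posterior is effectively
Gaussian whenever the likelihood is informative. The error of the Laplace
approximation scales, up to proportionality, as

    (D−1) · Σ_j 1/n_j            (`laplace_error_bound`),

growing with the number of categories and shrinking with per-sample
totals. The diagnostic is reported per fit; the acceptance experiments
confirm the qualitative behavior (mean discrepancy vs a Metropolis oracle
drops ~25× as n_j goes 5 → 500). Under extreme sparsity the Hessian can
lose definiteness; a jitter ladder (1e-8, 1e-6, 1e-4 × mean diagonal) is
applied with a warning, and a hard failure names the sparsity caveat. A
column with n_j = 0 is rejected at fit time: it carries no likelihood
information but would destabilize reporting.

## Defaults and tunables

| parameter | default | meaning |
|---|---|---|
| Θ | 0 | prior mean of coefficients (ALR coordinates) |
| Γ | I_Q | covariate-side prior covariance |
| Ξ | I_P | inverse-Wishart scale (category-side) |
| ν | D+10 | prior degrees of freedom; smaller values (D+3, D+2) give heavier tails and are accepted via config |
| S | 2000 | posterior draws |
| gradient tolerance | 1e-4 (sup-norm) | MAP convergence |
| SE kernel | lengthscale 1 time-unit, scale 1 | GP smoothness; user config |
| pseudo-count | 0.5 | baseline model and MAP initialization only |

All log-likelihoods omit the multinomial coefficient (constant in η);
users comparing absolute densities across packages should add it back.
Reports default to centered log-ratio (CLR) coordinates — obtained from
ALR by appending the zero reference row and centering each column — so
every category gets its own coordinate; ALR is available by flag.

## Oracles and what passing tests mean

Because no external dataset ships with the package, correctness rests on
independent oracles:

* 1-D quadrature of the normal × inverse-Wishart scale mixture for the
  scalar matrix-t density; KS tests against the equivalent Student-t.
* Forward simulation of each full hierarchy (10⁴ draws) against the
  collapsed matrix-t moments — the marginal-consistency property that
  justifies the whole approach.
* An adaptive random-walk Metropolis sampler on vec(η) (`mh_oracle_sampler`,
  Haario-style covariance adaptation, intended for PN ≲ 60) as the
  brute-force posterior reference.
* A Geweke-style successive-conditional simulator for the joint
  correctness of uncollapse + resimulation (moment z-scores < 4).
* Grid-search, least-squares limits, and dense joint-Gaussian conditioning
  for individual conjugate updates.

## Synthetic data generator

`simulate_pibble_data` draws from the linear-model hierarchy itself:
Σ_true ~ IW(I, D+10), Λ_true ~ N(0, Σ_true, I), X iid standard normal
(optional intercept row), η ~ N(Λ_true X, Σ_true, I), multinomial counts
with fixed totals n_j = 5000 by default (log-normal totals available).
It emulates the count variation, compositional constraint, and sparsity
structure of sequencing data as a function of D and n_j, but not real
data's taxonomic correlation structure, overdispersion beyond the
logistic-normal, or library-size/batch artifacts — so passing recovery
and calibration tests demonstrates correct inference *under the model*,
not robustness to model misspecification.

The evaluation harness (`run_grid`) records sparsity, the error-bound
diagnostic, coefficient RMSE against simulated truth, and sd-RMSE against
the Metropolis oracle when the instance is small enough, for the Laplace
CU sampler and for the pseudo-count linear model (PCLM) baseline that
fixes η at the ALR of (Y+0.5) proportions. Problem sizes used throughout
the tests and the acceptance script (N ≤ 200, D ≤ 10 for fits; chains of
4×10⁴–1.2×10⁵ steps; 10⁴-draw moment checks) were chosen so the whole
validation runs in minutes on one core.

## Numerical choices

* Column-major vec convention everywhere (vec(Y) ~ N(vec M, V⊗U)).
* All determinants and inversions via Cholesky; non-PD inputs fail fast
  with the offending matrix named, except the Laplace Hessian (jitter
  ladder, above) and degenerate filter/GP conditional covariances, which
  use an eigenvalue-clipping PSD square root (warning if clipping exceeds
  rounding error) so noise-free limits (W→0, γ→0, kernel→0) remain exact.
* Multivariate gamma via scipy's log-gamma sum.
* Matrix-t evaluation uses log|K+ΔA⁻¹Δᵀ| − log|K| rather than forming
  K⁻¹ explicitly.

## Known limitations

* Dense PN×PN Hessian: memory is the binding constraint around
  P·N ≳ 5×10⁴; larger problems need a structured factorization that is
  out of scope here.
* Hyperparameters (ν, kernel parameters, W_t) are fixed by the user, not
  inferred.
* Prediction of unobserved *categories* through a kernel on category
  metadata is not implemented; Ξ is a fixed matrix on observed categories.
* The dynamic-family uncollapse assumes the γ_t, W_t, C0 given; discount
  factors are not implemented.
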