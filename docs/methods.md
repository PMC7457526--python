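# Methods

## Marginal model

Responses are clustered by subject on a balanced J × K grid (J
experimental conditions × K channels), vectorized condition-major:
(j=1,k=1), …, (j=1,k=K), (j=2,k=1), …  The marginal model is

    E(Y_ijk) = μ_ijk,  g(μ_ijk) = x_ijkᵀ β,  Var(Y_ijk) = φ v(μ_ijk),
    Cov(Y_i) = V_i = A_i^{1/2} R A_i^{1/2} φ,

estimated by generalized estimating equations with a working correlation
R. Only the Gaussian family with identity link is exercised (v ≡ 1,
φ fixed at 1); the A_i/v(μ) hooks are kept in the score and information
so other families slot in structurally, but those paths are untested and
should not be relied on. With φ fixed, residual scale lives entirely
outside R: every working correlation is normalized to unit diagonal.

Unbalanced clusters are rejected rather than imputed: the Kronecker
structure below is only defined on the full grid, and silently dropping
or filling cells would change the correlation model. The loader enforces
the condition-major ordering regardless of input row order.

## Working correlation structures

Available structures: independence, AR(1), compound symmetry (CS),
unstructured, and the separable (Kronecker) structure R = B ⊗ Σ with a
condition factor B (unstructured or independence) and a channel factor Σ
(AR(1), CS, or unstructured). Entry ((j,k),(j′,k′)) of B ⊗ Σ is
B[j,j′]·Σ[k,k′]; both factors are constrained to unit diagonal because a
separable covariance identifies its factors only up to a scalar.

Parameters are method-of-moments estimates from Pearson residuals at the
current coefficient iterate, with numerators and denominators pooled
globally over the same index set (the pooling level is not dictated by
the estimating theory; global pooling is the simplest consistent
choice):

- AR(1) / Σ-side AR(1): ρ̂ = mean of within-condition lag-1 products ÷
  overall mean squared residual, clipped to [−0.99, 0.99];
- CS: mean off-diagonal product ÷ mean squared residual, clipped to the
  open positive-definite range (−1/(m−1), 0.99);
- unstructured B: B̂[j,j′] = mean over subjects and channels of
  e_ijk·e_ij′k, rescaled to unit diagonal; analogously for an
  unstructured Σ from within-condition pairs.

A non-positive-definite unstructured estimate is repaired by flooring
its eigenvalues at 10⁻⁶ and rescaling to unit diagonal; a realized
working correlation must have smallest eigenvalue above 10⁻¹⁰. R is
re-estimated at every Newton iteration (the standard iterative GEE
alternation).

## Group SCAD penalty and MM algorithm

The penalized estimating function is U(β) = S(β) − n·q_λᴳ(β)·sign(β),
where q_λᴳ gives every coefficient of group g the scalar rate
q_λ(‖β_g‖₁), with the SCAD derivative

    q_λ(θ) = λ on [0, λ],  (aλ − θ)₊/(a−1) on (λ, ∞),   a = 3.7.

The two branches agree at θ = λ, and the continuous closed form is used;
a = 3.7 is the conventional SCAD shape value. Unpenalized terms
(intercept, condition effects by default) receive rate 0. Singleton
groups make the rate q_λ(|β_j|), i.e. individual SCAD, exactly.

The nonsmooth penalty is minorized with the |β_j|/(ε + |β_j|) surrogate,
giving the diagonal matrix E_n with entries q_λ(‖β_g‖₁)/(ε + |β_j|) and
the Newton–Raphson update

    β^k = β^{k−1} + [H_n + n E_n]⁻¹ [S_n − n E_n β^{k−1}],
    H_n = Σᵢ Xᵢᵀ A_i^{1/2} R̂⁻¹ A_i^{1/2} Xᵢ.

Numerical choices, with rationale:

- ε = 10⁻⁶ (standard choice for this surrogate); stopping rule
  Σ_j |Δβ_j| < 10⁻⁵; max_iter = 100 (fits exceeding it are returned with
  `converged=False`).
- Initializer: the working-independence GEE estimate (ordinary least
  squares for the Gaussian identity case). Starting at or near zero is
  not an option: the MM weight 1/(ε + |β_j|) pins coefficients at zero.
- H_n + n E_n carries a 10⁻⁸ ridge: E_n entries reach 1/ε for dead
  coefficients and the system is otherwise near-singular.
- Support thresholding: after convergence a group is retained iff
  ‖β̂_g‖∞ > 10⁻³; coefficients of dropped groups are set to exactly 0.
  The MM iteration shrinks towards but never exactly to zero; 10⁻³ sits
  above the MM residue at this tolerance and below signals of practical
  size. Unpenalized coefficients are never thresholded.
- A non-finite update aborts the fit (reported as a failed grid point).

The inner loop has a numba-compiled implementation mirroring the
reference numpy code path; the test suite asserts the two agree to
machine precision, and the reference path remains the one used when an
iterate trace is requested.

## Penalty level selection

λ is tuned over a 30-point log-spaced grid from λ_max down to
0.01·λ_max, with λ_max = max_g ‖S(0)_g‖∞ / n computed from the GEE score
at β = 0 under the working correlation (estimated from the β = 0
residuals). At that level the zero vector satisfies the penalized
stationarity condition, so the grid spans full shrinkage to
near-unpenalized. Fits ascend the grid, each warm-started from its
smaller-λ neighbour (the smallest from the independence initializer);
this is cheap, and it reproduces the monotone, non-increasing support
one expects along increasing λ.

The selection criterion is a clustered-data BIC built on the Gaussian
pseudo-likelihood with the dispersion profiled out:

    BIC(λ) = N·log(Q_λ/N) + log(N)·df_λ,      N = n·m,

where Q_λ is the residual quadratic form Σᵢ rᵢᵀ R̂⁻¹ rᵢ under a working
covariance estimated once at the least-penalized grid point and then
held fixed across the path, and df_λ counts retained plus unpenalized
coefficients. Three design points deserve comment, because the exact
criterion is genuinely open:

- *Quadratic-form fit term.* With an unweighted RSS fit term the
  improvement contributed by weakly informative groups is diluted by the
  (large, correlated) residual variance, and such groups are never
  retained; the R̂⁻¹-weighted form measures fit on the scale the
  estimator actually uses.
- *Common covariance.* If each candidate model supplies its own R̂, the
  pseudo-likelihood term n·log|R̂| swings by far more than the dimension
  penalty for tiny changes in ρ̂, and the criterion degenerates into a
  comparison of correlation estimates. Holding one R̂ fixed (as QIC
  does) keeps the comparison about the mean model.
- *log(N) with N = n·m.* For clustered data the effective sample size
  for the dimension penalty is debatable (clusters vs observations);
  the observation count gives the stronger penalty, which is what the
  desk-scale calibration of this design requires to keep pure-noise
  groups out (see the pure-noise property test).

Ties in BIC resolve to the larger λ (the more parsimonious fit).

## Simulation harness

The generator reproduces a specific benchmark: n ∈ {50, 100} subjects,
m = 20 observations as 2 conditions × 10 channels, p = 40 covariates in
8 groups of 5 with

    β = (2,1,1,1,1, 3,3,3,3,0, 0,0,0,0,0.1, 0.1,1,1,1,0, 0,…,0),

covariate 1 ~ Bernoulli(0.5) and covariates 2–40 multivariate normal
with AR(1) correlation 0.5 *across the covariate index*, drawn freshly
for every observation; per-subject errors are MVN(0, B ⊗ Σ) with B = I₂
and Σ an AR(1) with marginal variance 10 and autocorrelation 0.9. Five
estimators are compared (individual SCAD with AR(1) or the separable
correlation; group SCAD with AR(1), unstructured ⊗ CS, or
unstructured ⊗ AR(1)), each BIC-tuned per replicate. Selection is
classified exact/under/over at group level for the group-penalized
estimators (truth: the four groups containing nonzero coefficients) and
at covariate level for the singleton estimators (truth: the 14 nonzero
coefficients); "under" means any true term is missed. MSE is the mean
over replicates of ‖β̂ − β‖²₂ and SE its sample standard deviation
(defined as 0 for a single replicate). Replicate r uses seed
base + r, so runs are deterministic and estimators can be compared on
identical datasets.

What the generator emulates: the separable error correlation, the
grouped sparse signal with both strong (1–3) and weak (0.1)
coefficients, and the high residual variance typical of single-trial
averaged ERP amplitudes. What it does not emulate: unbalanced grids,
missing biomarkers, non-Gaussian or heteroscedastic responses,
between-subject covariate structure (covariates are redrawn per
observation), or channel geometry beyond the AR(1) ordering. Passing
simulation tests therefore say nothing about robustness to those
features of real data.

A design limitation worth stating plainly: at these sample sizes the
per-coefficient information bound puts the sampling error of the 0.1
coefficients on the same scale as the largest noise-coefficient
estimates, so *no* tuning criterion can separate the weakest true group
from noise groups with high reliability at n = 50 — exact-selection
rates in the 60–80% range (rising with n) are what the design supports,
with mean squared errors around 0.05–0.15. The acceptance suite records
the exact rates and errors the pipeline actually achieves rather than
asserting unattainable ones; the ordering between estimators (structured
correlation + group penalty vs individual SCAD + plain AR(1)) is the
robust, reproducible finding.

## Problem sizes used in the checks

The bundled acceptance runs use 200 replicates per benchmark row in
`scripts/acceptance.py` and 100 replicates per row in the test suite's
reproduction module (with selection tolerance widened accordingly);
correlation-recovery checks use 2000 simulated subjects and generator
moment checks 500, with 3-Monte-Carlo-SE margins computed by the delta
method at subject level.

## Known limitations

- Gaussian identity-link responses only; no sandwich/robust standard
  errors or post-selection inference.
- Balanced complete grids only; no missing-data handling.
- The BIC variant is a documented design choice (see above), not a
  uniquely determined criterion; conclusions that hinge on the precise
  over/under split of borderline models may be sensitive to it.
- The group penalty uses the L1 group norm with a shared rate, so within
  a retained group individual coefficients are still shrunk individually
  by the MM surrogate; groups whose norm is dominated by a single weak
  coefficient behave similarly to individually penalized terms.
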