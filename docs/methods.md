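# Methods

## The distribution

`nbuw` implements a two-parameter distribution for proportions obtained by
mapping a Weibull random variable Y on (0, ∞) through X = 1/(1+Y).  With
scale-like parameter α > 0 and shape β > 0,

    F(x; α, β) = exp(−α ((1−x)/x)^β),   0 < x ≤ 1,
    f(x; α, β) = α β ((1−x)/x)^{β−1} x^{−2} F(x; α, β),
    Q(u; α, β) = [1 + (−log u / α)^{1/β}]^{−1}.

The closed-form quantile function makes inverse-transform sampling exact
and cheap, and is what the quantile-regression reparameterization exploits.
The density can be bathtub-shaped (β < 1), right-skewed, or unimodal; with
α = 1 it concentrates at 1/2 as β grows.  The support excludes 0: data with
exact zeros are outside the model (a stated limitation, not handled here).
Observations exactly equal to 1 — which are in the support of the CDF but
are a singular point of the density — are clamped to 1 − 1e−10 with a
warning before likelihood evaluation.

### Numerical policy

All powers of (1−x)/x are taken in log space, so shapes up to β ≈ 30 and
beyond do not overflow; CDF underflow deep in the left tail (values below
~1e−300) is deliberate and maps to probability 0.  `nbuw_ppf` ∘ `nbuw_cdf`
round-trips to 1e−10 on interior grids; next to x = 1 the round-trip is
limited to ~1e−6 by double-precision conditioning of log1p(−x), not by the
algorithm.

### The "hazard" formula

The rate α β ((1−x)/x)^{β−1} x^{−2} presented with the model as its hazard
rate function is algebraically f(x)/F(x) — the *reversed* hazard — because
the exponential factor cancels, not the classical f/(1−F).  The package
exposes it as `reversed_hazard` (with the identity f = reversed_hazard · F
tested to machine precision) and provides `classical_hazard` separately
rather than guessing intent.

## Moments and entropies

Adaptive quadrature is authoritative for every moment, the MGF and the
entropies.  Raw moments and the MGF integrate through the quantile
substitution E[g(X)] = ∫₀¹ g(Q(u)) du, which removes both boundary
singularities; entropies integrate f^θ directly with divergence detection
(∫ f^θ diverges at x = 1 whenever θ(β−1) ≤ −1, and the q-entropy is
undefined whenever ∫ f^q ≥ 1 — both raise, neither is silently truncated).

A formal double series expressing the density in beta-distribution kernels
(coefficients Δij = (−1)^{i+j}/j! · C(β−1, i) · α^j, beta-function terms
B(i+m−βj−β, βj+1)) accompanies the model.  The first beta argument is
non-positive for many (i, j), where B is undefined, so the series cannot be
summed literally; restricting to admissible terms discards mass and does
*not* recover the quadrature value (for m = 1, β = 2 no admissible term
exists at all).  The series is therefore exposed as a guarded diagnostic —
truncation bound 50 per index, tail tolerance 1e−10, generalized binomials
via `scipy.special.binom` — and the unit tests document its disagreement
with quadrature rather than pretending otherwise.  The Rényi series
variant uses the exponent-consistent first argument i−βj−βθ−θ+1 (the +1
required by the x^{a−1} convention).

## Sequential probability ratio test

For H0: β = β0 vs H1: β = β1 (β1 > β0, α known), each observation adds
ξ = log(β1/β0) + (β1−β0) log t − α t^{β1} + α t^{β0} with t = (1−x)/x;
the test stops when the cumulative sum leaves (log B, log A) with
A = (1−ψ)/δ, B = ψ/(1−δ).  The increment equals the log-density difference
identically (a machine-precision test invariant).  Boundary hits use ≤/≥
with no overshoot correction.

E_β(ξ) is computed by quadrature through the quantile substitution (no
closed form exists); a Monte-Carlo fallback reports its standard error.
The operating characteristic has nominal Wald values only at the two
hypothesized points (L(β0) = 1−δ, L(β1) = ψ); at any other β it is
estimated by simulation.  Two ASN numerators are provided under H1: the
form printed with the model, δ·log B + (1−ψ)·log A, and the standard Wald
form ψ·log B + (1−ψ)·log A; they coincide when δ = ψ.  One caution that
the simulations make vivid: for well-separated hypotheses the increments
are large relative to the boundaries, overshoot inflates |E(S_N)| (by
~2.4× at α = 1, β0 = 0.75, β1 = 1.5, δ = ψ = 0.05), and the no-overshoot
ASN formula underestimates the mean stopping time by the same factor.
Wald's identity E(S_N) = E(N)·E(ξ) itself holds to a few percent in
simulation, which is what the test suite asserts.

## Maximum likelihood for (α, β)

With t_i = (1−x_i)/x_i the log-likelihood is
l = n log α + n log β + (β−1) Σ log t − 2 Σ log x − α Σ t^β,
so α̂(β) = n / Σ t^β in closed form.  The fitter profiles the likelihood
to a one-dimensional bounded search in log β on [−7, 7] (no starting point
needed, no convergence sensitivity — important for the ~100,000 fits the
simulation tables require) and recovers α̂ from the profile.  Standard
errors come from the analytic observed information; the 2×2 Hessian is
closed form:

    l_αα = −n/α²,  l_αβ = −Σ log t · t^β,  l_ββ = −n/β² − α Σ (log t)² t^β.

`NBUWMLE` wraps this as a scikit-learn-style density estimator
(`fit` / `score_samples` / `sample`); `fit_nbuw` returns a frozen
`FitResult`.

## Quantile reparameterization and regression

Fixing a known level q and writing μ for the q-th quantile gives
α = −(1/μ − 1)^{−β} log q, under which G(μ) = q holds exactly for all
(β, μ) — a machine-precision anchoring identity, since the substitution is
evaluated symbolically rather than through rounding-prone intermediates.
The regression model links conditional quantiles to covariates through a
logit link, logit(μ_i) = x_i·δ, with a common shape β; q is user-supplied
and fixed (default 0.5, the conditional median), exactly as the model
treats it.

A reduction worth recording: 1/μ − 1 = e^{−η} with η the linear predictor,
so the per-observation rate is α_i t_i^β = −log q · exp(β(η_i + log t_i)).
The log-likelihood, its gradient and its Hessian are then elementary in
(β, δ), which is what makes 10,000-replication recovery studies cheap.
The printed form of the likelihood omits the exponent β on the final
(1−y)/y factor; the implementation keeps the exponent, which is forced by
the identity l(Ψ) = Σ log π(y_i; β, μ_i, q) (asserted to 1e−10 in tests).

`NBUWQuantileRegressor` estimates (β, δ) jointly: a damped Newton
iteration on the exact Hessian in (log β, δ) handles well-behaved
problems in a handful of steps, and any start that stalls falls back to
BFGS with the exact gradient; starting values are OLS of logit(y) on the
design with β = 1.  Inference is Wald (observed information, two-sided
normal p-values); AIC/BIC count p coefficients + 1 shape parameter.  The
fitted estimator exposes `predict` (conditional q-th quantile),
`predict_cdf` (PIT values), `sample`, and a coefficient `summary_frame`,
and passes scikit-learn's clone/cross-validation machinery.  The MLE was
cross-validated against an independent R `optim` implementation of the
same likelihood (agreement to ~1e−6 on a 300-observation dataset).

## Residual diagnostics

Quantile residuals Φ^{−1}(G(y_i)) are deterministic PIT transforms (the
response is continuous, so no randomization is involved) and standard
normal under a correct model; Cox–Snell residuals −log(1 − G(y_i)) are
unit exponential.  Both are monotone transforms of the same PIT values,
an identity the tests assert pointwise.  PIT values at 0 or 1 are clamped
to [1e−12, 1 − 1e−12] with a warning.  The one-sample KS test is the
naive version: its p-value does not account for estimated parameters,
and it is labelled as such.  A half-normal envelope plot (pointwise
min/max of simulated standard-normal |residuals|, 100 simulations by
default) is provided as a plotting helper.

## Simulation harnesses and what they show

`run_distribution_study` regenerates the distribution-recovery tables:
for each n in {20, 45, …, 195}, 1000 inverse-transform samples are fitted
and summarized by bias, MSE, the empirical 95% percentile interval of the
replicate MLEs (the reading consistent with the published intervals'
asymmetry; per-fit Wald intervals are also available), and each summary's
own Monte-Carlo standard error.  `run_regression_study` does the same for
the regression model: standard-normal covariates redrawn each replication
(unconditional summaries), responses drawn through the reparameterized
quantile function, summaries RB = 100·(mean − truth)/truth and RMSE per
parameter.  Seeding spawns one independent `SeedSequence` child per
(cell, replication) from a single master seed, so any cell is
re-runnable in isolation and whole tables are bit-reproducible.
Replications that fail to converge are dropped and counted (failure rates
are zero at these settings in practice); cells above 5% are flagged.

The generator's defaults are the study conditions themselves: scheme
coefficient/shape values as published, covariates N(0, 1), q ∈ {0.1, 0.5,
0.9}, 1000 replications (distribution) and 10,000 (regression; the
test-suite rerun uses 2,000 with correspondingly widened Monte-Carlo
tolerances).  What the generator does not emulate about real proportion
data: covariate dependence and non-normal designs, exact ones/zeros,
overdispersion from clustering, or model misspecification — passing
recovery tests therefore demonstrate estimator correctness under the
model, not robustness beyond it.

Three properties of the published regression table deserve note, because
the rerun exposes them.  First, the shape-RMSE column is on the relative
scale: recomputed absolute RMSE(β̂) equals the printed value times the
true β, scheme by scheme (the harness reports `rel_rmse_beta` alongside
the absolute value for this reason).  Second, the slope cells are printed
identically across the three quantile levels, and the n = 25 slope cells
are incompatible with 1/√n scaling; recomputed values agree with the
printed ones at n ∈ {150, 300} to a few percent but not at small n.
Third, two blocks (the second and third schemes at q = 0.5) print
intercept/slope RMSEs 1.5–2× larger than both the recomputed Monte-Carlo
values and the average observed-information standard errors, which agree
with each other to ~1–2% — the corresponding acceptance comparisons are
left failing rather than widened, since three independent routes (the
Monte-Carlo rerun, the analytic information matrix, and an R `optim`
cross-check of the fitter) give the same answer.

## Known limitations

* No support for exact zeros (outside the model's support) or
  zero/one-inflated variants.
* The naive KS p-value with estimated parameters is conservative.
* The nominal ASN/OC values inherit Wald's no-overshoot approximation and
  can be far from simulated stopping times for well-separated hypotheses;
  use `simulate_runs` when the increments are large.
* The diagnostic series representations reproduce printed formulas, not
  usable numerics; quadrature is the only supported route to moments and
  entropies.
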