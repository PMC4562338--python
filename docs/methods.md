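# Methods

## Model

The package models a heavy-tailed observable Y as a deterministic,
monotone transform of a latent location–scale variable X ~ F_X with mean
μ_X and standard deviation σ_X:

    U = (X − μ_X)/σ_X,
    Y = H_δ(U) σ_X + μ_X,      H_δ(u) = u exp((δ/2) u²),  δ ≥ 0.

H_δ is odd and strictly increasing for δ ≥ 0, so the map is bijective and
its inverse is explicit through the principal branch of the Lambert W
function: W_δ(z) = sgn(z) √(W(δz²)/δ). Negative δ would compress the tails
but destroys bijectivity (the support becomes parameter-dependent and the
inverse non-unique), so it is rejected everywhere rather than partially
supported. A generalized exponent, H_{δ,α}(u) = u exp((δ/2)(u²)^α), is
implemented for completeness; all defaults, estimators and studies use
α = 1, the Tukey-h case. The inner u² (rather than |u|) keeps the map
smooth and bijective for every α > 0.

The double-tail (hh) variant applies δ_ℓ to u ≤ 0 and δ_r to u > 0.
Because the transform preserves sign, inversion picks the branch by
sgn(z); both one-sided maps agree (identity-like) at the center, so the
density is continuous there.

With Gaussian input the output is Tukey's h distribution. The n-th moment
of Z = H_δ(U), U ~ N(0,1), is finite only for n < 1/δ (the output's tail
index); for even n below that bound it equals
n!(1 − nδ)^{−(n+1)/2} / (2^{n/2}(n/2)!). Orders at or above 1/δ are
reported as +∞ for even n and NaN ("does not exist") for odd n — the
boundary order n = 1/δ is grouped with the divergent regime, a convention
choice at a measure-zero parameter set. The variance and kurtosis maps
follow: σ_Y = σ_X(1 − 2δ)^{−3/4} for δ < 1/2, otherwise +∞; γ₂(δ) =
3(1 − 2δ)³/(1 − 4δ)^{5/2} for δ < 1/4, otherwise +∞.

## Likelihood structure

The output density factorizes the log-likelihood as

    ℓ(β, δ; y) = ℓ(β; x_τ) + ℛ(τ; y),

where x_τ is the back-transformed sample and
ℛ = Σ_i [ −(δ/2) u_i² − log(1 + δ u_i²) ] ≤ 0 is a penalty for
transforming the data, zero iff δ = 0 (observations at μ_X contribute
nothing). Every fit object stores both parts; the identity is asserted to
1e−8 in the tests and cross-checked against the sum of log output
densities.

For known location/scale the δ-likelihood simplifies to
ℓ(δ; z) = −N log√(2π) − ((1+δ)/2) Σu_i² − Σ log(1 + δu_i²), u_i = W_δ(z_i).
Its maximizer is 0 exactly when Σz⁴/Σz² ≤ 3, and otherwise unique and
interior. The implementation checks the moment-ratio condition first and
then finds the interior optimum as the root of the analytic score
dℓ/dδ (using d(u²)/dδ = −u⁴/(1 + δu²)), bracketed by doubling and solved
by Brent's method to δ-tolerance 1e−12. Root-finding on the score was
preferred over generic 1-D maximization because uniqueness of the
stationary point makes it both safe and more precise; a dense-grid search
oracle in the test suite confirms agreement to 1e−3.

The joint 3-parameter MLE maximizes the total likelihood over
(μ, log σ, log δ) — the log parameterization enforces positivity and makes
δ → 0 approachable — with Nelder–Mead from three starts (the default start
uses the median for μ, the Taylor-rule δ floored at 1e−4, and
σ⁰ = sd(y)(1 − 2δ⁰)^{3/4} inverting the variance map; a near-Gaussian
start is always included) followed by a BFGS polish. The boundary case is
decided by comparing the best interior candidate against the closed-form
δ = 0 profile optimum (the plain Gaussian MLE); candidates whose
likelihood evaluation is non-finite (overflow deep in the tail) are
rejected. Standard errors come from the numerically differentiated
observed information in the natural parameterization; the SE of δ̂ is
undefined (NaN) at the boundary. The 4-parameter hh fit starts from the
symmetric solution, so its attained likelihood never falls below the
nested model's — the nesting inequality is enforced and tested.

## IGMM

The iterative generalized method of moments estimator targets a
back-transformed sample with kurtosis exactly 3, with no parametric
assumption on the input beyond finite fourth moments after
back-transformation. The iteration implemented here is a reconstruction
of the skewness-analogue scheme (the original description of the
heavy-tail variant is in supplementary material that is not distributed
with this package): starting from μ⁰ = median(y),
σ⁰ = sd(y)(1 − 2δ⁰)^{3/4} (δ⁰ from the Taylor rule), repeat

1. z = (y − μᵏ)/σᵏ;
2. δᵏ⁺¹ = the δ ∈ [0, 10] with sample kurtosis of W_δ(z) equal to 3
   (Brent root-finding; 0 if the kurtosis at δ = 0 is already ≤ 3, 10 if
   still above 3 at the cap);
3. x = W_{δᵏ⁺¹}(z) σᵏ + μᵏ; μᵏ⁺¹ = mean(x), σᵏ⁺¹ = sd(x);

until max|τᵏ⁺¹ − τᵏ| < tol, default tol = 1.22·10⁻⁴ and at most 100
iterations. The kurtosis of W_δ(z) is decreasing in δ in practice; Brent's
method only requires the verified sign change, so a non-monotone
pathological sample cannot silently break the step. The achieved exit
kurtosis is recorded on the fit and asserted (3 ± tol-scale) in tests.

The Taylor rule itself inverts the truncated kurtosis expansion
γ₂ = 3 + 12δ + 66δ², giving δ̂ = (√(66 γ̂₂ − 162) − 6)/66, clipped at 0 for
γ̂₂ ≤ 3. Kurtosis and skewness statistics are the uncorrected moment
ratios m₄/m₂² and m₃/m₂^{3/2}: the rule derives from population moments,
and bias-corrected versions would shift the fixed point of the IGMM
kurtosis match away from 3.

## Numerical choices

* **Small arguments.** The exact inverse is 0/0 at δz² → 0; for
  δz² < 1e−14 the analytic limit W_δ(z) → z is returned directly.
* **Large arguments.** z² overflows double precision for |z| > ~1e154.
  The inverse then evaluates W through its log-domain asymptotic
  w ≈ log x − log log x refined by Newton steps on w + log w = log x, so
  W_δ never overflows; entry into this regime is logged. The forward
  transform may legitimately overflow to ±∞, which is flagged with a
  warning, never returned as silent NaN.
* **Stable factors.** The density ratio W_δ(z)/z is computed as
  exp(−δu²/2) (exact algebraic identity), avoiding huge-z cancellation;
  1 + W(δz²) is computed as 1 + δu² (log1p where logged).
* **Ties and degenerate input.** Constant samples raise (kurtosis
  undefined); NaN inputs propagate with a logged count; estimation
  functions require n ≥ 4 finite observations.

## Simulation harness

Two designs mirror the estimator studies the distribution family is
typically evaluated on. The `delta_only` study draws standardized
Tukey-h samples over a grid of (N, δ) with location/scale known and
records, per cell, the bias and √N-scaled RMSE of the δ-MLE over seeded
replications (default 1000). The `joint` study draws location-scale
samples with (μ_X, σ_X) = (0, 1) — the standard benchmark configuration —
and compares the sample median, the plain Gaussian MLE, IGMM and the joint
Lambert W MLE, reporting per-parameter means, bias, sd and √N·RMSE,
including the implied σ̂_Y = σ̂_X(1 − 2δ̂)^{−3/4}, whose cell mean is +∞
whenever any replicate's δ̂ reaches 1/2 (a faithful property of the
statistic, not an error). For δ ≥ 1 the mean of Y does not exist and the
location target is read as the median. The √N scaling of the RMSE column
is the only scaling consistent with small-N summaries (an N-scaling would
put the scaled RMSE below the bias at N = 10).

Replicates are seeded by SeedSequence spawn keys (seed, cell, replicate,
attempt): cells are statistically independent, individually re-runnable,
and the full summary is a pure function of the spec. A replicate whose
fit fails numerically (non-finite likelihood, IGMM non-convergence) is
redrawn under a fresh attempt key and counted, so each summarized cell
contains the nominal number of valid replicates.

The generator emulates exactly the study conditions: i.i.d. draws from
the parametric output law itself. It does not emulate serial dependence,
conditional heteroskedasticity, asymmetric contamination or measurement
error, so passing recovery tests demonstrates correctness of the
estimators under the model, not robustness to misspecification on real
data.

Problem sizes in the shipped tests and the acceptance script: the δ-only
cells run the full 1000 replications at N = 1000; the joint-MLE cell runs
300 replications at N = 1000, with Monte-Carlo standard errors widened
accordingly (the relative MC error of an RMSE over r replications is
≈ 1/√(2r), and tolerances use three such standard errors). Simulated
critical values for the δ = 0 boundary test use the LR statistic of the
joint fit against the Gaussian fit under Gaussian truth; they fall below
the χ²₁ quantiles, as expected when the null value lies on the parameter
boundary. The LR helper also offers the ½χ²₀ + ½χ²₁ mixture reference as
an analytic alternative.

## Known limitations

* Closed-form moments and the moment-based estimators are specific to
  Gaussian input; other inputs get pdf/cdf/quantiles/sampling and
  likelihood decomposition, with moments by quadrature only.
* Asymptotic theory for the joint MLE (σ̂, δ̂ jointly) is not established;
  reported standard errors are observed-information approximations.
* The skewness/kurtosis of the asymmetric hh law are exposed only
  numerically; no closed forms are provided.
* Multivariate data and time-series (GARCH/SV-style) extensions are out
  of scope; the CLI and API are univariate and unconditional.
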