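# Methods

## Setting and target parameters

`mataboot` addresses interval estimation for a parameter that keeps the same
interpretation across a set of candidate models — here, the expected response
in one cell of a balanced two-level factorial experiment with a positively
skewed, lognormally distributed response. On the log scale the model for an
observation in cell (i, j, k) is

    log Y_ijkl = μ_ijk + ε_ijkl,      ε_ijkl ~ N(0, σ²),
    μ_ijk = μ + α_i + β_j + γ_k + αβ_ij + αγ_ik + βγ_jk + αβγ_ijk,

with ±1 (sum-to-zero) coding of the two levels. The candidate set consists of
every submodel closed under marginality (an interaction enters only with all
its lower-order terms); for three factors this gives 19 models, ordered by
model size and then by term indices in design order.

Two target kinds are supported per cell:

- **lognormal mean** (default): θ_ijk = E(Y) with η_ijk = log θ_ijk
  = μ_ijk + σ²/2, estimated per model by η̂ = μ̂ + σ̂²/2 with the unbiased
  variance V̂(η̂) = σ̂² h_m + (σ̂²)² / (2(ν_m + 2));
- **log-scale mean** (the median of Y): η = μ_ijk, V̂ = σ̂² h_m. For this
  kind the studentized estimate is exactly t-distributed with ν_m degrees of
  freedom under the generating model.

Here σ̂²_m is the residual mean square (RSS/ν_m, unbiased, χ²_ν scaled — the
second variance term is unbiased for σ⁴/(2ν) only with this scaling), and
h_m is the cell-mean variance factor x₀ᵀ(XᵀX)⁻¹x₀. In a balanced
effect-coded design the columns of X are orthogonal with squared norm C·r
(C cells, r replicates), so h_m = p_m/(C·r): 1/r for the saturated model,
1/(C·r) for the intercept-only model. A `literal_r` sensitivity mode forces
h = 1/r for every model; it is exact only for the saturated model and is not
the default, because only the general factor keeps V̂ unbiased under every
candidate model.

## Model weights and the interval suite

AIC weights w_m ∝ exp(−AIC_m/2) are computed with
AIC = n·log(RSS/n) + 2(p+1) (Gaussian profile likelihood, σ² counted as a
parameter). Any additive constant cancels in the normalization, so only
relative AIC matters; the smallest AIC is subtracted before exponentiation
for overflow safety. Perfect fits (RSS = 0) receive AIC = −∞ and absorb all
the weight, split uniformly if tied; downstream interval constructors reject
the accompanying zero variance explicitly.

Six intervals are provided on the η scale and back-transformed by
exponentiation:

- **Full-Wald**: θ̂ ± t_{ν,1−α}·se from the saturated model.
- **MA-Wald**: θ̄ ± z_{1−α}·√V̂(θ̄) with the variance
  Σ w_m {(t_{ν_m,1−α}/z_{1−α})² V̂(θ̂_m) + (θ̂_m − θ̄)²}. The t/z ratio uses
  the same α as the requested interval.
- **MATA-Wald (z and t)**: the limits solve
  Σ w_m Pr(T_m ≤ (θ̂_m − θ_U)/se_m) = α and
  Σ w_m Pr(T_m ≥ (θ̂_m − θ_L)/se_m) = α with T_m ~ N(0,1) or t_{ν_m}.
- **MATA-SBoot**: the same tail equations with the per-model distributions
  replaced by the empirical distribution of the studentized parametric
  bootstrap statistic T*_m = (η̂*_m − η̂_m)/√V̂(η̂*_m), estimated from B
  resamples of the fitted version of model m. Note the bootstrap-t reversal:
  the upper limit is driven by the lower tail of T*_m.
- **Percentile bootstrap (PB)**: B resamples from the fitted full model;
  for each, the AIC-best model supplies θ̂*, and the limits are the
  ⌈α(B+1)⌉-th and ⌈(1−α)(B+1)⌉-th order statistics. AIC ties prefer the
  smaller model, then canonical order.

Weights inside the tail equations are always those computed once from the
original data, never recomputed per bootstrap sample.

## Numerical choices

- **Tail-equation solver.** Both weighted tail functions are strictly
  monotone in θ, so roots are unique. Scalar construction uses Brent's
  method (`xtol=1e-12`) on a bracket spanning all per-model estimates ± 20
  max standard errors, doubled geometrically up to 10 times if needed; the
  simulation engine uses an equivalent bisection vectorized over the eight
  cells (70 iterations, driving the bracket to rounding error). Tests check
  the two solvers agree to 1e-9 and that solutions satisfy the tail
  equations to 1e-8.
- **Empirical tail probabilities.** The ECDF of the B sorted statistics is
  piecewise linear through the plotting positions b/(B+1) and clamped to
  [1/(B+1), B/(B+1)] outside the sample range, hence continuous and
  nondecreasing with a unique root for the tail equations. This forces
  B ≥ 1/α − 1 (B ≥ 39 at α = 0.025), which is enforced wherever tails are
  built for or consumed by interval construction.
- **Sufficient-statistic resampling.** Under the Gaussian log-scale model
  the per-cell means and the pooled within-cell sum of squares are jointly
  sufficient and independent: means are N(fitted, σ̂²/r), the SS is
  σ̂²·χ²_{C(r−1)}. The bootstrap engine and the simulation study draw these
  statistics directly rather than materializing every resampled table; this
  is an exact distributional identity, not an approximation, and the test
  suite verifies agreement (two-sample KS) with the literal
  table-resampling path. Bootstrap refits with zero residual variance
  (probability zero; reachable only from pathological near-degenerate
  inputs) are redrawn and counted, with a warning above 0.1% of B.
- **Degenerate fits.** RSS = 0 is allowed in fitting (σ̂² = 0) but rejected
  by `eta_variance` and the resamplers, with explicit errors.

## Synthetic-data generator and simulation study

The generator emulates the study design: a 2³ factorial with r replicates
per cell, lognormal errors with variance σ² = 1 by default (skewness
coefficient (e^{σ²}+2)√(e^{σ²}−1) ≈ 6.2), overall effect fixed at 0, and
randomized effect magnitudes: each term's value is drawn N(0, magnitude²)
with magnitude 2 (High), 1 (Medium) or 0.1 (Low) by term type. The ten
scenario labels LLL … HHH order magnitudes as main/two-way/three-way,
reflecting the usual effect hierarchy. Each simulation replicate draws a
fresh effect set, so conclusions average over a neighbourhood of parameter
values rather than a single truth.

What the generator does **not** emulate: departures from lognormality
(gamma/Weibull responses), heteroscedastic σ², unbalanced layouts, factors
with more than two levels, or correlated errors. Passing tests therefore
demonstrate correct behaviour under the assumed model, not robustness to
its violation.

Per scenario and method the study reports the lower and upper error rates
(fraction of replicates with θ_L > θ and θ_U < θ, averaged over the eight
cells) and the mean relative half-widths (θ_L − θ)/θ and (θ_U − θ)/θ.
Replicate random streams are spawned deterministically from the scenario
seed, making results reproducible and invariant to the worker count.

Default problem sizes are chosen for confident single-machine runs:
n_sim = 2000 replicates and B = 199 bootstrap samples, giving a binomial
standard error of about 0.35% on an error rate near 2.5%. The full-scale
configuration (n_sim = 10⁵, B = 9999) is exposed as the `--preset full`
option of the CLI's `simulate` command and is intended for cluster use.

## Known limitations

- The tail-area construction does not guarantee exact coverage even when
  each T_m is exactly pivotal; the simulation study is the evidence base.
- The sample skewness of a lognormal(0, 1) sample converges very slowly
  (its Monte-Carlo spread involves sixth moments), so skewness checks at
  n = 10⁶ remain noticeably seed-dependent even though the closed form is
  exact.
- MATA-SBoot inherits the usual caveats of the studentized bootstrap: it
  requires each T*_m to be approximately pivotal and a stable standard
  error estimate; at very small B the ECDF clamp limits achievable α.
- Only two-level balanced factorials are supported; unbalanced data are
  rejected rather than approximated.
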