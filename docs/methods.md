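# Methods

## Planning model

The package sizes two-arm parallel CRTs, randomized 1:1 at the cluster
level, for a test of systematic treatment-effect heterogeneity: the
interaction `β₄` between the cluster-level treatment `W` and a single
individual-level effect modifier `X` in the linear mixed model

    Y_ij = β₁ + β₂W_i + β₃X_ij + β₄W_iX_ij + μ_i + ε_ij,

with exchangeable (compound-symmetric) outcome correlation `ρ_y` after
covariate adjustment. The complete-data variance of the GLS/REML estimator
is

    Var(β̂₄) = σ²_y(1−ρ_y){1+(m−1)ρ_y} / [n m σ²_w σ²_x {1+(m−2)ρ_y − (m−1)ρ_x ρ_y}],

a function of both the outcome ICC and the covariate ICC `ρ_x`; the required
`n` follows by inverting the two-sided z-test relation. Throughout, the test
is referred to the standard normal: no small-sample (Satterthwaite or
Kenward–Roger) degrees-of-freedom correction is applied, which is why very
small `n` scenarios can show empirical power slightly below prediction. A
warning is issued when a computed requirement falls below 10 clusters.

The variance denominator term `1+(m−2)ρ_y−(m−1)ρ_xρ_y` is bounded below by
`1−ρ_y > 0` whenever `ρ_x ≤ 1`, so genuinely infeasible parameter sets can
arise only through the unequal-cluster-size correction bracket (extreme CV);
both paths raise `InfeasibleDesignError` rather than returning a negative
requirement.

## Attrition under MCAR

Follow-up indicators `O_ij ~ Bernoulli(π)` are exchangeable within a cluster
with correlation `τ ∈ [−1/(m−1), 1]`. Attrition then acts exactly like
randomly varying cluster sizes: the observed size has mean `πm` and variance
`π(1−π)m{1+τ(m−1)}`. The requirement `n₁` evaluates the complete-data
formula at `πm` and multiplies by the correction factor

    CF(π, τ) = [1 − (1−π){1+τ(m−1)} ρ_y(1−ρ_y)(ρ_x−ρ_y) / (brace · {1+(πm−1)ρ_y}²)]⁻¹.

Two properties worth noting, both verified in tests:

* `CF = 1` exactly at `τ = −1/(m−1)` (every cluster loses the same number of
  people, so there is no size variability), and `CF` is increasing in `τ`
  when `ρ_x ≥ ρ_y`.
* The sign of `CF − 1` follows the sign of `ρ_x − ρ_y`: size variability
  costs power when the covariate ICC dominates and helps slightly when the
  outcome ICC dominates. Descriptions of this correction elsewhere sometimes
  state the opposite direction; the direction implemented here is the one
  consistent with the formula itself and with every tabulated requirement we
  reproduce.

The `n₁/n₀` ratio against the direct-inflation comparator is below 1
wherever `ρ_x ≥ ρ_y` (direct inflation is conservative there). In the
opposite corner (`ρ_x < ρ_y`, large `ρ_y`) the ratio can slightly exceed 1;
the grid export keeps unrounded requirements so such surfaces stay smooth.

## Attrition under MAR

Follow-up is allowed to depend on the effect modifier through a
mixed-effects logistic model `logit Pr(O=1|X,b) = α₀ + α₁X + b`,
`b ~ N(0, σ²_b)`. The missingness ICC is interpreted on the latent logistic
scale, `τ = σ²_b/(σ²_b + π²/3)` where `π²/3 ≈ 3.2899` is the logistic
residual variance (the circle constant, distinguished in code from the
follow-up rate, which regrettably shares the symbol). Note this latent-scale
`τ` is *not* numerically the same quantity as the binary-indicator
correlation used under MCAR; each mechanism uses its own stated definition
and no conversion is attempted, so `τ = 1` is attainable under MCAR (whole-
cluster attrition) but not under MAR.

Calibration solves `σ²_b` from `τ` in closed form and root-solves `α₀` so
the marginal follow-up rate hits the target `π`. Because the linear
predictor `α₀ + α₁X + b` is Gaussian for a normal covariate, the marginal
expectation collapses to one-dimensional Gauss–Hermite quadrature (80 nodes;
accuracy ≪ 1e−6); a binary covariate uses the two-point mixture over `X`
with quadrature over `b`.

The variance of `β̂₄` is estimated by simulation: draw covariates and
follow-up indicators for `n` clusters, accumulate the GLS information
`Σ Zᵢᵀ Rᵢ⁻¹ Zᵢ` of the observed design rows (mean-centered treatment codes
±1/2 under forced balance), average the 4×4 information over `B` draws
(default `B = 1000`), invert the *average* once, and scale the (4,4) element
by `σ²_y`. Inverting the averaged matrix (rather than averaging per-draw
inverses) matches the estimator being approximated and is robust to
occasional near-empty clusters; clusters losing all members contribute a
zero matrix — that is the realized design under attrition, so they are not
redrawn. Implementation note: because each cluster's contribution depends
only on (m_i, Σx, Σx²) and the arm code, the accumulation is fully
vectorized over draws and clusters; the compound-symmetry inverse is applied
in closed form, never numerically.

The search starts from the MCAR closed form (a cheap, close initial value)
and steps by ±2 clusters until power(n) ≥ target and power(n−2) < target.
Each candidate `n` is evaluated on its own deterministic substream derived
from the seed, so a candidate always sees the same draws regardless of the
path, making the search cache-consistent, reproducible, and immune to
oscillation from Monte Carlo noise. Seed-to-seed variation at `B = 1000`
moves the result by at most one ±2 step in our checks.

## Synthetic-data generators

The generators emulate the planning model exactly — they are the study
conditions, not approximations of a particular real dataset:

* Continuous covariate: `X = 0.5 + λ_i + γ_ij`, variance split `ρ_x σ²_x` /
  `(1−ρ_x)σ²_x` (the mean is irrelevant to power but reproduced for
  fidelity).
* Binary covariate: beta-binomial with marginal mean 0.3; shapes solved from
  the mean and `ρ_x = 1/(1+q₁+q₂)`; `ρ_x = 0` degenerates to a constant
  cluster rate.
* MCAR indicators: conditional-linear-family recursion for exchangeable
  binary vectors — the conditional mean of `O_j` given the previous draws is
  `π + τ/(1+(j−2)τ)·Σ_{k<j}(O_k−π)` — which realizes the full feasible `τ`
  range including the endpoints; requests outside the attainable range fail
  with the computed bounds.
* Outcomes: the linear mixed model above with `(β₁, β₂, β₃) = (0, 0.25,
  0.1)` by default (nuisance values; they do not affect the operating
  characteristics).
* Treatment: exactly `n/2` clusters per arm by permutation, so `W̄ = 1/2`
  and `σ²_w = 1/4` exactly.

What these generators do **not** emulate: baseline covariate imbalance
between arms, non-normal outcomes or covariates, cluster sizes that vary for
reasons other than attrition, missingness depending on treatment or outcome
(MNAR), and multivariate effect modifiers. Passing tests therefore certify
the internal consistency of the machinery under its own assumptions, not
robustness to violations of them.

A single seeded `numpy.random.Generator` threads through every generator;
replicate-level independence comes from `SeedSequence` spawning.

## Empirical validation

`run_study` simulates whole trials, restricts to observed rows, refits the
interaction model by REML (`statsmodels` `MixedLM`, random cluster
intercept) and applies the two-sided Wald z-test. Rejection rates under the
alternative and the null estimate power and type-I error with binomial
Monte Carlo standard errors. Fits are warm-started from OLS slopes plus a
one-way ANOVA estimate of the variance ratio, which roughly halves fit time
without changing the optimum; a failed fit is retried once on a fresh draw
from the same substream and otherwise excluded and counted (>1% failures
warns, >10% errors). The reference check at 228 clusters, 70% follow-up,
runs at 600 replicates per hypothesis in the acceptance script and 300 in
the test suite — scaled down from 3000 in the original study design, with
the binomial comparison bands widened accordingly.

## Worked example

The packaged example reproduces the planning grid for a workplace
flexibility trial (56 groups averaging 29 employees; outcome: control over
working hours at 6 months, `ρ_y = 0.14`, `σ²_y = 0.23`; baseline score as
effect modifier, `ρ_x = 0.058`, `σ²_x = 0.4`). The mean group size 29 is
used as the common `m`; observed-size variability enters only through the
attrition CV. Closed-form columns are exact and invariant to `τ`; the MAR
column is seeded and stable to ±2 clusters.

## Numerical conventions

* Requirements round **up** to the next even integer; an exact even integer
  stays (a 1e−12 guard absorbs float fuzz).
* Normal quantiles via `scipy.stats.norm.ppf`; powers via the one-tail
  formula `Φ(|δ|/√Var − z_{1−α/2})`, so `δ = 0` yields `α/2`.
* `ρ_y = 1` is rejected (singular compound symmetry); `m_i = 1` inverts to
  the scalar 1; `m_i = 0` contributes zero information.
* The MAR calibration brackets `α₀` in [−20, 20] and verifies the achieved
  marginal rate to 1e−6.
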