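# hteplan

Sample size and power for detecting **treatment-effect heterogeneity (HTE)**
in two-arm, 1:1 **cluster randomized trials (CRTs)** when some outcomes will
be missing at follow-up.

## Who this is for

Trialists and biostatisticians planning a CRT whose objective (primary or
secondary) is a treatment-by-covariate interaction — e.g. "does the
intervention work differently for participants with low baseline scores?" —
and who expect attrition. Standard HTE sample-size formulas assume complete
follow-up; dividing their answer by the expected follow-up rate is the usual
workaround, and it can over- or under-shoot. This package provides
principled alternatives for two missingness mechanisms, plus a simulation
engine that verifies the predictions.

## The model

Outcomes follow a linear mixed model with a random cluster intercept and an
individual-level effect modifier `X`:

    Y_ij = β₁ + β₂ W_i + β₃ X_ij + β₄ W_i X_ij + μ_i + ε_ij
    μ_i ~ N(0, ρ_y σ²_y),   ε_ij ~ N(0, (1 − ρ_y) σ²_y)

`W_i` is the cluster-level treatment indicator and `β₄` the HTE parameter.
The trial is sized so a two-sided Wald z-test of `H₀: β₄ = 0` has power
`1 − ζ` against the effect size `δ`, given the cluster size `m`, the adjusted
outcome ICC `ρ_y`, the covariate ICC `ρ_x`, the variances `σ²_y`, `σ²_x` and
the treatment-indicator variance `σ²_w = 1/4`.

Attrition enters through follow-up indicators `O_ij` with marginal rate
`π = Pr(O_ij = 1)` and within-cluster missingness ICC `τ`:

* **MCAR** (`n₁`, closed form): attrition independent of everything. The
  observed cluster sizes become random with mean `πm` and CV
  `√[(1−π){1+τ(m−1)}/(πm)]`; the complete-data formula is evaluated at `πm`
  and multiplied by a correction factor `CF(π, τ)`.
* **MAR** (`n₂`, Monte Carlo): follow-up depends on the effect modifier via a
  mixed logistic model `logit Pr(O_ij=1|X_ij,b_i) = α₀ + α₁X_ij + b_i` with
  `b_i ~ N(0, σ²_b)`, `τ = σ²_b/(σ²_b + π²/3)` on the latent scale. The
  variance of `β̂₄` is estimated by averaging GLS information matrices over
  simulated draws, and the smallest adequate even `n` is found by a ±2 search.
* **Direct inflation** (`n₀`, comparator): complete-data requirement divided
  by `π`.

All requirements are rounded up to the nearest even integer (equal arms).

## Worked example

How many clusters of 20 are needed to detect an interaction of `δ = 0.1`
(unit variances, `ρ_y = 0.01`, `ρ_x = 0.1`, α = 0.05, 80% power) if only 70%
of outcomes are expected, with missingness ICC 0.05?

```python
from hteplan import HTEDesign, AttritionSpec, CovariateSpec, Mechanism
from hteplan import n_complete, n_mcar, n_direct_inflation, search_n

design = HTEDesign(m=20, rho_y=0.01, rho_x=0.1, delta=0.1)
mcar = AttritionSpec(mechanism=Mechanism.MCAR, pi=0.7, tau=0.05)

print(n_complete(design).n)          # 160  (no attrition)
print(n_mcar(design, mcar).n)        # 228  (MCAR-adjusted)
print(n_direct_inflation(design, mcar).n)  # 228  (naive comparator)
print(round(n_mcar(design, mcar).predicted_power, 3))  # 0.802

# if missingness actually depends on X (slope 0.5 on the log-odds scale):
mar = AttritionSpec(mechanism=Mechanism.MAR, pi=0.7, tau=0.05, alpha1=0.5)
cov = CovariateSpec(kind="continuous", rho_x=0.1)
print(search_n(design, mar, cov, B=1000, seed=1).n)  # 238
```

The MCAR answer says 228 clusters keep 80% power once a third of outcomes
are lost (up from 160 with complete data). If the loss is concentrated among
people with low `X`, the Monte Carlo search shows 228 is optimistic — 238
clusters are needed. The same calculations are available from the shell:

```bash
hteplan size --method mcar --m 20 --rho-y 0.01 --rho-x 0.1 \
    --delta 0.1 --pi 0.7 --tau 0.05
hteplan example wfhs --skip-mar     # packaged workplace-trial example
hteplan validate --m 20 --rho-y 0.01 --rho-x 0.1 --delta 0.1 \
    --n 228 --pi 0.7 --tau 0.05 --reps 500 --seed 1
```

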