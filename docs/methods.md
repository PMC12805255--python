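# Methods

## Models and estimands

For subject `i` with exposure `X_i`, covariates `Z_i`, mediators
`M_i ∈ R^p`, event time `D_i`, censoring time `C_i`, observed time
`T_i = min(D_i, C_i)` and indicator `Δ_i = 1{D_i ≤ C_i}`, the package
works under a linear mediator model with exposure coefficients `α` and
a Cox proportional hazards outcome model with mediator coefficients
`β`, direct effect `γ`, and an unspecified baseline hazard.  The true
mediator set is `H₁ = {j : α_j ≠ 0 and β_j ≠ 0}`; on the log-hazard
scale `NIE_j = α_j β_j (x − x*)` and `NDE = γ (x − x*)`.  The package
estimates `H₁` with finite-sample FDR control and reports the plug-in
effect estimates for the selected set.  Identification assumptions
(no-unmeasured-confounding conditions) are taken as given; nothing in
the software can verify them.

## Why data splitting controls the FDR

Conditional on the candidate set, the two halves of a split are
independent.  For a null mediator the Group-I (penalized) and Group-II
(refit) coefficient estimates are independent and the refit estimate is
centered at zero, so the mirror statistic
`Q_j = sign(β̂¹_jβ̂²_j)(|β̂¹_j|+|β̂²_j|)` is symmetric about zero; large
negative `Q`s therefore count false positives among the large positive
ones, making `#{Q ≤ −τ}/max(#{Q ≥ τ},1)` a conservative FDP estimate at
threshold `τ`.  Aggregating over `B` splits through inclusion rates
stabilizes the selection: each split distributes a total importance of
at most 1 across its selections, and cutting the sorted rates so that
the mass at or below the cutoff stays within `q2` bounds the expected
share of false selections.  This control is distribution-free in the
mediators — the reason the procedure remains valid for correlated,
beta-distributed methylation values.

One sharp edge inherited from the literal selection rule: because `q2`
enters both the per-split threshold and the aggregation budget, the
final selection is *not* monotone in `q2`; in particular, when the whole
inclusion-rate mass fits inside the budget (tiny signal, or very large
`q2`) the rule selects nothing.  Per-split selections are monotone in
`q2` and that invariant is tested.

## Solvers

**Breslow partial likelihood.**  All fits use risk sets computed by one
descending-time scan after sorting (`O(n log n)`), with the Breslow
convention for ties (exact for the simulator's continuous times).  The
linear predictor is centered (a partial-likelihood invariance) and
clipped at ±100 so risk sums can neither overflow nor underflow; the
clip only binds under separation.

**Group-I MCP solver.**  Minimizes `(1/n)·npll(β) + Σ_j MCP(β_j; λ, a)`
over the mediator block, exposure and covariates unpenalized, by cyclic
coordinate descent on an iteratively reweighted quadratic (diagonal
Hessian weights).  Mediator columns are standardized internally;
coefficients are reported on the original scale.  The coordinate update
is the exact scalar MCP minimizer, including the concave branch that
arises when the working curvature `v_j` falls below `1/a` — there the
minimizer jumps between 0 and the flat-region boundary, so the MCP path
is genuinely discontinuous in `λ` (the lasso limit `a → ∞` is
continuous, and that is the form in which path continuity is tested).
The path is log-spaced over 30 penalties from `λ_max` (smallest penalty
with an all-zero mediator block) down to `0.01·λ_max`, warm-started.
Convergence: coefficient sup-norm below 1e-6, at most 1000 reweighting
iterations.  The inner coordinate loop is JIT-compiled.

**Penalty tuning.**  `λ` is chosen per split by BIC,
`−2·loglik + log(#events)·|active set|` (default), or by the
Verweij–van Houwelingen cross-validated partial likelihood
(`tuning="cv"`).  BIC is deterministic, adds no within-split randomness
and is roughly 5× faster; it selects close to the oracle support at
n ≥ 400.  CV selects more liberally and more noisily, which lowers
power at balanced splits but degrades gracefully when Group I is very
small.  One observable consequence of the BIC default: power varies
smoothly and monotonically with the split proportion (a smaller Group I
costs less than a larger refit group gains), so the half-half optimum
reported for noisier tuning rules does not reproduce as an interior
maximum here, although the half-half operating characteristics
themselves agree with the replication harness results.

**Group-II refit.**  Exact-Hessian Newton–Raphson with step-halving
(log partial likelihood non-decreasing across iterations), tolerance
1e-6, at most 100 iterations.  Monotone likelihood (separation) is
detected when a coefficient passes |β| = 20; the coefficient is capped
and the fit flagged.  The refit agrees with an established Cox
implementation to 1e-5 on random instances, and the penalized solver at
`λ → 0` agrees with the refit to 1e-4.

**MCP concavity `a = 3`** follows the conventional default of reference
MCP implementations; it is configurable.

## Simulator

The generator mirrors the validated study conditions: `X ~ Ber(0.6)`,
`Z = (Ber(0.3), U(0,1))`, `γ = 0.5`, `θ = ϑ = (0.3, −0.2)`, mediator
intercepts 0, and sparse coefficient patterns
`α[1..10] = κ_α·(1,1,1,1,−1,−1,−1,−1,1,−1)`,
`β[1..12] = κ_β·(1,1,1,1,1,1,1,1,0,0,1,−1)`, so `H₁ = {1,…,8}`, indices
9–10 are exposure-associated nulls and 11–12 outcome-only nulls.
Gaussian mediator errors follow a stationary AR(1) recursion giving the
Toeplitz correlation `ρ^{|k−l|}` at `O(np)` cost; beta-distributed
mediators use logit-linear means `μ_ij` and per-mediator precisions
`φ_j` with `M_ij ~ Beta(φ_j μ_ij, φ_j(1−μ_ij))`.  The `φ_j` default to
log-uniform on [2, 100], spanning typical array-methylation precisions;
any sampler or fixed vector can be plugged in.  Event times are
exponential with rate `0.5·exp(linear predictor)` (predictor clipped at
±50 with a logged warning) and censoring is exponential with rate `c0`.

**Censoring calibration.**  `c0` solves
`mean_i c0/(c0 + λ_i) = target` — the exact censoring probability for
competing exponentials — over a fixed-seed Monte-Carlo draw of 10⁵
subject hazards (only the twelve outcome-relevant mediator columns are
generated; the AR(1) recursion makes that leading block exact).  Root
bracketing on [1e-6, 1e6]; realized censoring lands within ±0.02 of the
target across replicates.

**What the simulator does not emulate:** probe-level measurement error,
genome-scale block correlation beyond AR(1)/shared-covariate structure,
batch effects, informative censoring, or missing data.  Passing tests
therefore demonstrate correctness of the selection machinery under the
stated generative models, not robustness to real-data artifacts.

## Scenario registry and replication harness

`correlated` / `split-prop` (n=500, p=2000, κ=(0.50,0.35), 30%
censoring, ρ configurable), `sample-size` (ρ=0.6, 60% censoring, same
κ), `beta` (κ=(0.90,0.80), beta mediators).  The κ values for the
split-proportion and sample-size studies are assumed equal to the
correlated setting's printed values; the sample-size source did not
restate them, and the measured screening ceiling at n=100 (on average
fewer than one of eight true mediators survives BH screening at
κ_α=0.50) indicates the original sub-study likely used stronger unstated
scalings — its small-n power figures should be read with that caveat.

`replicate_cell` runs independent replicates from spawned seed streams
(deterministic given the master seed, order-independent), calibrates
`c0` once per cell, and reports mean FDR/TPP with Monte-Carlo standard
errors.  Default replication in the test suite and acceptance script is
12–60 replicates per cell (chosen so a full sweep stays a routine run);
`--reps-scale` in `scripts/acceptance.py` scales every count toward the
original 500-replicate design.

## Defaults

| parameter | default | meaning |
|---|---|---|
| `q1` | 0.2 (simulations) | BH level of the screening step; cohort analyses used 5e-4 / 0.05 |
| `q2` | 0.1 | target FDR of the final selection |
| `B` | 25 | number of data splits |
| `split_prop` | 0.5 | Group-I share of the sample |
| `aggregation` | `ira` | inclusion-rate aggregation (`qa` available) |
| `eta` | 0.05 | quantile level of the QA statistic (type-7 quantile) |
| `mcp_a` | 3.0 | MCP concavity |
| `tuning` | `bic` | per-split λ rule (`cv` available) |
| contrast | 1.0 | exposure contrast `x − x*` for effect reports |

## Known limitations

Breslow ties only (fine for continuous times; heavy real-data ties
would favor Efron).  No standard errors or post-selection inference for
the reported effects — they are descriptive summaries after selection.
Degenerate splits (a group without events) are redrawn up to three
times, then recorded as empty selections to keep `B` fixed.  Screening
assumes complete data; missing values are an input error by design.
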