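# Methods

## The model

The data-generating model is a pairwise binary Markov random field on
`{0,1}^p`, parameterised by a symmetric positive matrix `M` of odds ratios:

    P(x) ∝ exp( Σ_i h_i x_i + Σ_{i<j} J_ij x_i x_j ),
    h_i = ln M_ii  (baseline odds),  J_ij = ln M_ij  (i ≠ j).

With this convention the full conditional of each variable is logistic,

    logit P(X_i = 1 | x_-i) = h_i + Σ_{j≠i} J_ij x_j,

so an off-diagonal entry `M_ij` is exactly the conditional odds ratio of
`X_i` and `X_j` given the rest, `M_ij = 1` means conditional independence,
and the support of `J` is the conditional-independence graph. We work on
the log scale deliberately: treating the odds ratios themselves as additive
logit contributions would make an all-ones matrix (no interactions) depend
on the number of active neighbors, which contradicts the odds-ratio
interpretation. An all-ones `M` yields `p` independent Bernoulli(1/2)
variables — a convenient null model.

## Gibbs sampler

One chain per dataset; each sweep updates variables `1..p` sequentially
from their full conditionals. The starting state draws each variable
independently from its baseline odds `M_ii/(1+M_ii)`. Defaults: 5000
burn-in sweeps and 10 sweeps between recorded observations, so recorded
rows are nearly independent draws. The sampler is seeded and bit-for-bit
reproducible; provenance (seed, burn-in, spacing) is recorded on the
dataset. `exact_joint` enumerates all `2^p` state probabilities (p ≤ 20)
and is the oracle the sampler is validated against (chi-square
goodness-of-fit on the 64-state joint of the six-variable benchmark).

## Benchmark structures

* `m6` — six variables: a 4-cycle `X1–X2–X4–X3–X1` with all present odds
  ratios 2 and baseline odds 1, plus two isolated noise variables.
* `paper19` — twenty variables: a fixed, documented 19-edge structure
  connecting `V01..V18` (a 12-cycle `V01..V12` with the chord `V01–V07`
  and six branch nodes: `V13–V03`, `V14–V06`, `V17–V14`, `V15–V09`,
  `V16–V12`, `V18–V16`), plus isolated `V19`, `V20`. All present edges have
  odds ratio 2, all baseline odds are 1. The topology mimics the circle-like
  subgraphs with short branches seen in graphical models of clinical
  functioning data while keeping maximum degree small (≤ 4); an empty
  estimate scored against it has SHD 19.

## Penalized logistic solver

The node-wise fits minimise the unscaled penalized negative log-likelihood
`−ℓ(β0, β) + λ‖β‖₁` with an unpenalized intercept, by iteratively
reweighted least squares with cyclic coordinate descent on the working
quadratic (soft-thresholding gives exact zeros). Predictors are
standardized to mean 0, variance 1 (population divisor) before fitting;
active sets refer to standardized-scale coefficients (zero is
scale-invariant). Numerical choices:

* Convergence is declared when the KKT stationarity conditions of the true
  objective hold within 2e-7, guaranteeing the advertised 1e-6 certificate
  (`|x_j'(y−π)| ≤ λ` for zero coefficients, `= λ·sign(β_j)` for nonzero,
  intercept score 0).
* Linear predictors are clipped at ±30 and IRLS weights floored at 1e-6 to
  guard quasi-separated resamples; the outer loop is capped at 200
  iterations.
* Penalty grid: 100 log-spaced values from `λ_max` (the largest absolute
  score at the intercept-only fit — the smallest penalty with an empty
  active set) down to `λ_max × 1e-3`. Paths are computed in decreasing-λ
  order with warm starts.

Penalty selection: stratified seeded 10-fold cross-validation maximising
mean out-of-fold log-likelihood (refolded up to 10 times if a training fold
is single-class); AIC `−2ℓ + 2k` / BIC `−2ℓ + k ln n` with `k` = number of
nonzero slopes (intercept excluded), ties resolved toward the larger
penalty; or the size rule — the largest grid penalty whose active set has
at least `l` members (the realized set may overshoot when several
coefficients enter together and is used as-is).

## Graph estimation

Single-lasso methods (`lasso-cv`, `lasso-aic`, `lasso-bic`) select one
penalty per node on the data and read the neighborhood off the active set.
Constant columns cannot be outcomes or predictors; they are excluded with a
warning and kept as isolated nodes so node sets remain comparable.

Bolasso (`bolasso`, `bolasso-cv`) draws `B` row resamples with replacement
(resample `b` seeded `seed + b`), refits every node, and records selection
frequencies `μ_ba`; the neighborhood keeps `b` when `μ_ba ≥ π_cut`.
Frequencies are retained so several thresholds can be re-applied without
refitting, and edge sets shrink weakly as `π_cut` grows. Two penalty
protocols:

* `bolasso-cv`: the cross-validated penalty is fixed once per node on the
  original data and reused in every resample (classical bagged-lasso
  protocol).
* `bolasso` (size rule): the penalty is re-selected **within each
  resample** as the largest grid value whose active set reaches the target
  size `l`. A penalty tuned to a neighborhood size transfers across
  resamples as a size, not as a fixed λ: the size-`l` penalty sits exactly
  at the entry boundary of the `l`-th variable, so refitting resamples at
  that fixed λ leaves every candidate's selection frequency hovering near
  the boundary (we measured μ ≈ 0.3–0.9 for true neighbors on the
  six-variable benchmark, and recovery essentially never succeeds at
  `π_cut = 0.90`), defeating the aggregation. With per-resample size
  targeting, true neighbors are selected in nearly all resamples while
  noise variables rotate, which is the behaviour that makes bagging
  effective. The walk re-uses the original-data grid and warm starts, so it
  costs only a few extra fits per resample.

Resamples whose outcome is single-class contribute an empty active set but
stay in the denominator of `μ` (conservative, keeps `μ` a multiple of
`1/B`); predictors constant within a resample get coefficient zero.

Edge combination: AND-rule `ε = {(a,b) : a ∈ ne_b ∧ b ∈ ne_a}`, OR-rule
with `∨`. AND ⊆ OR always; the CLI default is OR, matching the aggregation
step of the Bolasso algorithm, and the study driver always evaluates both.

## Evaluation

Confusion counts run over all `p(p−1)/2` unordered pairs. SHD = FP + FN
(the edge edits needed to reach the truth); sensitivity `q = TP/(TP+FN)`;
specificity `TN/(TN+FP)`; Youden `J = q + specificity − 1`. We use the
standard sensitivity/specificity definitions: they keep `J` defined for
empty estimates (an empty estimate against a nonempty, non-complete truth
scores exactly `J = 0`, which is what makes `J` the right complement to
SHD, since SHD alone rewards empty models). Vacuous-denominator
conventions: `q := 1` for an edgeless truth, specificity `:= 1` for a
complete truth.

## Simulation-study driver

`run_study` sweeps `(method, rule, n, B, π_cut, l)` with seeded replicates.
Default grids follow the benchmark study design: `n ∈ (50, 100, 200, 500,
1000)`, `B ∈ (40, 80, 120, 160, 200)`, `π_cut ∈ (0.90, 0.95, 0.99, 1.00)`;
the default size grid is thinned to `(1, 2, 5, 10, 18)` to keep desk-scale
runtime (the full `1..18` range is one config field away). Replicates
default to 10 per cell. Per-cell seeds are `base_seed + crc32(cell key)`,
so results are reproducible and extending a grid does not shift existing
cells. Efficiency: bootstrap refits run once at `max(B_grid)` and smaller
`B` reuse the leading resamples; all thresholds are applied to stored
frequencies; both rules are scored from the same neighborhoods;
non-applicable parameters are recorded as nulls.

`optimal_configuration` fits an ordinary least-squares model of SHD (or J)
on factor-coded `π_cut`, `B`, `l` plus the `π_cut × l` interaction — the
simplest member of the GLM family, with the raw cell-mean optimum reported
alongside as a robustness check — and returns the grid cell with the best
fitted value. `π_cut` and `l` must have at least two levels; `B` is
dropped from the model (not the answer) when it does not vary.

## What the generator does and does not emulate

The synthetic benchmark has homogeneous effect sizes (all conditional odds
ratios 2), balanced margins, no missingness, and exact pairwise structure.
Real clinical binary data have heterogeneous effects, skewed margins,
higher-order interactions and measurement error; passing the benchmark
therefore demonstrates correctness of the estimators and the expected
ordering of methods/thresholds, not field performance on any particular
dataset.

## Problem sizes used in the shipped checks

The test suite and the reproduction script use desk-scale versions of the
study: the threshold sweep runs the 20-node structure at `n = 500`,
`B = 200`, `l ∈ {2, 5, 10}` with 10 replicates; sampler validation uses
50 000 spaced draws from the six-variable model; recovery checks use 20
replicates at `n ∈ {100, 1000}`. These sizes were chosen so a full check
runs in minutes on a single core while leaving the stochastic margins
comfortable.

## Known limitations

* Pairwise interactions only; no continuous or mixed variables.
* One Gibbs chain without convergence diagnostics (burn-in is fixed, not
  adaptive).
* The size-rule grid walk assumes active-set size is locally monotone in λ;
  occasional non-monotone paths can make the "largest penalty reaching
  size l" locally rather than globally optimal (harmless in aggregation).
* `optimal_configuration` assumes an additive cell-mean structure plus one
  interaction; strong higher-order interactions would call for the raw
  cell means it also reports.
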