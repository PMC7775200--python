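# Methods

## The estimation model

The wellness index is linear in 7 daily behavior variables, estimated by
a one-way random-effects panel regression

y_it = β₀ + Σₖ βₖ x_k,it + μ_i + u_it,  μ_i ~ N(0, σ_μ²), u_it ~ N(0, σ_u²),

fit by Swamy–Arora feasible GLS: σ̂_u² from the within (fixed-effects)
residual sum of squares with N − n_units − K degrees of freedom; σ̂_μ²
from the between (unit-means) regression, σ̂_μ² = max(0, SSR_b/(n−K−1) −
σ̂_u²/T_h) with T_h the harmonic mean unit size (the max(0, ·) is the
standard negative-variance truncation; the harmonic-mean correction is
one of several equivalent unbalanced-panel conventions and only matters
for realism, not for the GLS algebra).  Estimation then quasi-demeans
y, X and the intercept by θ_i = 1 − √(σ̂_u²/(σ̂_u² + T_i σ̂_μ²)) per unit
and runs OLS; with known variance components this is algebraically exact
GLS, which the test suite verifies against a brute-force (X'Ω⁻¹X)⁻¹X'Ω⁻¹y
oracle to 1e-8.  Standard errors are conventional FGLS SEs,
√(σ̂_u² diag((X*'X*)⁻¹)); no robust correction is applied because the
bias measures use point estimates only.

Unit identity always comes from `unit_id`.  The 40 one-hot dummy columns
exist so the data set has the documented 884×49 design shape and so
imputers can exploit them; the random-effects fit never uses them.

Infeasible fits — fewer than 9 rows, rank-deficient regressors, fewer
than 2 units, or no repeated observations within units — raise a typed
`MethodFailure` rather than returning a silently wrong answer.  This is
the mechanism by which listwise deletion "fails" at high missingness.

## The synthetic reference panel

The generator emulates a 41-person × 28-day student lifelog panel: 1148
collected unit-days, 264 dropped uniformly at random (the study's
device-failure exclusions, treated as ignorable), leaving 884 complete
rows of 7 behavior variables plus a perceived-score proxy, all on [0, 1].

* **Marginals.**  Each behavior variable matches a published mean/SD and
  support: meal ratings are graded on {0, .33, .66, 1} (probabilities
  solved to hit the mean exactly and the SD as closely as the support
  allows), exercise is binary (mean .053; the implied SD .224 matches the
  published value exactly), and the achievement percentages are
  continuous, matched by scaled Beta distributions (sleep achievement on
  [.067, 1], its published range).
* **Dependence.**  A Gaussian copula with low-rank latent scores:
  Z = F·Λ' + ε with rank(Λ) = `latent_rank` (default 5) and 90% of each
  latent score's variance carried by the shared factors
  (`communality = 0.9`), mapped through each variable's quantile
  function.  This preserves an approximately low-rank measured block —
  the property that makes matrix-completion imputation interesting — and
  the generated 884×8 block's top 6 singular values carry ≥ 90% of its
  centered variance (asserted in tests).  Discretization of the graded
  and binary variables attenuates the latent correlations, so the
  realized cross-variable dependence is weaker than the latent 0.9.
* **Proxy score.**  y follows the random-effects model with the
  published coefficient estimates as ground truth (intercept 0.305,
  slopes 0.097, 0.105, 0.088, 0.087, 0.061, 0.131, 0.066), σ_μ = σ_u =
  0.1, clipped to [0, 1].  σ_u = 0.1 keeps clipping below ~1% of rows;
  σ_μ = 0.1 was chosen so the model-implied SD of y,
  √(Var(Xβ) + σ_μ² + σ_u²) ≈ 0.158, matches the published proxy-score
  SD of 0.159.  The time variable maps day d linearly to (d−1)/(n_days−1)
  ∈ [0, 1], consistent with the all-variables-in-[0,1] convention.

What the generator does **not** emulate: real exclusions are not
uniformly random (device failures cluster); real behavior series are
autocorrelated in time and the copula draws days independently;
intervention/reminder effects on missingness are absent; and the real
participants' coefficients are unknowable, so all results are relative
to the synthetic reference fit, not the original study's estimates.
Passing tests therefore demonstrate correct machinery and qualitative
method ordering on data with the stated marginal and low-rank structure,
not quantitative biases for any real cohort.

## Missingness

MCAR masks are drawn uniformly without replacement over the 884×8
measured cells only (7072 cells; identifiers, dummies and time are
bookkeeping, not collected lifelogs — and masking them would make
listwise deletion fail far below any realistic ceiling).  Each mask
deletes exactly round(p/100 × 7072) cells, round-half-to-even.
Per-replicate seeds derive from SeedSequence((master_seed, p, s)), so any
single (p, s) cell reproduces in isolation.

## The six handling methods

* **Listwise deletion** keeps complete rows; fails at 0 complete rows,
  or downstream when the reduced panel cannot support the fit.
* **Mean imputation** substitutes observed column means.
* **kNN**: k is the odd integer nearest √(#complete rows), ties broken
  downward (884 complete rows → k = 29).  Distances are Euclidean over
  the target row's observed coordinates, rescaled by √(8/n_obs); donors
  are the complete rows; imputations are Gaussian-kernel (exp(−d²))
  weighted donor averages, with a uniform-average alternative.  A row
  with no observed measured value has no distance to any donor → method
  failure; this is what truncates kNN's curve at high missingness
  (P(all 8 cells missing) = p⁸ per row).
* **Low-rank (soft-impute)**: iterative SVD soft-thresholding
  Z ← S_λ(P_obs(X) + P_miss(Z)) on the column-centered full study matrix
  (dummies + time + measured, 884×49) — the design columns are always
  observed and let the singular vectors carry unit-level structure; only
  measured cells are imputed, clipped to [0, 1].  λ is selected by warm
  starts down a 20-point log grid from λ_max to λ_max/100, scored on a
  held-out 5% validation mask of observed measured cells, then refit on
  all observed cells warm-started from the winner.  Convergence uses the
  canonical squared relative Frobenius criterion ‖ΔZ‖²/‖Z‖² < 1e-5
  (an unsquared 1e-5 is unattainable within the 500-iteration budget at
  the small end of the grid), with the denominator floored at the data
  scale so the exact-zero solution at λ ≥ λ_max converges.  The rank cap
  defaults to min(dims)−1 and is exposed (`max_rank`), mirroring the
  reference implementation's `rank.max`.  The selection-by-validation
  step is the method's weakest link at very high missingness, where the
  validation curve is nearly flat in λ: a 1-SE parsimony rule was
  evaluated and rejected (it collapses to rank-1 solutions).
* **EM-MI (bootstrap-EM)**: for each of m = 5 imputations, a row
  bootstrap propagates parameter uncertainty; EM estimates the
  multivariate-normal mean/covariance of the 8 measured variables
  (pattern-grouped E-step; ridge 1e-4·I on the covariance; convergence
  at max parameter change < 1e-6, up to 500 iterations); missing cells
  are drawn from their conditional normals and clipped to [0, 1].  A
  variable with < 2 observed values in the resample, or a singular
  observed-block covariance, is a method failure.
* **PMM-MI (chained equations)**: 10 sweeps over the 8 variables,
  predictors = the other 7 (current fill) + time; Bayesian linear
  regression with the standard noninformative posterior; type-1 matching
  (posterior-draw predictions for missing cells, posterior-mean
  predictions for donors); 5-donor pools with a uniform donor draw; the
  m = 5 chains run independently from independent random-observed-value
  fills.  Imputed values are always members of the variable's observed
  set, so no clipping is needed.

All methods preserve observed cells exactly, and every completed data
set is verified complete on construction.

## Bias measures and comparison

MAB averages the absolute deviations of the 8 coefficients (intercept
included) from the reference fit; GAB averages the MABs over replicates
at one proportion and is **undefined unless every replicate succeeded**
(a partial-mean mode exists behind `allow_partial`, off by default).
Multiple-imputation coefficient sets are pooled by Rubin's rules before
the MAB (point estimate = mean; total variance = W̄ + (1 + 1/m)B).

Methods with defined GAB at a proportion are compared pairwise by the
Dunnett modified Tukey–Kramer (Dunnett C) procedure: CI half-width
q(α, J, ν)/√2 · √(s_A²/n_A + s_B²/n_B) with the studentized-range
quantile at family size J (methods in the comparison) and
Welch–Satterthwaite ν; a method wins a pair when the CI excludes zero in
its favor.  Quantiles come from `scipy.stats.studentized_range`,
validated against published tables (q(.05, 6, 120) = 4.10).  Win counts
are summed over the proportion ranges 1–30%, 31–60%, 61–80%.

## Scale and runtime choices

The full design (80 proportions × 200 replicates × 6 methods) is the
documented long-running mode.  The tested default is the smoke scale —
p ∈ {10, 40, 70}% with 20 replicates — which exercises every stage,
including the listwise/kNN failure regime at 70%, in a few minutes.  At
20 replicates the DTK comparison has limited power: bias differences of
~0.01–0.02 between the best imputation methods at 70% missingness fall
inside the CI half-width (~0.025), so ties in the superior set at high
missingness are expected at smoke scale that resolve into a sole winner
at the 200-replicate design (verified for p = 70% in development runs).

## Known limitations

* The failure ceilings depend on this implementation's feasibility
  conditions (rank checks, donor availability, covariance
  invertibility), which are principled analogues — not replicas — of the
  R packages' internal thresholds; our bootstrap-EM with a ridge prior,
  in particular, remains feasible at proportions where Amelia-style EM
  reportedly fails.
* λ selection for soft-impute by a single 5% validation mask is noisy at
  high missingness (see above).
* GAB strictly requires all replicates to succeed; a single unlucky
  replicate undefines a method at that proportion, which is faithful to
  the "no GAB" semantics but makes the defined/undefined boundary itself
  a random variable.
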