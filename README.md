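# lwibench

Benchmarking missing-data handling methods for estimating a
**lifelogs-based wellness index (LWI)** from panel health-behavior data.

## The problem

A lifelogs-based wellness index maps daily health-behavior lifelogs
(meal-quality ratings, exercise, step / sleep-duration / "golden-time"
achievement, collected by smartwatch and app) to a single 0–100 wellness
score.  With a panel of daily observations per person, the index
coefficients are estimated by a one-way random-effects regression

```
y_it = β₀ + Σ_k β_k x_k,it + μ_i + u_it,     μ_i ~ N(0, σ_μ²),  u_it ~ N(0, σ_u²)
```

where `y_it` is person *i*'s perceived wellness score on day *t*,
`x_k,it` are the 7 behavior variables (all min-max normalized to [0, 1]),
and `μ_i` absorbs person-specific heterogeneity.  Lifelog panels are
riddled with missing data (forgotten devices, drained batteries), and the
choice of missing-data handling method can bias the estimated
coefficients badly — increasingly so as the missingness proportion grows.

`lwibench` is a tested, reusable simulation pipeline that quantifies that
bias for six handling methods:

| method     | type                  |
|------------|-----------------------|
| `listwise` | complete-case analysis |
| `mean`     | single imputation (column mean) |
| `knn`      | single imputation (k-nearest neighbors, k ≈ √#complete, odd) |
| `lowrank`  | single imputation (soft-threshold SVD matrix completion) |
| `em_mi`    | multiple imputation (bootstrap-EM multivariate normal, m = 5) |
| `pmm_mi`   | multiple imputation (predictive-mean matching chained equations, m = 5) |

The pipeline: generate a complete synthetic **reference panel** (41 units
× 28 days, 884 complete rows after exclusions, 49 design columns) with
known ground-truth coefficients and a low-rank latent structure across
the behavior variables; inject MCAR masks at each missingness proportion
*p* (1–80%); apply each handling method; refit the random-effects model
(pooling multiple imputations by Rubin's rules); compare each coefficient
value set with the reference fit via the **mean of absolute biases**
(MAB, mean over the 8 coefficients of |β̂ₖ − âₖ|); average the replicate
MABs into the **grand mean of absolute biases** (GAB) per (p, method);
and compare methods per proportion with Dunnett's modified Tukey–Kramer
(DTK) pairwise procedure at α = .05, counting for each method the
pairwise comparisons it wins with statistically smaller bias.  A method
that cannot complete a data set (e.g. listwise deletion leaving too few
complete rows) is recorded as a *method failure* and has no GAB at that
proportion.

## Worked example

```python
import lwibench as lw

# step 0: synthetic reference panel + reference coefficients
reference, ref_coefs = lw.generate_reference(lw.GeneratorConfig(seed=0))
print(len(reference.frame), lw.build_design(reference).shape)
# 884 (884, 49)
print([round(a, 3) for a in ref_coefs.a])
# [0.334, 0.085, 0.098, 0.08, 0.065, 0.062, 0.111, 0.079]

# inject 10% MCAR missingness and impute with matrix completion
incomplete, pattern = lw.inject_mcar(reference, p=10, seed=42)
print(len(pattern.cells))          # 707 of the 7072 measured cells
result = lw.soft_impute(incomplete, seed=1)
coef, _ = lw.fit_random_effects(result.completed[0])
rec = lw.compute_mab(coef, ref_coefs)
print(round(rec.mab, 4))           # 0.0111 — mean abs coefficient bias
```

The reference fit lands near the generating coefficients (intercept 0.305,
slopes 0.097 … 0.066) up to sampling noise, and a 10% MCAR mask handled by
low-rank imputation perturbs the 8 coefficients by ≈0.01 on average.

A complete benchmark sweep:

```python
res = lw.run_experiment(lw.ExperimentConfig(scale="smoke", master_seed=1))
print(res.gab_table())     # GAB per (p, method); NaN where a method failed
print(res.range_sums)      # DTK win totals per proportion range
lw.plot_results(res, "figures/")
```

`scale="smoke"` runs p ∈ {10, 40, 70}% with 20 replicates in minutes;
`scale="full"` is the long-running 80-proportion × 200-replicate design.
The same stages are available from the shell via the `lwibench` command
(`generate`, `inject`, `impute`, `fit`, `evaluate`, `compare`, `run-all`,
`plot`).

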