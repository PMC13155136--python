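# cooplda

Analysis of limiting dilution assays (LDAs) when clonogenic growth is
cooperative or competitive.

In an LDA, a geometric dilution series of single cells is seeded into
replicate wells (`S` expected cells per well, `n` wells per dilution) and
each well is scored for clonogenic growth. The classical single-hit Poisson
model assumes every cell founds a colony independently with probability `p`,
so the expected number of active cells per well is `λ = p·S` and the
probability a well fails to grow is `μ = e^{−pS}`. Many cell populations
violate that independence assumption: cells support each other through
secreted factors (cooperation) or compete for nutrients, and frequency
estimates from the linear model then swing wildly with assay conditions.

`cooplda` fits the power-law generalization

```
λ = p · S^b          μ = exp(−p · S^b)          ln(−ln μ) = α + b·ln S
```

with `α = ln p` — a binomial GLM with log–log link on the fraction of
negative wells. `b = 1` recovers the single-hit model, `b > 1` indicates
cooperative and `0 < b < 1` competitive growth. From the fit it derives:

* the **clonogenic activity** `a = e^{−α/b}` — the number of cells to seed
  per well so that on average one active cell arises (leaving `1/e ≈ 37%` of
  wells without growth) — with a Fieller-type confidence interval obtained
  by inverting the link-scale confidence band (or, optionally, first-order
  error propagation);
* **survival fractions** `SF_t = a_0 / a_t = e^{α_t/b_t − α_0/b_0}` of each
  treatment against the untreated reference, with 95% intervals built by
  combining the 83.5% intervals of the two activities;
* a **likelihood-ratio test and ΔAIC** against the nested fixed-slope
  (`b = 1`) model, so departures from linearity are assessed formally.

It is aimed at researchers quantifying clonogenic survival (radiation or
drug response) of cell lines, suspension cells and organoids in 96/384-well
LDA formats, and at method developers who need a faithful generative
simulator of such assays.

## Worked example

```python
from cooplda import (SimulationConfig, simulate_lda, fit_loglog_glm,
                     clonogenic_activity, compare_models, survival_table)

exp = simulate_lda(SimulationConfig(
    p=0.1, b=1.8, n_wells=12, n_replicates=3,
    treatments=(("0Gy", 1.0), ("4Gy", 0.45)), seed=3))

fit = fit_loglog_glm(exp.pooled_group("0Gy"))
print(fit.summary())
```

```
Limiting dilution power-law model
================================================================
treatment: 0Gy    replicate: pooled
dilutions: 8    wells: 288    negative wells: 74
converged: True    iterations: 8
----------------------------------------------------------------
                    coef     std err      [0.025      0.975]
alpha            -2.9868      0.4609     -3.8901     -2.0835
b                 2.2638      0.3435      1.5905      2.9371
----------------------------------------------------------------
p = exp(alpha) = 0.0504478    b = 2.2638
clonogenic activity a = exp(-alpha/b) = 3.74111 cells/well
log-likelihood -5.2808    deviance 0.3832    AIC 14.5617
```

The slope `b ≈ 2.3` flags strongly cooperative growth: seeding twice as many
cells more than doubles the expected number of active cells. Roughly
`a ≈ 3.7` cells must be seeded per well for one active cell on average.

```python
est = clonogenic_activity(fit, level=0.95)
cmp = compare_models(fit, fit_loglog_glm(exp.pooled_group("0Gy"), slope_fixed=True))
print(f"activity a = {est.a:.3f}, 95% CI ({est.ci[0]:.3f}, {est.ci[1]:.3f})")
print(f"LRT vs linear: delta deviance {cmp.delta_deviance:.2f}, p = {cmp.lrt_p:.4f}")
print(survival_table(exp, mode="pooled").iloc[:, :7].to_string(index=False))
```

```
activity a = 3.741, 95% CI (3.231, 4.389)
LRT vs linear: delta deviance 23.97, p = 0.0000
treatment reference       sf  ci95_lower  ci95_upper   mode  n_replicates
      0Gy       0Gy 1.000000    0.809133    1.235890 pooled             3
      4Gy       0Gy 0.468103    0.375485    0.585607 pooled             3
```

The likelihood-ratio test rejects the linear model decisively, and the
estimated survival fraction after 4 Gy (0.468, CI 0.375–0.586) brackets the
generating truth of 0.45.

The same workflow is available from the shell:

```
cooplda simulate --p 0.1 --b 1.8 --n-replicates 3 \
    --treatments 0Gy:1.0,4Gy:0.45 --seed 3 --out data/
cooplda report --input data/simulated.csv --reference 0Gy --out results/
```

which writes `fits.csv`, `activities.csv`, `survival.csv` and
`model_comparison.csv`. Real data are supplied as a CSV with columns
`treatment, replicate, cells_per_well, n_wells, n_positive` (or
`n_negative`); `--schema` remaps custom column names.

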