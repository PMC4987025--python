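# pedmix

Family-based mixed-model analysis of chronic pain and comorbid
depression: pedigree variance components, bivariate genetic and
environmental correlations, and polygenic risk-score profiling — with a
synthetic-cohort generator so every stage can be validated against
known ground truth.

## The problem

Chronic pain aggregates in families, but relatives share more than
genes: spouses share a household and a recent environment, siblings
shared a childhood. Family cohorts with extended pedigrees let the
phenotypic variance of an ordinal pain grade (0 = none … 4 = severe,
disabling) be split into additive genetic and shared-environment parts,
and let the covariance between pain and major depression be partitioned
into genetic and environmental channels. `pedmix` is for statistical
geneticists and epidemiologists running that analysis — or testing
methods for it — without access to managed cohort data.

## The model

For trait vector **y** with fixed effects (sex, age, age²):

```
y = Xb + u_a + u_s + e,   u_a ~ N(0, σ²_a A),  u_s ~ N(0, σ²_s S),  e ~ N(0, σ²_e I)
```

where `A` is the additive (numerator) relationship matrix from the
pedigree (tabular method, `A = 2·kinship`) and `S` is a 0/1 block
matrix over couples (analogous structures exist for sibships and
households). Heritability is `h² = σ²_a / Σσ²`. Ordinal and binary
traits are modelled on the liability scale — a latent Gaussian cut at
thresholds — by a parameter-expanded Gibbs sampler with the residual
fixed at 1; a blocked AI-REML backend fits Gaussian (or numeric-coded)
traits and drives likelihood-ratio model comparison. Forward stepwise
selection over {spouse, sib, household}, judged by LRT or by DIC
(marginal-deviance focus), reproduces the study design in which each
environmental effect is tested alongside the genetic component. The
bivariate model gives each random component an unstructured 2×2 trait
covariance, yielding the genetic correlation `r_g = cov_a/√(σ²_a1 σ²_a2)`
and its constrained-null (`r_g = 0`) chi-squared(1) test. Polygenic
scores are weighted allele-dosage sums over discovery SNPs below
p-value thresholds {0.01, 0.05, 0.1, 0.5}, associated with traits in a
mixed model that accounts for relatedness.

## Worked example

```python
import numpy as np
from pedmix import (
    CohortDesign, SimulationTruth, MixedModelSpec,
    simulate_pedigree, simulate_phenotypes,
    additive_relationship_matrix, group_covariance_matrix,
    fit_gibbs_ordinal, fit_bivariate_reml,
    constrained_fit, correlation_significance, FAST_MCMC,
)

# a 650-family cohort (~6,000 people) with known truth:
# liability h2 = 0.40, spouse-shared environment = 0.20, rg = 0.5
truth = SimulationTruth()
ped = simulate_pedigree(CohortDesign(n_families=650), seed=7)
phenotypes = simulate_phenotypes(ped, truth, seed=8)
structures = {
    "additive": additive_relationship_matrix(ped),
    "spouse": group_covariance_matrix(ped, "spouse_share"),
}

spec = MixedModelSpec(response="cpg", scale="ordinal",
                      random_components=("additive", "spouse"),
                      mcmc=FAST_MCMC)
fit = fit_gibbs_ordinal(spec, phenotypes, structures, seed=9)
for name, (est, lo, hi) in fit.proportions.items():
    print(f"{name:9s} {100*est:5.1f}% of liability variance "
          f"(95% CrI {100*lo:.1f}-{100*hi:.1f}%)")

null = constrained_fit(phenotypes, "cpg", "mdd", structures, constraint="rg")
full = fit_bivariate_reml(phenotypes, "cpg", "mdd", structures,
                          theta_start=null.theta)
lrt = correlation_significance(full, null)
print(f"genetic correlation rg = {full.rg[0]:.2f} (SE {full.rg[1]:.2f}), "
      f"LRT chi2(1) = {lrt.statistic:.1f}, p = {lrt.p_value:.2g}")
```

prints

```
additive   41.4% of liability variance (95% CrI 35.8-46.9%)
spouse     18.7% of liability variance (95% CrI 12.9-23.7%)
residual   39.9% of liability variance (95% CrI 32.4-48.4%)
genetic correlation rg = 0.36 (SE 0.08), LRT chi2(1) = 20.5, p = 5.9e-06
```

The decomposition recovers the simulated 40/20/40 split — additive
genetics explains ~41% of pain-liability variance, the spouse-shared
environment ~19% — and the pain–depression genetic correlation (truth
0.5; this single cohort estimates 0.36 ± 0.08, within two standard
errors) is strongly significant. The `FAST_MCMC` profile (5,000
iterations) is for quick runs; use the default profile (85,000
iterations, 3 chains) for publication-grade intervals.

The same three stages run from a single YAML config on files or
simulated data via the CLI:

```
pedmix simulate   --config study.yaml       # write cohort files + truth manifest
pedmix univariate --config study.yaml       # stepwise decomposition report
pedmix bivariate  --config study.yaml       # rg / r_env / phenotypic correlations
pedmix prs        --config study.yaml       # per-threshold score associations
pedmix all        --config study.yaml
```

Reports (TSV + JSON summary) embed the config hash, seed, and package
version; reruns with the same config and seed are byte-identical. See
`tests/test_pipeline.py` for a minimal config.

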