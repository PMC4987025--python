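# Methods

`pedmix` implements family-based mixed-model analysis of a chronic-pain
style ordinal trait and a comorbid binary disorder: variance
decomposition over pedigree-derived covariance structures, bivariate
genetic/environmental correlation, and polygenic risk-score profiling.
This note records the models, the defaults and why they were chosen,
the numerical machinery, and what the synthetic cohorts do and do not
emulate.

## Relationship structures

The additive (numerator) relationship matrix `A` is built by the
tabular method in topological order: for individual *i* with parents
*f, m*,

    A_ii = 1 + 0.5 * A_fm          (1 if a parent is unknown)
    A_ij = 0.5 * (A_jf + A_jm)     (unknown parents contribute 0)

An individual with exactly one known parent is treated as the child of
a unique, non-inbred phantom founder — the standard tabular convention.
`A` equals twice the kinship matrix; it is computed densely within each
family (connected component of the parent graph) and stored sparse, so
cohorts of 10^4–10^5 individuals are cheap. Inbreeding coefficients are
`F_i = A_ii − 1`.

Shared-environment structures (spouse, sibship, household) are 0/1
block matrices over a partition of individuals: entry (i, j) is 1 when
the pair shares a group. Individuals in no group are singleton blocks,
i.e. they still carry the component's variance but share it with no
one; this matches the interpretation of the variance component as the
variance of a group-level random effect. Couples may overlap through
remarriage, which would break the partition; partnership groups are
therefore the connected components of the couple graph. When no couples
file is supplied, couples are inferred as parent pairs with at least
one common offspring — the only pedigree-internal signal for a current
or previous partnership.

## Univariate variance components

The model for a phenotype vector `y` is

    y = X b + Σ_k u_k + e,   u_k ~ N(0, σ²_k K_k),   e ~ N(0, σ²_e I)

with fixed effects sex, age and age² by default and `K_k` the
structures above. Two backends estimate it:

**AI-REML** (Gaussian working scale). The engine treats the covariance
as a general linear structure `V(θ) = Σ_q θ_q D_q` and maximises the
REML likelihood with average-information updates, an EM / scaled-score
fallback when an AI step leaves the parameter space or decreases the
likelihood, and step-halving acceptance. Standard errors come from the
inverse AI matrix; proportion-of-variance intervals use the delta
method. Because families are independent blocks, every REML quantity
decomposes over connected components of the combined sparsity pattern;
blocks of equal size are stacked and evaluated with batched dense
linear algebra, which makes a 6,000-person fit a sub-second operation
and repeated-simulation studies practical. Ordinal grades are fitted as
numeric 0–4 working scores under this backend (the model-comparison
role); estimates on that scale are attenuated relative to the liability
scale, which is why the Bayesian backend is the effect-size authority
for discrete traits. Nested-model comparisons warm-start the larger
model at the smaller model's optimum (new component at zero), which
guarantees monotone log-likelihoods for the likelihood-ratio test.

**Ordinal-probit Gibbs sampler** (liability scale). The observed
category is a censored latent Gaussian liability with residual variance
fixed at 1 and the first finite cutpoint at 0. A sweep updates: free
cutpoints by a collapsed random-walk Metropolis step on the category
likelihood given the linear predictor (liabilities integrated out —
the classical liability-conditioned uniform draw mixes pathologically
slowly at realistic sizes); liabilities from truncated normals; fixed
effects jointly; each family's random effects jointly from its
mixed-model equations (additive effects carry the family `A_f⁻¹` prior
precision, shared-environment effects are one scalar per group); and
the variance components. The inner loop is compiled (numba) over
ragged per-family arrays, so a 5,000-iteration chain over ~2,000
individuals takes a few seconds.

### Priors and the latent-scale ridge

Threshold models with a fixed unit residual are only weakly identified
along a joint rescaling of (fixed effects, cutpoints, variance
components): the relationship matrix's near-unit diagonal lets the
additive component absorb extra residual-like variance, so the
conditional likelihood keeps improving as everything inflates, and at
modest n the data barely resist. With flat priors the chain drifts up
this ridge. Three weakly-informative proper priors anchor the scale:

- each component's standard deviation has a half-normal(1) prior,
  implemented by parameter expansion (`σ_k = |α_k| s_k` with
  `α_k ~ N(0, 1)` and the working variance fixed at 1); the expansion
  step also breaks the liability/variance coupling and is what makes
  the sampler mix. A scaled-inverse-chi-squared working variance
  (heavier tail) can be requested via the `priors` dict, but its
  polynomial tail cannot hold the ridge at small n;
- fixed effects get a g-prior-form precision `X'X/(25 n)` —
  negligible shrinkage, but a proper restraint on the fitted-value
  scale;
- free cutpoints get N(0, 10).

These scales suit unit-liability problems (every simulated trait here);
they are settings, not constants, and should be revisited for traits
deliberately modelled on other scales.

### Model comparison

The likelihood-ratio test compares `2 (logL_full − logL_null)` to a
chi-squared distribution with the parameter-count difference; an
optional boundary-corrected p-value uses the equal mixture of
chi-squared df and df−1 (a point mass at zero when df = 1). The plain
chi-squared is the default reported test; the mixture is exposed
because a variance component sits on the boundary under its null.

DIC is `mean deviance + p_D` with `p_D = mean deviance − deviance at
the posterior means`. The deviance is evaluated at the *model* focus —
fixed effects, variance components, cutpoints — with the random effects
integrated out family by family using the GHK orthant-probability
estimator (32 draws per family, the thinned posterior subsampled to
≤300 draws). The latent-focus (conditional) deviance, stored alongside
for reference, rewards any added random component by construction and
cannot rank models at desk scale; with the marginal focus a null
component changes DIC by roughly ±2 units while a real spouse
component improves it by tens.

Stepwise selection starts from the additive-only model, adds the best
single shared-environment candidate if it improves the criterion, then
tries one more, stopping when nothing improves. Improvement means LRT
p < 0.05 against the current model, or a DIC drop larger than 5 units
— the tie tolerance sits above the Monte Carlo uncertainty of the GHK
deviance (±1–3 units per model), and ties keep the smaller model.

## Bivariate model

Both traits (ordinal grade and 0/1 disorder on their numeric working
scales, mirroring the Gaussian-REML treatment such analyses use) enter
a stacked model in which every random component carries an unstructured
2×2 trait covariance (Kronecker with the relationship structure) and
individuals missing one trait contribute the other (pairwise-complete
likelihood). Correlations are `cov/√(var₁ var₂)` with delta-method
SEs. The genetic (or environmental) correlation's significance is a
one-degree-of-freedom LRT against a fit with that off-diagonal pinned
at zero; the full fit is warm-started from the null's optimum so the
nesting is numerically monotone. The adjusted phenotypic correlation is
the correlation of the summed component covariance, tested as
estimate/SE against a standard normal (two-tailed); the raw Pearson
correlation is reported beside it because the two definitions are both
in circulation. No liability-scale conversion is applied to the
correlations — genetic correlations are nearly invariant to the
working-scale reduction, and the reference analyses report unconverted
coefficients. An exactly duplicated trait makes every 2×2 block
singular at the optimum (unbounded likelihood); the fit approaches that
boundary (correlations > 0.9) but cannot represent it exactly.

## Polygenic scoring

Scores are `score_i = Σ_{j: p_j ≤ pT} w_j d_ij` over discovery SNPs at
thresholds pT ∈ {0.01, 0.05, 0.1, 0.5}, after aligning discovery
weights to the target's counted alleles (negation for swapped labels;
strand-ambiguous A/T and C/G SNPs excluded; every exclusion reported
with its reason). Missing dosages are imputed at twice the counted
allele's sample frequency; SNPs absent from the target are dropped.
Scores are standardized before association, so the reported coefficient
is a standardized beta; raw scores shift by a constant under allele
relabelling while centered scores are exactly invariant. Association
uses the score as a fixed effect in a mixed model with the additive
relationship matrix (Wald test under REML; posterior summaries under
the Gibbs backend), plus sex, age, age² and the top-4 principal
components of the standardized genotype matrix — PCA rather than
classical multidimensional scaling of an identity-by-state matrix,
which spans the same adjustment space. For an unrelatedness-filtered
cohort the relationship structure can be omitted, reducing to plain
regression. Variance explained is `Var(β·score)/Var(phenotype)`. No
LD clumping is applied by default (simulated SNPs are unlinked); a
greedy r²-window pruning utility exists for linked data.

## Synthetic cohorts

`simulate_pedigree` builds independent families: a founder couple,
Poisson(2.2) offspring per couple, three generations by default, each
non-final-generation offspring partnering a married-in founder with
probability 0.7; households contain a couple plus their never-partnered
offspring. Defaults give ~9 members per family, so ~650 families ≈
6,000 individuals.

Phenotypes follow the liability model exactly: per-trait liability =
sex/age/age² fixed effects + additive genetic value (gene dropping:
founders N(0, σ²_a), descendants parent-mean plus Mendelian deviate
with variance `0.5 σ²_a (1 − (F_f + F_m)/2)`; the bivariate version
uses a 2×2 genetic covariance throughout) + one shared deviate per
couple / sibship / household + residual. Defaults: σ²_a = 0.4,
σ²_spouse = 0.2, σ²_sib = σ²_household = 0, σ²_e = 0.4 (h² = 0.40,
spouse share 0.20), genetic correlation 0.5 and spouse-environment
correlation 0.5 between the traits. Grades 0–4 cut the pain liability
at its empirical quantiles for frequencies (0.55, 0.13, 0.11, 0.11,
0.10) — a majority-ungraded population with declining severity, since
no public grade table exists for the reference cohorts; the binary
trait is liability above the quantile matching a 12% prevalence. Ages
are uniform 18–90 and sex Bernoulli(1/2): enough to exercise the
fixed-effect machinery, with no demographic realism intended.

Genotypes are unlinked SNPs dropped through the pedigree (founders at
Hardy–Weinberg given each SNP's frequency, descendants by Mendelian
transmission, vectorized a generation at a time). The training study
simulates an independent unrelated sample and per-SNP marginal
regressions; for genome-wide panels (hundreds of thousands of SNPs) the
estimates can instead be drawn from their exact sampling distribution
(`method="analytic"`), which is equivalent in distribution for unlinked
SNPs and avoids materializing a 20,000 × 260,000 genotype matrix.

What the generator does **not** emulate: linkage disequilibrium,
assortative mating, population stratification (a hook exists but the
default is a homogeneous population), genotyping error, age-structured
households, or informative missingness. Green tests therefore certify
the estimators under a correctly specified family model, not robustness
to those real-data features.

## Problem sizes in the test suite

Simulation studies run at the sizes their questions need and the suite
keeps moderate: recovery and bivariate studies at ~6,000 individuals
(20 seeds); LRT selection at ~3,000 (20 seeds per arm); DIC selection
at ~2,250 with single 3,000-iteration chains (20 spouse-truth seeds, 10
null seeds) — the fast-profile default for interactive fits remains
5,000/1,000/5, and published-scale analyses should use the full
85,000/15,000/50 profile; LRT calibration at ~1,500 individuals × 200
replicates; backend concordance on Gaussian data coded into 8 ordered
categories (comparable scales for both backends) at ~1,500 × 10
datasets; polygenic scoring on a 260,000-SNP panel trained at
n = 20,000 and scored in a ~2,000-person cohort, where the score
explains well under 1% of the trait, echoing realistic thin-information
discovery.

## Known limitations

- REML on ordinal scores is a declared approximation; its variance
  proportions are attenuated relative to the liability scale.
- The Gibbs sampler's effective sample size per 5,000-iteration chain
  is modest (tens); the `converged` flag and ESS diagnostics should be
  consulted, and long chains used for publication-grade intervals.
- DIC's marginal deviance is a GHK estimate; differences within a few
  units are noise by design and treated as ties.
- The probit latent scale is weakly identified at small n even with
  the anchoring priors; below ~1,000 informative individuals the
  posterior spreads visibly along the scale ridge.
- Single-threaded throughout; no X-linked, dominance, or genomic
  (SNP-based) relationship matrices.
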