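"""Synthetic family cohorts with known ground truth.

Emulates the statistical structure of a family- and population-based
cohort: multigenerational families with couples, sibships and
households; two correlated traits on the liability scale (an ordinal
chronic-pain grade 0-4 and a binary depression status) built from
additive genetics, shared spouse / sibship / household environments and
residual noise; unlinked SNP genotypes dropped through the pedigree; and
an independent "training" association study that yields summary
statistics for polygenic scoring.

Genetic values are simulated by gene dropping — founders drawn from the
base population, descendants as the parental mean plus a Mendelian
sampling deviate — which is linear in pedigree size and exactly matches
the covariance sigma2_a * A implied by the numerator relationship matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pedigree import Individual, Pedigree, topological_order
from .relatedness import additive_relationship_matrix, inbreeding_coefficients

__all__ = [
    "SimulationTruth",
    "CohortDesign",
    "GwasTruth",
    "simulate_pedigree",
    "simulate_breeding_values",
    "simulate_phenotypes",
    "simulate_target_genotypes",
    "simulate_training_gwas",
    "realize_gwas",
    "write_cohort_tables",
    "write_truth_manifest",
]


@dataclass(frozen=True)
class SimulationTruth:
    """Liability-scale generative parameters for the two traits.

    Both traits share the variance decomposition; their additive values
    are correlated ``rg`` and their spouse-environment deviates ``r_spouse``.
    Grades are cut from the pain liability at ``thresholds`` (or at the
    empirical quantiles implied by ``grade_freqs`` when thresholds are
    None); the binary trait is liability above the quantile matching
    ``prevalence_mdd``.
    """

    var_additive: float = 0.4
    var_spouse: float = 0.2
    var_sib: float = 0.0
    var_household: float = 0.0
    var_residual: float = 0.4
    rg: float = 0.5
    r_spouse: float = 0.5
    thresholds: tuple[float, ...] | None = None
    grade_freqs: tuple[float, ...] = (0.55, 0.13, 0.11, 0.11, 0.10)
    prevalence_mdd: float = 0.12
    # per-trait (sex, age, age^2) liability coefficients; sex coded 1=female
    fixed_effects: dict = field(
        default_factory=lambda: {
            "pain": (0.20, 0.008, -5e-5),
            "mdd": (0.30, -0.004, 2e-5),
        }
    )

    def __post_init__(self):
        for name in ("var_additive", "var_spouse", "var_sib", "var_household", "var_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("rg", "r_spouse"):
            if not -1.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [-1, 1]")
        if self.thresholds is not None and np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        if abs(sum(self.grade_freqs) - 1.0) > 1e-8:
            raise ValueError("grade frequencies must sum to 1")
        if not 0.0 < self.prevalence_mdd < 1.0:
            raise ValueError("prevalence_mdd must lie in (0, 1)")

    @property
    def total_variance(self) -> float:
        return (
            self.var_additive + self.var_spouse + self.var_sib
            + self.var_household + self.var_residual
        )

    @property
    def h2(self) -> float:
        return self.var_additive / self.total_variance

    @property
    def proportions(self) -> dict[str, float]:
        t = self.total_variance
        return {
            "additive": self.var_additive / t,
            "spouse": self.var_spouse / t,
            "sib": self.var_sib / t,
            "household": self.var_household / t,
            "residual": self.var_residual / t,
        }


@dataclass(frozen=True)
class CohortDesign:
    """Shape of the simulated families."""

    n_families: int = 600
    generations: int = 3
    mean_offspring: float = 2.2
    offspring_dist: str = "poisson"  # or "constant"
    couple_rate: float = 0.7
    household_rule: str = "couple_plus_minors"  # or "none"

    def __post_init__(self):
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.generations < 2:
            raise ValueError("generations must be >= 2")
        if self.offspring_dist not in ("poisson", "constant"):
            raise ValueError(f"unknown offspring distribution {self.offspring_dist!r}")
        if self.household_rule not in ("couple_plus_minors", "none"):
            raise ValueError(f"unknown household rule {self.household_rule!r}")


@dataclass(frozen=True)
class GwasTruth:
    """Stand-in discovery GWAS: unlinked SNPs, a sparse causal subset,
    and an independent unrelated training sample."""

    n_snps: int = 2000
    n_causal: int = 200
    h2_snp: float = 0.3
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_train: int = 20_000
    snp_ids: tuple[str, ...] | None = None
    effect_allele: tuple[str, ...] | None = None
    other_allele: tuple[str, ...] | None = None
    maf: tuple[float, ...] | None = None
    true_beta: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal cannot exceed n_snps")
        if not 0.0 <= self.h2_snp <= 1.0:
            raise ValueError("h2_snp must lie in [0, 1]")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("MAF range must lie in (0, 0.5]")

    @property
    def realized(self) -> bool:
        return self.maf is not None


# non strand-ambiguous allele pairs (A/T and C/G are excluded by scoring)
_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T")]


def realize_gwas(gwas: GwasTruth, seed: int) -> GwasTruth:
    """Draw the per-SNP frequencies, alleles and true effects once, so
    that training and target data share the same genetic architecture.

    True effects are scaled so the causal SNPs explain exactly
    ``h2_snp`` of unit phenotypic variance in the training population.
    """
    rng = np.random.default_rng(seed)
    m = gwas.n_snps
    maf = rng.uniform(*gwas.maf_range, size=m)
    pair_idx = rng.integers(len(_ALLELE_PAIRS), size=m)
    flip = rng.integers(2, size=m).astype(bool)
    a1 = np.array([_ALLELE_PAIRS[k][0] for k in pair_idx])
    a2 = np.array([_ALLELE_PAIRS[k][1] for k in pair_idx])
    a1[flip], a2[flip] = a2[flip], a1[flip].copy()
    beta = np.zeros(m)
    if gwas.n_causal > 0 and gwas.h2_snp > 0:
        causal = rng.choice(m, size=gwas.n_causal, replace=False)
        raw = rng.standard_normal(gwas.n_causal)
        var_g = np.sum(2 * maf[causal] * (1 - maf[causal]) * raw**2)
        beta[causal] = raw * np.sqrt(gwas.h2_snp / var_g)
    width = len(str(m))
    snp_ids = tuple(f"snp{k + 1:0{width}d}" for k in range(m))
    return replace(
        gwas,
        snp_ids=snp_ids,
        effect_allele=tuple(a1),
        other_allele=tuple(a2),
        maf=tuple(maf),
        true_beta=tuple(beta),
    )


# ---------------------------------------------------------------------
# pedigree simulation


def simulate_pedigree(design: CohortDesign, seed: int) -> Pedigree:
    """Independent families of the requested depth.

    Each family starts from a founder couple; offspring counts are
    Poisson; in non-final generations an offspring partners (with a
    married-in founder) with probability ``couple_rate`` and reproduces.
    Households, when formed, contain a couple plus their never-partnered
    offspring.
    """
    rng = np.random.default_rng(seed)
    individuals: list[Individual] = []
    couples: list[tuple[str, str]] = []
    households: dict[str, frozenset[str]] = {}
    fam_width = len(str(design.n_families))
    for fam in range(design.n_families):
        counter = 0

        def new_id():
            nonlocal counter
            counter += 1
            return f"F{fam + 1:0{fam_width}d}_I{counter:03d}"

        def add(father, mother, sex):
            iid = new_id()
            individuals.append(Individual(id=iid, father=father, mother=mother, sex=sex))
            return iid

        dad = add(None, None, "male")
        mum = add(None, None, "female")
        parent_couples = [(dad, mum)]
        couples.append((dad, mum))
        hh_children: dict[tuple[str, str], list[str]] = {(dad, mum): []}
        for gen in range(1, design.generations):
            next_couples = []
            for f, m in parent_couples:
                n_off = (
                    rng.poisson(design.mean_offspring)
                    if design.offspring_dist == "poisson"
                    else int(round(design.mean_offspring))
                )
                for _ in range(n_off):
                    sex = "female" if rng.random() < 0.5 else "male"
                    child = add(f, m, sex)
                    partnered = (
                        gen < design.generations - 1
                        and rng.random() < design.couple_rate
                    )
                    if partnered:
                        spouse_sex = "male" if sex == "female" else "female"
                        spouse = add(None, None, spouse_sex)
                        pair = (child, spouse) if sex == "male" else (spouse, child)
                        couples.append((child, spouse))
                        next_couples.append(pair)
                        hh_children[pair] = []
                    else:
                        hh_children[(f, m)].append(child)
            parent_couples = next_couples
        if design.household_rule == "couple_plus_minors":
            for k, ((f, m), kids) in enumerate(hh_children.items()):
                households[f"H{fam + 1:0{fam_width}d}_{k + 1:02d}"] = frozenset([f, m, *kids])
    return Pedigree(individuals=individuals, couples=couples, households=households)


# ---------------------------------------------------------------------
# gene dropping


def _as_cov(var_or_cov) -> np.ndarray:
    G = np.atleast_2d(np.asarray(var_or_cov, dtype=float))
    if G.shape == (1, 1) and G[0, 0] < 0:
        raise ValueError("variance must be non-negative")
    if not np.allclose(G, G.T):
        raise ValueError("genetic covariance must be symmetric")
    eig = np.linalg.eigvalsh(G)
    if eig.min() < -1e-10:
        raise ValueError("genetic covariance must be positive semidefinite")
    return G


def _psd_sqrt(G: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(G)
    return v @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ v.T


def simulate_breeding_values(
    ped: Pedigree,
    var_additive,
    seed: int,
    n_replicates: int | None = None,
    inbreeding: dict[str, float] | None = None,
) -> np.ndarray:
    """Additive genetic values by gene dropping, in pedigree input order.

    ``var_additive`` may be a scalar (one trait) or a PSD 2x2 covariance
    (two correlated traits).  Founders are drawn independently with the
    full (co)variance; a non-founder is the mean of its parental values
    plus a Mendelian-sampling deviate with (co)variance
    ``0.5 * G * (1 - (F_f + F_m) / 2)``.  An unknown parent is treated
    as a unique non-inbred founder whose value is drawn on the fly.

    Returns ``(n, t)`` (or ``(R, n, t)`` with ``n_replicates=R``).
    """
    G = _as_cov(var_additive)
    t = G.shape[0]
    L = _psd_sqrt(G)
    if inbreeding is None:
        inbreeding = inbreeding_coefficients(additive_relationship_matrix(ped))
    rng = np.random.default_rng(seed)
    R = 1 if n_replicates is None else n_replicates
    order = topological_order(ped)
    values: dict[str, np.ndarray] = {}
    for iid in order:
        ind = ped[iid]
        if ind.father is None and ind.mother is None:
            values[iid] = rng.standard_normal((R, t)) @ L.T
            continue
        f_inb = []
        parent_mean = np.zeros((R, t))
        for parent in (ind.father, ind.mother):
            if parent is None:  # phantom founder
                parent_mean += 0.5 * (rng.standard_normal((R, t)) @ L.T)
                f_inb.append(0.0)
            else:
                parent_mean += 0.5 * values[parent]
                f_inb.append(inbreeding[parent])
        ms_scale = np.sqrt(0.5 * (1.0 - 0.5 * sum(f_inb)))
        values[iid] = parent_mean + ms_scale * (rng.standard_normal((R, t)) @ L.T)
    out = np.stack([values[i.id] for i in ped.individuals], axis=1)  # (R, n, t)
    return out[0] if n_replicates is None else out


# ---------------------------------------------------------------------
# phenotypes


def _spouse_groups(ped: Pedigree) -> list[list[str]]:
    parent: dict[str, str] = {}

    def find(x):
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    for a, b in ped.couples:
        parent.setdefault(a, a)
        parent.setdefault(b, b)
        parent[find(a)] = find(b)
    groups: dict[str, list[str]] = {}
    for x in parent:
        groups.setdefault(find(x), []).append(x)
    return [g for g in groups.values() if len(g) > 1]


def _shared_deviates(
    n: int,
    groups: list[list[int]],
    var: float,
    cross_corr: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One bivariate deviate per group, identical for all members;
    individuals outside every group get their own independent deviate."""
    out = np.zeros((n, 2))
    if var <= 0:
        return out
    C = var * np.array([[1.0, cross_corr], [cross_corr, 1.0]])
    L = _psd_sqrt(C)
    in_group = np.zeros(n, dtype=bool)
    for g in groups:
        d = rng.standard_normal(2) @ L.T
        out[g] = d
        in_group[g] = True
    singles = np.flatnonzero(~in_group)
    out[singles] = rng.standard_normal((len(singles), 2)) @ L.T
    return out


def simulate_phenotypes(
    ped: Pedigree,
    truth: SimulationTruth,
    seed: int,
    return_components: bool = False,
):
    """Phenotype table for the cohort: ordinal pain grade (cpg 0-4),
    binary depression (mdd), sex, age, plus the underlying continuous
    liabilities (columns ``liability_pain`` / ``liability_mdd``) for
    analyses on the Gaussian scale.
    """
    rng = np.random.default_rng(seed)
    n = len(ped)
    idx = {iid: k for k, iid in enumerate(ped.ids)}

    sex = np.array(
        [
            1.0 if i.sex == "female" else 0.0 if i.sex == "male" else float(rng.random() < 0.5)
            for i in ped.individuals
        ]
    )
    age = rng.uniform(18.0, 90.0, size=n)

    G = truth.var_additive * np.array([[1.0, truth.rg], [truth.rg, 1.0]])
    a = simulate_breeding_values(ped, G, seed=int(rng.integers(2**31 - 1)))
    spouse = _shared_deviates(
        n,
        [[idx[i] for i in g] for g in _spouse_groups(ped)],
        truth.var_spouse,
        truth.r_spouse,
        rng,
    )
    sib = _shared_deviates(
        n,
        [[idx[i] for i in g] for g in ped.sibships.values() if len(g) > 1],
        truth.var_sib,
        0.0,
        rng,
    )
    household = _shared_deviates(
        n,
        [[idx[i] for i in g] for g in ped.households.values() if len(g) > 1],
        truth.var_household,
        0.0,
        rng,
    )
    resid = rng.standard_normal((n, 2)) * np.sqrt(truth.var_residual)

    liab = np.empty((n, 2))
    for tnum, trait in enumerate(("pain", "mdd")):
        b_sex, b_age, b_age2 = truth.fixed_effects[trait]
        fixed = b_sex * sex + b_age * age + b_age2 * age**2
        liab[:, tnum] = (
            fixed + a[:, tnum] + spouse[:, tnum] + sib[:, tnum]
            + household[:, tnum] + resid[:, tnum]
        )

    if truth.thresholds is not None:
        cuts = np.asarray(truth.thresholds, dtype=float)
    else:
        cum = np.cumsum(truth.grade_freqs)[:-1]
        cuts = np.quantile(liab[:, 0], cum)
        if np.any(np.diff(cuts) <= 0):
            raise ValueError("grade frequencies give non-increasing liability cutpoints")
    cpg = np.searchsorted(cuts, liab[:, 0], side="left")
    mdd = (liab[:, 1] > np.quantile(liab[:, 1], 1.0 - truth.prevalence_mdd)).astype(int)

    table = pd.DataFrame(
        {
            "id": ped.ids,
            "sex": sex.astype(int),
            "age": np.round(age, 2),
            "age2": np.round(age, 2) ** 2,
            "cpg": cpg,
            "mdd": mdd,
            "liability_pain": liab[:, 0],
            "liability_mdd": liab[:, 1],
        }
    )
    if return_components:
        parts = {
            "genetic": a,
            "spouse": spouse,
            "sib": sib,
            "household": household,
            "residual": resid,
            "thresholds": cuts,
        }
        return table, parts
    return table


# ---------------------------------------------------------------------
# genotypes and the training study


def simulate_target_genotypes(
    ped: Pedigree,
    gwas: GwasTruth,
    seed: int,
    missing_rate: float = 0.0,
):
    """Unlinked SNP genotypes for the pedigree: founders at
    Hardy-Weinberg given each SNP's allele frequency, descendants by
    Mendelian transmission (each parent passes an allele with
    probability genotype/2; an unknown parent contributes a population
    allele).  Returns a :class:`pedmix.prs.GenotypeMatrix` whose counted
    allele is the effect allele."""
    from .prs import GenotypeMatrix

    if not gwas.realized:
        gwas = realize_gwas(gwas, seed)
    rng = np.random.default_rng(seed)
    maf = np.asarray(gwas.maf)
    m = gwas.n_snps
    n = len(ped)
    # generation depth so whole levels can be simulated at once
    depth = np.zeros(n, dtype=int)
    for iid in topological_order(ped):
        ind = ped[iid]
        k = ped.index_of(iid)
        for parent in (ind.father, ind.mother):
            if parent is not None:
                depth[k] = max(depth[k], depth[ped.index_of(parent)] + 1)
    maf32 = maf.astype(np.float32)
    geno = np.zeros((n, m), dtype=np.int8)
    for level in range(depth.max() + 1):
        rows = np.flatnonzero(depth == level)
        if level == 0:
            # two allele draws beat rng.binomial's generic varying-p path
            geno[rows] = (
                (rng.random((len(rows), m), dtype=np.float32) < maf32).astype(np.int8)
                + (rng.random((len(rows), m), dtype=np.float32) < maf32).astype(np.int8)
            )
            continue
        for parent_slot in (0, 1):
            par_idx = np.array([
                ped.index_of(getattr(ped.individuals[r],
                                     "father" if parent_slot == 0 else "mother"))
                if (ped.individuals[r].father if parent_slot == 0
                    else ped.individuals[r].mother) is not None else -1
                for r in rows
            ])
            known = par_idx >= 0
            if known.any():
                gp = geno[par_idx[known]]
                u = rng.random(gp.shape, dtype=np.float32)
                # heterozygous parents transmit with probability 1/2,
                # homozygous parents deterministically (no float upcast)
                trans = (gp == 2) | ((gp == 1) & (u < 0.5))
                geno[rows[known]] += trans
            if (~known).any():  # unknown parent: population allele
                u = rng.random(((~known).sum(), m), dtype=np.float32)
                geno[rows[~known]] += (u < maf32)
    # rows are already in pedigree input order; int8 kept when complete
    if missing_rate > 0:
        dosages = geno.astype(np.float32)
        mask = rng.random(dosages.shape) < missing_rate
        dosages[mask] = np.nan
    else:
        dosages = geno
    return GenotypeMatrix(
        ids=tuple(ped.ids),
        snp_ids=tuple(gwas.snp_ids),
        counted_allele=tuple(gwas.effect_allele),
        other_allele=tuple(gwas.other_allele),
        dosages=dosages,
    )


def simulate_training_gwas(
    gwas: GwasTruth, seed: int, method: str = "sampled"
) -> pd.DataFrame:
    """Summary statistics from an independent, unrelated training sample
    of size ``n_train``: per-SNP marginal linear regression of the
    training phenotype on dosage, columns SNP, A1, A2, BETA, SE, P.

    ``method="sampled"`` materializes the training genotypes and runs
    the regressions; ``method="analytic"`` draws each estimate from its
    exact marginal-regression sampling distribution (equivalent in
    distribution for unlinked SNPs, and the only practical route for
    genome-wide panels of hundreds of thousands of SNPs)."""
    if not gwas.realized:
        gwas = realize_gwas(gwas, seed)
    rng = np.random.default_rng(seed)
    maf = np.asarray(gwas.maf)
    beta = np.asarray(gwas.true_beta)
    n = gwas.n_train  # noqa: E501  (used by both branches)
    if method == "analytic":
        se = np.sqrt(1.0 / (n * 2.0 * maf * (1.0 - maf)))
        bhat = beta + rng.standard_normal(gwas.n_snps) * se
        from scipy import stats as _st

        pvals = 2.0 * _st.norm.sf(np.abs(bhat / se))
        return pd.DataFrame(
            {
                "SNP": list(gwas.snp_ids),
                "A1": list(gwas.effect_allele),
                "A2": list(gwas.other_allele),
                "BETA": bhat,
                "SE": se,
                "P": np.clip(pvals, np.finfo(float).tiny, 1.0),
            }
        )
    if method != "sampled":
        raise ValueError(f"unknown method {method!r}")
    g = (
        (rng.random((n, gwas.n_snps)) < maf).astype(np.float32)
        + (rng.random((n, gwas.n_snps)) < maf).astype(np.float32)
    )
    gc = g - 2 * maf
    y = gc @ beta + rng.standard_normal(n) * np.sqrt(max(1.0 - gwas.h2_snp, 1e-12))
    yc = y - y.mean()
    gc_obs = g - g.mean(axis=0)
    sxx = np.einsum("ij,ij->j", gc_obs, gc_obs)
    sxy = yc @ gc_obs
    bhat = sxy / sxx
    ssr = np.einsum("i,i->", yc, yc) - bhat * sxy
    sigma2 = ssr / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    tstat = bhat / se
    pvals = 2.0 * _t_sf(np.abs(tstat), n - 2)
    return pd.DataFrame(
        {
            "SNP": list(gwas.snp_ids),
            "A1": list(gwas.effect_allele),
            "A2": list(gwas.other_allele),
            "BETA": bhat,
            "SE": se,
            "P": np.clip(pvals, np.finfo(float).tiny, 1.0),
        }
    )


def _t_sf(x, df):
    from scipy import stats

    return stats.t.sf(x, df)


# ---------------------------------------------------------------------
# writers


def write_cohort_tables(ped: Pedigree, outdir: str | Path) -> dict[str, Path]:
    """Write pedigree, couples, and households TSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    ped_path = outdir / "pedigree.tsv"
    with open(ped_path, "w") as fh:
        fh.write("id\tfather\tmother\tsex\n")
        for ind in ped.individuals:
            fh.write(
                f"{ind.id}\t{ind.father or '0'}\t{ind.mother or '0'}\t{ind.sex}\n"
            )
    paths["pedigree"] = ped_path
    cpath = outdir / "couples.tsv"
    with open(cpath, "w") as fh:
        fh.write("id1\tid2\n")
        for a, b in ped.couples:
            fh.write(f"{a}\t{b}\n")
    paths["couples"] = cpath
    hpath = outdir / "households.tsv"
    with open(hpath, "w") as fh:
        fh.write("household\tid\n")
        for label in sorted(ped.households):
            for iid in sorted(ped.households[label]):
                fh.write(f"{label}\t{iid}\n")
    paths["households"] = hpath
    return paths


def write_truth_manifest(
    path: str | Path,
    truth: SimulationTruth,
    design: CohortDesign | None = None,
    gwas: GwasTruth | None = None,
    seed: int | None = None,
) -> None:
    doc: dict = {"truth": asdict(truth)}
    if design is not None:
        doc["design"] = asdict(design)
    if gwas is not None:
        doc["gwas"] = {
            k: v for k, v in asdict(gwas).items()
            if k in ("n_snps", "n_causal", "h2_snp", "maf_range", "n_train")
        }
    if seed is not None:
        doc["seed"] = seed
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
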