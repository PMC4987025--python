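"""End-to-end orchestration of the three study stages.

A single structured config drives (1) univariate decomposition of the
pain grade with stepwise shared-environment selection, (2) the bivariate
pain-depression correlation with constrained-null tests, and (3)
polygenic-score profiling with relatedness-aware association.  Data come
either from input files (pedigree/phenotypes/couples/households TSV,
summary-stats TSV, VCF or dosage genotypes) or from the synthetic-cohort
generator with known truth.  Every report embeds the config hash, the
seed, and the package version; a rerun with the same config and seed is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _VERSION
from .bivariate import (
    adjusted_phenotypic_correlation,
    correlation_significance,
    fit_bivariate_reml,
)
from .gibbs import fit_gibbs_ordinal
from .pedigree import Pedigree, parse_pedigree
from .prs import (
    ancestry_components,
    prs_mixed_association,
    read_genotypes,
    read_summary_stats,
    threshold_and_score,
    write_vcf,
)
from .relatedness import additive_relationship_matrix, group_covariance_matrix
from .simulate import (
    CohortDesign,
    GwasTruth,
    SimulationTruth,
    realize_gwas,
    simulate_pedigree,
    simulate_phenotypes,
    simulate_target_genotypes,
    simulate_training_gwas,
    write_cohort_tables,
    write_truth_manifest,
)
from .variance import (
    FAST_MCMC,
    MCMCControl,
    MixedModelSpec,
    fit_reml,
    stepwise_model_selection,
)

__all__ = ["StudyConfig", "load_config", "run_univariate", "run_bivariate",
           "run_prs", "run_all"]


@dataclass
class StudyConfig:
    """Parsed study configuration (see the README for the YAML layout)."""

    seed: int = 1
    outdir: str = "pedmix_out"
    profile: str = "fast"  # fast | paper
    simulate: dict | None = None
    inputs: dict | None = None
    univariate: dict = field(default_factory=dict)
    bivariate: dict = field(default_factory=dict)
    prs: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError(
                "config must provide exactly one of 'simulate' or 'inputs'"
            )
        if self.profile not in ("fast", "paper"):
            raise ValueError("profile must be 'fast' or 'paper'")

    @property
    def mcmc(self) -> MCMCControl:
        return FAST_MCMC if self.profile == "fast" else MCMCControl()

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path, **overrides) -> StudyConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = dict(raw)
    cfg.update({k: v for k, v in overrides.items() if v is not None})
    return StudyConfig(
        seed=int(cfg.get("seed", 1)),
        outdir=str(cfg.get("outdir", "pedmix_out")),
        profile=str(cfg.get("profile", "fast")),
        simulate=cfg.get("simulate"),
        inputs=cfg.get("inputs"),
        univariate=cfg.get("univariate", {}) or {},
        bivariate=cfg.get("bivariate", {}) or {},
        prs=cfg.get("prs", {}) or {},
        raw=cfg,
    )


# ---------------------------------------------------------------------
# data assembly


@dataclass
class StudyData:
    pedigree: Pedigree
    phenotypes: pd.DataFrame
    structures: dict
    genotypes: object | None = None
    summary_stats: object | None = None
    truth: SimulationTruth | None = None


def _require(path_str: str | None, role: str) -> Path:
    if not path_str:
        raise FileNotFoundError(f"config provides no {role} file")
    p = Path(path_str)
    if not p.exists():
        raise FileNotFoundError(f"{role} file not found: {p}")
    return p


def prepare_data(config: StudyConfig, need_genotypes: bool = False) -> StudyData:
    rng = np.random.default_rng(config.seed)
    stage_seeds = {k: int(rng.integers(2**31 - 1))
                   for k in ("pedigree", "phenotypes", "gwas", "genotypes", "train")}
    if config.simulate is not None:
        design = CohortDesign(**(config.simulate.get("design") or {}))
        truth = SimulationTruth(**{
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in (config.simulate.get("truth") or {}).items()
        })
        ped = simulate_pedigree(design, seed=stage_seeds["pedigree"])
        phe = simulate_phenotypes(ped, truth, seed=stage_seeds["phenotypes"])
        geno = sumstats = None
        if need_genotypes:
            gwas = realize_gwas(
                GwasTruth(**(config.simulate.get("gwas") or {})),
                seed=stage_seeds["gwas"],
            )
            geno = simulate_target_genotypes(ped, gwas, seed=stage_seeds["genotypes"])
            train = simulate_training_gwas(gwas, seed=stage_seeds["train"])
            from .prs import SummaryStats

            sumstats = SummaryStats(table=pd.DataFrame({
                "snp": train["SNP"], "effect_allele": train["A1"],
                "other_allele": train["A2"], "weight": train["BETA"],
                "p": train["P"],
            }))
            # polygenic part of the pain liability: add the scored-SNP
            # genetic value so target traits carry the training signal
            gv = (geno.dosages.astype(float) - 2 * np.asarray(gwas.maf)) @ np.asarray(gwas.true_beta)
            phe = phe.copy()
            phe["cpg"] = _regrade(
                phe["liability_pain"].to_numpy() + gv, truth, phe
            )
            phe["liability_pain"] = phe["liability_pain"].to_numpy() + gv
        data = StudyData(
            pedigree=ped, phenotypes=phe,
            structures=_build_structures(ped),
            genotypes=geno, summary_stats=sumstats, truth=truth,
        )
        return data
    inputs = config.inputs or {}
    ped = parse_pedigree(
        _require(inputs.get("pedigree"), "pedigree"),
        couples_file=inputs.get("couples"),
        households_file=inputs.get("households"),
    )
    phe = pd.read_csv(_require(inputs.get("phenotypes"), "phenotype"), sep="\t",
                      dtype={"id": str})
    geno = sumstats = None
    if need_genotypes:
        geno = read_genotypes(
            _require(inputs.get("genotypes"), "genotype"),
            format=inputs.get("genotype_format", "vcf"),
        )
        sumstats = read_summary_stats(
            _require(inputs.get("summary_stats"), "summary statistics"),
            column_map=inputs.get("summary_columns"),
        )
    return StudyData(pedigree=ped, phenotypes=phe,
                     structures=_build_structures(ped),
                     genotypes=geno, summary_stats=sumstats)


def _regrade(liability: np.ndarray, truth: SimulationTruth, phe: pd.DataFrame):
    if truth.thresholds is not None:
        cuts = np.asarray(truth.thresholds)
    else:
        cuts = np.quantile(liability, np.cumsum(truth.grade_freqs)[:-1])
    return np.searchsorted(cuts, liability, side="left")


def _build_structures(ped: Pedigree) -> dict:
    return {
        "additive": additive_relationship_matrix(ped),
        "spouse": group_covariance_matrix(ped, "spouse_share"),
        "sib": group_covariance_matrix(ped, "sib_share"),
        "household": group_covariance_matrix(ped, "household_share"),
    }


def _stamp(config: StudyConfig) -> dict:
    return {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "version": _VERSION,
    }


def _write_report(outdir: Path, name: str, table: pd.DataFrame, summary: dict):
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / f"{name}.tsv", sep="\t", index=False,
                 float_format="%.6g")
    (outdir / f"{name}.txt").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=str) + "\n"
    )


# ---------------------------------------------------------------------
# stages


def run_simulate(config: StudyConfig) -> dict:
    """Materialize the synthetic cohort as files under outdir/data."""
    if config.simulate is None:
        raise ValueError("config has no simulation block")
    data = prepare_data(config, need_genotypes=True)
    outdir = Path(config.outdir) / "data"
    outdir.mkdir(parents=True, exist_ok=True)
    paths = write_cohort_tables(data.pedigree, outdir)
    data.phenotypes.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False,
                           float_format="%.6g")
    write_vcf(data.genotypes, outdir / "genotypes.vcf")
    ss = data.summary_stats.table.rename(columns={
        "snp": "SNP", "effect_allele": "A1", "other_allele": "A2",
        "weight": "BETA", "p": "P",
    })
    ss.to_csv(outdir / "summary_stats.tsv", sep="\t", index=False,
              float_format="%.6g")
    write_truth_manifest(outdir / "truth.yaml", data.truth, seed=config.seed)
    return {"outdir": str(outdir), "n_individuals": len(data.pedigree),
            **_stamp(config)}


def run_univariate(config: StudyConfig, data: StudyData | None = None) -> dict:
    """Stepwise variance decomposition of the ordinal pain grade.

    Fits the additive-only model plus each shared-environment candidate,
    selects forward by the configured criterion, and reports the full
    model-comparison table plus the selected model's variance
    proportions from both backends.
    """
    uv = config.univariate
    data = data or prepare_data(config)
    response = uv.get("response", "cpg")
    scale = uv.get("scale", "ordinal")
    criterion = uv.get("criterion", "LRT")
    spec = MixedModelSpec(
        response=response, scale=scale,
        fixed_effects=tuple(uv.get("fixed_effects", ("sex", "age", "age2"))),
        random_components=("additive",),
        mcmc=config.mcmc,
    )
    sel = stepwise_model_selection(
        spec, data.phenotypes, data.structures,
        candidates=tuple(uv.get("candidates", ("spouse", "sib", "household"))),
        criterion=criterion,
        seed=config.seed,
    )
    rows = []
    for step in sel.trace:
        rows.append({
            "model": " + ".join(step.components),
            "criterion": criterion,
            "value": step.criterion_value,
            "selected": step.components == sel.best_components,
        })
    table = pd.DataFrame(rows)

    # effect sizes for the selected model, from both backends
    best = spec.with_components(sel.best_components)
    reml_fit = fit_reml(best, data.phenotypes, data.structures)
    gibbs_fit = None
    if scale in ("ordinal", "binary"):
        gibbs_fit = fit_gibbs_ordinal(
            best, data.phenotypes, data.structures,
            seed=config.seed, control=config.mcmc,
        )

    summary = {
        "selected_model": list(sel.best_components),
        "criterion": criterion,
        "proportions_reml": reml_fit.proportions,
        "n_used": reml_fit.n_used,
        **_stamp(config),
    }
    disagreement = None
    if gibbs_fit is not None:
        summary["proportions_gibbs"] = gibbs_fit.proportions
        summary["dic"] = gibbs_fit.dic
        # flag backend disagreement beyond 2 combined SEs per component
        flags = {}
        for comp in sel.best_components:
            r, g = reml_fit.proportions[comp], gibbs_fit.proportions[comp]
            se_r = (r[2] - r[1]) / 3.92
            se_g = (g[2] - g[1]) / 3.92
            se = max(np.hypot(se_r, se_g), 1e-12)
            flags[comp] = bool(abs(r[0] - g[0]) > 2 * se)
        disagreement = flags
        summary["backend_disagreement"] = flags
    _write_report(Path(config.outdir), "univariate", table, summary)
    return {"table": table, "selection": sel, "reml_fit": reml_fit,
            "gibbs_fit": gibbs_fit, "summary": summary,
            "backend_disagreement": disagreement}


def run_bivariate(config: StudyConfig, data: StudyData | None = None) -> dict:
    """Genetic / spouse-environment / phenotypic correlation between the
    two traits, each with its constrained-null likelihood-ratio test."""
    bv = config.bivariate
    data = data or prepare_data(config)
    trait1 = bv.get("trait1", "cpg")
    trait2 = bv.get("trait2", "mdd")
    components = tuple(bv.get("components", ("additive", "spouse")))
    fixed = tuple(bv.get("fixed_effects", ("sex", "age", "age2")))

    null_rg = fit_bivariate_reml(
        data.phenotypes, trait1, trait2, data.structures,
        components=components, fixed_effects=fixed, constraint="rg",
    )
    full = fit_bivariate_reml(
        data.phenotypes, trait1, trait2, data.structures,
        components=components, fixed_effects=fixed, theta_start=null_rg.theta,
    )
    lrt_rg = correlation_significance(full, null_rg)
    env = [c for c in components if c != "additive"]
    lrt_env = null_env = None
    if env:
        null_env = fit_bivariate_reml(
            data.phenotypes, trait1, trait2, data.structures,
            components=components, fixed_effects=fixed, constraint="r_env",
        )
        lrt_env = correlation_significance(full, null_env)
    adj = adjusted_phenotypic_correlation(full)
    pearson = data.phenotypes[[trait1, trait2]].dropna().corr().iloc[0, 1]

    rows = [{
        "correlation": "genetic (rg)",
        "estimate": full.rg[0], "se": full.rg[1],
        "p_value": lrt_rg.p_value, "test": "LRT chi2(1)",
    }]
    for comp in env:
        est, se = full.r_env[comp]
        rows.append({
            "correlation": f"{comp} environment",
            "estimate": est, "se": se,
            "p_value": lrt_env.p_value if lrt_env else np.nan,
            "test": "LRT chi2(1)",
        })
    rows.append({
        "correlation": "phenotypic (adjusted)",
        "estimate": adj["estimate"], "se": adj["se"],
        "p_value": adj["p_value"], "test": "z two-tailed",
    })
    rows.append({
        "correlation": "phenotypic (Pearson, raw)",
        "estimate": float(pearson), "se": np.nan, "p_value": np.nan,
        "test": "descriptive",
    })
    table = pd.DataFrame(rows)
    summary = {
        "rg": full.rg, "r_env": full.r_env,
        "r_phenotypic": full.r_phenotypic,
        "lrt_rg_p": lrt_rg.p_value,
        "lrt_env_p": lrt_env.p_value if lrt_env else None,
        "n_individuals": full.n_individuals,
        "n_pairs_informative": full.n_pairs_informative,
        **_stamp(config),
    }
    _write_report(Path(config.outdir), "bivariate", table, summary)
    return {"table": table, "full": full, "null_rg": null_rg,
            "null_env": null_env, "lrt_rg": lrt_rg, "lrt_env": lrt_env,
            "summary": summary}


def run_prs(config: StudyConfig, data: StudyData | None = None) -> dict:
    """Polygenic profile scoring and association.

    Scores the target cohort at each p-value threshold, associates the
    standardized score with the same trait and the cross trait under
    relatedness adjustment, and repeats the same-trait association after
    excluding individuals affected by the cross trait."""
    pc = config.prs
    data = data or prepare_data(config, need_genotypes=True)
    thresholds = tuple(pc.get("thresholds", (0.01, 0.05, 0.1, 0.5)))
    response = pc.get("response", "cpg")
    cross = pc.get("cross_response", "mdd")
    k_anc = int(pc.get("ancestry_components", 4))
    backend = pc.get("backend", "reml")
    use_rel = bool(pc.get("use_relatedness", True))
    structures = {"additive": data.structures["additive"]} if use_rel else None

    profile = threshold_and_score(data.summary_stats, data.genotypes,
                                  thresholds=thresholds)
    anc = ancestry_components(data.genotypes, k=k_anc) if k_anc else None
    phe = data.phenotypes

    rows = []
    results = {}
    for role, resp, frame in (
        ("same_trait", response, phe),
        ("cross_trait", cross, phe),
        ("excluding_affected", response, phe[phe[cross] == 0]),
    ):
        for pt in thresholds:
            if pt not in profile.standardized:
                continue
            res = prs_mixed_association(
                profile, pt, frame, resp,
                structures=structures,
                ancestry=anc, backend=backend,
                mcmc_control=config.mcmc, mcmc_seed=config.seed,
            )
            results[(role, pt)] = res
            rows.append({
                "analysis": role, "response": resp, "threshold": pt,
                "n_snps": res.n_snps_used, "beta": res.beta,
                "ci_low": res.interval[0], "ci_high": res.interval[1],
                "p_value": res.p_value,
                "variance_explained": res.variance_explained,
                "n": res.n_used,
            })
    table = pd.DataFrame(rows)
    n_excluded = int((phe[cross] != 0).sum())
    summary = {
        "thresholds": list(thresholds),
        "n_snps_used": {str(k): v for k, v in profile.n_snps_used.items()},
        "n_target": data.genotypes.n_individuals,
        "n_excluded_affected": n_excluded,
        **_stamp(config),
    }
    _write_report(Path(config.outdir), "prs", table, summary)
    return {"table": table, "profile": profile, "results": results,
            "summary": summary}


def run_all(config: StudyConfig) -> dict:
    data = prepare_data(config, need_genotypes=True)
    return {
        "univariate": run_univariate(config, data),
        "bivariate": run_bivariate(config, data),
        "prs": run_prs(config, data),
    }
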