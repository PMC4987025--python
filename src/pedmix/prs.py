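"""Polygenic risk scoring from GWAS summary statistics.

A score at p-value threshold ``pT`` is the weighted allele-dosage sum
over SNPs whose discovery p-value is at or below ``pT``; weights come
from an independent discovery study (log odds or linear effects).
Alleles are aligned to the target genotypes before scoring: weights are
negated when the counted allele is the discovery study's other allele,
and strand-ambiguous (A/T, C/G) or mismatching SNPs are excluded.
Scores are standardized and associated with phenotypes in a mixed model
with the pedigree relationship matrix (or plain regression for an
unrelated cohort), adjusting for sex, age, age squared and ancestry
components; variance explained is ``Var(beta * score) / Var(phenotype)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .relatedness import RelationshipStructure

__all__ = [
    "SummaryStats",
    "GenotypeMatrix",
    "PRSProfile",
    "PRSAssociationResult",
    "SummaryStatsError",
    "GenotypeFormatError",
    "AlignmentResult",
    "read_summary_stats",
    "read_genotypes",
    "write_vcf",
    "write_dosage_tsv",
    "align_alleles",
    "threshold_and_score",
    "ancestry_components",
    "prs_mixed_association",
    "prs_variance_explained",
    "prune_by_ld",
]

DEFAULT_THRESHOLDS = (0.01, 0.05, 0.1, 0.5)
VALID_ALLELES = frozenset("ACGT")
AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


class SummaryStatsError(ValueError):
    """Summary-statistics file is malformed or violates invariants."""


class GenotypeFormatError(ValueError):
    """Genotype file is malformed (carries the offending line number)."""


@dataclass
class SummaryStats:
    """Per-SNP discovery records: id, effect/other allele, weight, p."""

    table: pd.DataFrame  # columns: snp, effect_allele, other_allele, weight, p

    def __post_init__(self):
        t = self.table
        required = ["snp", "effect_allele", "other_allele", "weight", "p"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise SummaryStatsError(f"summary statistics lack column(s) {missing}")
        dup = t["snp"][t["snp"].duplicated()]
        if len(dup):
            raise SummaryStatsError(f"duplicated SNP id(s): {sorted(set(dup))[:5]}")
        bad_alleles = t[
            ~t["effect_allele"].isin(VALID_ALLELES) | ~t["other_allele"].isin(VALID_ALLELES)
        ]
        if len(bad_alleles):
            raise SummaryStatsError(
                f"invalid allele codes for SNP(s) {list(bad_alleles['snp'])[:5]}"
            )
        p = t["p"].to_numpy(dtype=float)
        if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p > 1.0):
            bad = t["snp"][(p <= 0) | (p > 1) | ~np.isfinite(p)]
            raise SummaryStatsError(
                f"p-values must lie in (0, 1]; offending SNP(s): {list(bad)[:5]}"
            )

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GenotypeMatrix:
    """Dosages of the counted allele, individuals x SNPs, NaN = missing."""

    ids: tuple[str, ...]
    snp_ids: tuple[str, ...]
    counted_allele: tuple[str, ...]
    other_allele: tuple[str, ...]
    dosages: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages)
        if self.dosages.dtype != np.int8:  # int8 allowed (no missing values)
            self.dosages = self.dosages.astype(np.float32, copy=False)
        n, m = self.dosages.shape
        if n != len(self.ids) or m != len(self.snp_ids):
            raise ValueError("dosage matrix shape does not match id/SNP lists")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0.0) < 0 or np.nanmax(self.dosages, initial=0.0) > 2:
                raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def allele_frequencies(self) -> np.ndarray:
        """Sample frequency of the counted allele per SNP."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0


@dataclass
class PRSProfile:
    """Scores at each p-value threshold."""

    ids: tuple[str, ...]
    thresholds: tuple[float, ...]
    n_snps_used: dict[float, int]
    raw: dict[float, np.ndarray]
    standardized: dict[float, np.ndarray]
    snps_used: dict[float, tuple[str, ...]] = field(default_factory=dict)

    def score_frame(self) -> pd.DataFrame:
        data = {"id": list(self.ids)}
        for pt in self.thresholds:
            if pt in self.raw:
                data[f"prs_raw_p{pt:g}"] = self.raw[pt]
                data[f"prs_std_p{pt:g}"] = self.standardized[pt]
        return pd.DataFrame(data)


@dataclass
class PRSAssociationResult:
    threshold: float
    beta: float
    interval: tuple[float, float]
    p_value: float
    variance_explained: float
    n_used: int
    n_snps_used: int
    backend: str


# ---------------------------------------------------------------------
# readers / writers

DEFAULT_COLUMN_MAP = {
    "snp": "SNP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "weight": "BETA",
    "p": "P",
}


def read_summary_stats(
    path: str | Path, column_map: dict[str, str] | None = None
) -> SummaryStats:
    """Read a summary-statistics TSV; ``column_map`` maps the canonical
    field names (snp, effect_allele, other_allele, weight, p) to the
    file's column headers (default SNP/A1/A2/BETA/P)."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t")
    missing = [col for col in cmap.values() if col not in df.columns]
    if missing:
        raise SummaryStatsError(
            f"summary file {path} lacks column(s) {missing}; found {list(df.columns)}"
        )
    table = pd.DataFrame(
        {
            "snp": df[cmap["snp"]].astype(str),
            "effect_allele": df[cmap["effect_allele"]].astype(str).str.upper(),
            "other_allele": df[cmap["other_allele"]].astype(str).str.upper(),
            "weight": df[cmap["weight"]].astype(float),
            "p": df[cmap["p"]].astype(float),
        }
    )
    return SummaryStats(table=table)


_GT_DOSAGE = {
    "0/0": 0.0, "0|0": 0.0,
    "0/1": 1.0, "1/0": 1.0, "0|1": 1.0, "1|0": 1.0,
    "1/1": 2.0, "1|1": 2.0,
    "./.": np.nan, ".|.": np.nan, ".": np.nan,
}


def read_genotypes(path: str | Path, format: str = "vcf") -> GenotypeMatrix:
    """Load target genotypes from a VCF 4.2 (GT genotypes, ALT counted)
    or a dosage TSV (columns SNP, A1, A2, then one column per id)."""
    if format == "vcf":
        return _read_vcf(Path(path))
    if format == "dosage_tsv":
        return _read_dosage_tsv(Path(path))
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    ids: list[str] = []
    snps, a1, a2, rows = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                if len(fields) < 10:
                    raise GenotypeFormatError(
                        f"{path}:{lineno}: VCF header has no sample columns"
                    )
                ids = fields[9:]
                continue
            if not ids:
                raise GenotypeFormatError(f"{path}:{lineno}: data before #CHROM header")
            fields = line.split("\t")
            if len(fields) != 9 + len(ids):
                raise GenotypeFormatError(
                    f"{path}:{lineno}: expected {9 + len(ids)} columns, found {len(fields)}"
                )
            _, _, snp, ref, alt, _, _, _, fmt = fields[:9]
            if "GT" not in fmt.split(":"):
                raise GenotypeFormatError(f"{path}:{lineno}: no GT field in FORMAT")
            gt_pos = fmt.split(":").index("GT")
            row = np.empty(len(ids), dtype=np.float32)
            for k, cell in enumerate(fields[9:]):
                gt = cell.split(":")[gt_pos]
                try:
                    row[k] = _GT_DOSAGE[gt]
                except KeyError:
                    raise GenotypeFormatError(
                        f"{path}:{lineno}: unparseable genotype {gt!r}"
                    ) from None
            snps.append(snp)
            a1.append(alt.upper())  # counted allele = ALT
            a2.append(ref.upper())
            rows.append(row)
    if not rows:
        raise GenotypeFormatError(f"{path}: no variant records found")
    return GenotypeMatrix(
        ids=tuple(ids),
        snp_ids=tuple(snps),
        counted_allele=tuple(a1),
        other_allele=tuple(a2),
        dosages=np.stack(rows).T,
    )


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    for col in ("SNP", "A1", "A2"):
        if col not in df.columns:
            raise GenotypeFormatError(f"{path}: dosage TSV lacks column {col!r}")
    ids = [c for c in df.columns if c not in ("SNP", "A1", "A2")]
    return GenotypeMatrix(
        ids=tuple(ids),
        snp_ids=tuple(df["SNP"].astype(str)),
        counted_allele=tuple(df["A1"].astype(str).str.upper()),
        other_allele=tuple(df["A2"].astype(str).str.upper()),
        dosages=df[ids].to_numpy(dtype=np.float32).T,
    )


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Minimal VCF 4.2 with GT genotypes; ALT is the counted allele."""
    lines = [
        "##fileformat=VCFv4.2",
        "##source=pedmix",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(geno.ids),
    ]
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    for j, snp in enumerate(geno.snp_ids):
        col = geno.dosages[:, j]
        gts = "\t".join(
            "./." if np.isnan(d) else gt_of[float(round(d))] for d in col
        )
        lines.append(
            f"1\t{j + 1}\t{snp}\t{geno.other_allele[j]}\t{geno.counted_allele[j]}"
            f"\t.\tPASS\t.\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_dosage_tsv(geno: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(geno.dosages.T, columns=list(geno.ids))
    df.insert(0, "A2", list(geno.other_allele))
    df.insert(0, "A1", list(geno.counted_allele))
    df.insert(0, "SNP", list(geno.snp_ids))
    df.to_csv(path, sep="\t", index=False, float_format="%g")


# ---------------------------------------------------------------------
# alignment and scoring


@dataclass
class AlignmentResult:
    """Aligned weights over target SNP columns plus the exclusion report."""

    snp_index: np.ndarray              # target SNP column indices retained
    weights: np.ndarray                # on the counted-allele scale
    p_values: np.ndarray
    exclusions: list[tuple[str, str]]  # (snp, reason)


def align_alleles(
    stats: SummaryStats,
    geno: GenotypeMatrix,
    exclude_ambiguous: bool = True,
) -> AlignmentResult:
    """Match discovery weights to the target's counted alleles.

    Weights are kept as-is when the counted allele equals the effect
    allele, negated when the allele labels are swapped; strand-ambiguous
    (A/T, C/G) and mismatching SNPs are excluded, with each exclusion
    reported by reason."""
    target = pd.DataFrame({
        "snp": list(geno.snp_ids),
        "counted": list(geno.counted_allele),
        "other": list(geno.other_allele),
        "col": np.arange(geno.n_snps),
    })
    merged = target.merge(stats.table, on="snp", how="inner")
    if merged.empty:
        raise SummaryStatsError("no overlapping SNPs between summary stats and target")
    same = (merged["counted"] == merged["effect_allele"]) \
        & (merged["other"] == merged["other_allele"])
    swapped = (merged["counted"] == merged["other_allele"]) \
        & (merged["other"] == merged["effect_allele"])
    comp = merged["counted"].map({"A": "T", "T": "A", "C": "G", "G": "C"})
    ambiguous = comp == merged["other"]
    exclusions: list[tuple[str, str]] = []
    if exclude_ambiguous:
        for snp in merged.loc[ambiguous, "snp"]:
            exclusions.append((snp, "strand-ambiguous"))
        same &= ~ambiguous
        swapped &= ~ambiguous
        mismatch = ~(same | swapped | ambiguous)
    else:
        mismatch = ~(same | swapped)
    for snp in merged.loc[mismatch, "snp"]:
        exclusions.append((snp, "allele-mismatch"))
    kept = merged[same | swapped]
    weights = np.where(kept["counted"] == kept["effect_allele"],
                       kept["weight"], -kept["weight"])
    return AlignmentResult(
        snp_index=kept["col"].to_numpy(dtype=int),
        weights=weights.astype(float),
        p_values=kept["p"].to_numpy(dtype=float),
        exclusions=exclusions,
    )


def threshold_and_score(
    stats: SummaryStats,
    geno: GenotypeMatrix,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    alignment: AlignmentResult | None = None,
) -> PRSProfile:
    """Per-individual scores at each p-value threshold.

    ``score_i = sum_{j: p_j <= pT} w_j * dosage_ij`` with missing
    dosages imputed at twice the counted-allele sample frequency.  A
    threshold retaining zero SNPs yields a warning and no profile."""
    if alignment is None:
        alignment = align_alleles(stats, geno)
    dos = geno.dosages[:, alignment.snp_index]
    if dos.size and dos.dtype != np.int8 and np.isnan(dos.min()):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-missing SNPs
            freqs = np.nan_to_num(np.nanmean(dos, axis=0) / 2.0, nan=0.0)
        dos = np.where(np.isnan(dos), (2.0 * freqs[None, :]).astype(dos.dtype), dos)
    n_used, raw, std, used = {}, {}, {}, {}
    for pt in thresholds:
        keep = alignment.p_values <= pt
        k = int(keep.sum())
        if k == 0:
            warnings.warn(f"threshold p<={pt} retains no SNPs; profile omitted")
            continue
        score = (dos[:, keep].astype(np.float32)
                 @ alignment.weights[keep].astype(np.float32)).astype(np.float64)
        sd = score.std()
        n_used[pt] = k
        raw[pt] = score
        std[pt] = (score - score.mean()) / sd if sd > 0 else score - score.mean()
        used[pt] = tuple(geno.snp_ids[j] for j in alignment.snp_index[keep])
    return PRSProfile(
        ids=geno.ids,
        thresholds=tuple(thresholds),
        n_snps_used=n_used,
        raw=raw,
        standardized=std,
        snps_used=used,
    )


def ancestry_components(geno: GenotypeMatrix, k: int = 4) -> np.ndarray:
    """Top-k principal components of the centered, frequency-standardized
    genotype matrix (the ancestry adjustment covariates).  Deterministic
    sign: each component's largest-magnitude entry is positive."""
    if k == 0:
        return np.zeros((geno.n_individuals, 0))
    freqs = geno.allele_frequencies()
    var = 2.0 * freqs * (1.0 - freqs)
    keep = var > 0
    if keep.sum() < k:
        raise ValueError(f"k={k} exceeds the number of variable SNPs ({int(keep.sum())})")
    Z = (geno.dosages[:, keep].astype(float) - 2.0 * freqs[keep]) / np.sqrt(var[keep])
    Z = np.nan_to_num(Z, nan=0.0)
    if k > min(Z.shape) or k > np.linalg.matrix_rank(Z):
        raise ValueError(f"k={k} exceeds the rank of the genotype matrix")
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    comps = U[:, :k] * s[:k]
    for j in range(k):
        if comps[np.argmax(np.abs(comps[:, j])), j] < 0:
            comps[:, j] = -comps[:, j]
    return comps


def prune_by_ld(
    geno: GenotypeMatrix,
    p_values: dict[str, float] | None = None,
    r2_threshold: float = 0.1,
    window: int = 250,
) -> list[str]:
    """Greedy r^2-window pruning for real (linked) data: visit SNPs by
    ascending p-value (or input order), keep a SNP unless it is within
    ``window`` columns of a kept SNP with squared correlation above the
    threshold.  Returns the kept SNP ids."""
    m = geno.n_snps
    order = np.arange(m)
    if p_values:
        pv = np.array([p_values.get(s, 1.0) for s in geno.snp_ids])
        order = np.argsort(pv, kind="stable")
    dos = geno.dosages.astype(float)
    col_mean = np.nanmean(dos, axis=0)
    dos = np.where(np.isnan(dos), col_mean[None, :], dos)
    kept: list[int] = []
    for j in order:
        ok = True
        for i in kept:
            if abs(i - j) > window:
                continue
            r = np.corrcoef(dos[:, i], dos[:, j])[0, 1]
            if np.isfinite(r) and r * r > r2_threshold:
                ok = False
                break
        if ok:
            kept.append(int(j))
    kept_set = sorted(kept)
    return [geno.snp_ids[j] for j in kept_set]


# ---------------------------------------------------------------------
# association


def prs_mixed_association(
    profile: PRSProfile,
    threshold: float,
    phenotypes: pd.DataFrame,
    response: str,
    structures: dict[str, RelationshipStructure] | None = None,
    fixed_effects: tuple[str, ...] = ("sex", "age", "age2"),
    ancestry: np.ndarray | None = None,
    backend: str = "reml",
    standardize_response: bool = True,
    mcmc_control=None,
    mcmc_seed: int = 0,
) -> PRSAssociationResult:
    """Association of the standardized score with a phenotype.

    With ``structures`` containing an additive relationship matrix the
    model accounts for relatedness (REML Wald test, or the Gibbs backend
    with a posterior credible interval); with ``structures=None`` it is
    a plain fixed-effects regression for an unrelated cohort.  The
    response is standardized for ordinal phenotypes so the coefficient
    is a standardized beta."""
    from .variance import FAST_MCMC, MixedModelSpec, fit_reml

    if threshold not in profile.standardized:
        raise ValueError(f"profile has no scores at threshold {threshold}")
    score = profile.standardized[threshold]
    if score.std() == 0:
        raise ValueError("score is constant; association undefined")
    df = phenotypes.copy()
    df["id"] = df["id"].astype(str)
    sf = pd.DataFrame({"id": list(profile.ids), "prs": score})
    if ancestry is not None:
        ancestry = np.asarray(ancestry, dtype=float)
        for j in range(ancestry.shape[1]):
            sf[f"pc{j + 1}"] = ancestry[:, j]
    df = df.merge(sf, on="id", how="inner")
    if "age2" in fixed_effects and "age2" not in df.columns and "age" in df.columns:
        df["age2"] = df["age"].astype(float) ** 2
    work = response
    if standardize_response:
        y = df[response].astype(float)
        df["_y_std"] = (y - y.mean()) / y.std()
        work = "_y_std"
    fe = tuple(fixed_effects) + tuple(
        f"pc{j + 1}" for j in range(0 if ancestry is None else ancestry.shape[1])
    ) + ("prs",)

    if backend == "gibbs":
        from .gibbs import fit_gibbs_ordinal

        scale = "binary" if df[response].nunique() == 2 else "ordinal"
        spec = MixedModelSpec(
            response=response, scale=scale, fixed_effects=fe,
            random_components=tuple(structures) if structures else ("additive",),
            mcmc=mcmc_control or FAST_MCMC,
        )
        fit = fit_gibbs_ordinal(spec, df, structures, seed=mcmc_seed,
                                control=mcmc_control or FAST_MCMC)
        draws = fit.posterior["beta"][:, list(fit.fixed_effects).index("prs")]
        beta = float(draws.mean())
        lo, hi = np.percentile(draws, [2.5, 97.5])
        tail = min((draws > 0).mean(), (draws < 0).mean())
        p = float(max(2.0 * tail, 1.0 / draws.size))
        var_resp = 1.0  # latent scale
    else:
        if structures:
            spec = MixedModelSpec(
                response=work, scale="gaussian", fixed_effects=fe,
                random_components=tuple(structures),
            )
            fit = fit_reml(spec, df, structures)
            beta, se = fit.fixed_effects["prs"]
        else:
            cols = [np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in fe]
            X = np.column_stack(cols)
            yv = df[work].to_numpy(dtype=float)
            coef, _, _, _ = np.linalg.lstsq(X, yv, rcond=None)
            resid = yv - X @ coef
            dof = len(df) - X.shape[1]
            sigma2 = resid @ resid / dof
            cov = sigma2 * np.linalg.inv(X.T @ X)
            beta = float(coef[-1])
            se = float(np.sqrt(cov[-1, -1]))
        lo, hi = beta - 1.96 * se, beta + 1.96 * se
        p = float(2.0 * stats.norm.sf(abs(beta / se))) if se > 0 else np.nan
        var_resp = float(np.var(df[work].to_numpy(dtype=float)))
        beta = float(beta)
    mask = np.isin(np.asarray(profile.ids), df["id"].to_numpy())
    r2 = prs_variance_explained(score[mask], beta, df[work].to_numpy(dtype=float)) \
        if backend != "gibbs" else float(beta**2 * 1.0 / max(var_resp, 1e-300))
    return PRSAssociationResult(
        threshold=threshold,
        beta=beta,
        interval=(float(lo), float(hi)),
        p_value=p,
        variance_explained=float(np.clip(r2, 0.0, 1.0)),
        n_used=len(df),
        n_snps_used=profile.n_snps_used[threshold],
        backend=backend,
    )


def prs_variance_explained(score: np.ndarray, beta: float, phenotype: np.ndarray) -> float:
    """Coefficient of determination of the score: the variance of
    ``beta * score`` divided by the phenotype variance."""
    var_ph = float(np.var(np.asarray(phenotype, dtype=float)))
    if var_ph <= 0:
        raise ValueError("phenotype has zero variance")
    return float(beta**2 * np.var(np.asarray(score, dtype=float)) / var_ph)
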