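"""Bivariate pedigree mixed models: partitioning the covariance between
two traits (e.g. chronic pain grade and depression status, both on a
numeric working scale) into per-component 2x2 covariance blocks.

Each random component ``k`` contributes ``Cov_k (x) K_k`` (Kronecker of
an unstructured 2x2 trait covariance with the relationship structure);
the residual is ``Cov_e (x) I``.  Estimation is by the same blocked
AI-REML engine as the univariate models, over the stacked two-trait
observation vector; individuals missing one trait contribute the other
(pairwise-complete likelihood).  Correlations are derived as
``cov / sqrt(var1 * var2)`` with delta-method standard errors, and the
significance of a genetic or environmental correlation comes from a
likelihood-ratio test against a fit with that off-diagonal pinned at 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .relatedness import RelationshipStructure
from .reml import BlockedREML
from .variance import LRTResult, likelihood_ratio_test

__all__ = [
    "BivariateFit",
    "fit_bivariate_reml",
    "constrained_fit",
    "correlation_significance",
    "adjusted_phenotypic_correlation",
]


@dataclass
class BivariateFit:
    """Per-component 2x2 covariance blocks and derived correlations."""

    components: dict[str, np.ndarray]          # name -> 2x2 block (incl residual)
    rg: tuple[float, float]                    # additive correlation, SE
    r_env: dict[str, tuple[float, float]]      # per shared-env component
    r_phenotypic: tuple[float, float]          # total-covariance correlation, SE
    log_likelihood: float
    n_used: int                                # stacked observations
    n_individuals: int
    n_pairs_informative: dict[str, int]        # groups of size >= 2 per component
    converged: bool
    constraint: str | None = None
    theta: np.ndarray | None = None
    theta_cov: np.ndarray | None = None
    param_names: list[str] = field(default_factory=list)
    fixed_effects: dict[str, float] = field(default_factory=dict)

    def correlation(self, component: str) -> tuple[float, float]:
        if component == "additive":
            return self.rg
        return self.r_env[component]


def _corr_and_se(theta, cov, i11, i12, i22):
    c11, c12, c22 = theta[i11], theta[i12], theta[i22]
    denom = np.sqrt(max(c11 * c22, 1e-300))
    r = c12 / denom
    grad = np.zeros(len(theta))
    grad[i11] = -0.5 * r / max(c11, 1e-300)
    grad[i22] = -0.5 * r / max(c22, 1e-300)
    grad[i12] = 1.0 / denom
    se = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    return float(np.clip(r, -1.0, 1.0)), se


def _stack_component(K: sp.csr_matrix, map1, map2, N) -> list[sp.csr_matrix]:
    """Three stacked derivative matrices (d/dc11, d/dc12, d/dc22) for one
    relationship structure over the two-trait observation vector."""
    coo = K.tocoo()
    out = []
    for which in ("c11", "c12", "c22"):
        rows, cols, vals = [], [], []
        for i, j, v in zip(coo.row, coo.col, coo.data):
            if which == "c11":
                r, c = map1[i], map1[j]
                if r >= 0 and c >= 0:
                    rows.append(r); cols.append(c); vals.append(v)
            elif which == "c22":
                r, c = map2[i], map2[j]
                if r >= 0 and c >= 0:
                    rows.append(r); cols.append(c); vals.append(v)
            else:
                r, c = map1[i], map2[j]
                if r >= 0 and c >= 0:
                    rows.append(r); cols.append(c); vals.append(v)
                    rows.append(c); cols.append(r); vals.append(v)
        out.append(sp.coo_matrix((vals, (rows, cols)), shape=(N, N)).tocsr())
    return out


def _count_pairs(K: sp.csr_matrix) -> int:
    ncomp, labels = sp.csgraph.connected_components(K, directed=False)
    sizes = np.bincount(labels)
    return int(np.sum(sizes >= 2))


def fit_bivariate_reml(
    phenotypes: pd.DataFrame,
    trait1: str,
    trait2: str,
    structures: dict[str, RelationshipStructure],
    components: tuple[str, ...] = ("additive", "spouse"),
    fixed_effects: tuple[str, ...] = ("sex", "age", "age2"),
    constraint: str | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
    theta_start: np.ndarray | None = None,
) -> BivariateFit:
    """REML fit of the two-trait model with unstructured 2x2 covariance
    per component.  ``constraint`` pins one cross-trait covariance at 0:
    ``"rg"`` (the additive block), ``"r_env"`` (the first non-additive
    component), or a component name.
    """
    if "additive" not in components:
        raise ValueError("the bivariate model requires an additive component")
    for name in components:
        if name not in structures:
            raise ValueError(f"component {name!r} has no structure")

    df = phenotypes.copy()
    df["id"] = df["id"].astype(str)
    if "age2" in fixed_effects and "age2" not in df.columns and "age" in df.columns:
        df["age2"] = df["age"].astype(float) ** 2
    for c in fixed_effects:
        if c not in df.columns:
            raise ValueError(f"phenotype table lacks covariate {c!r}")
    df = df.drop_duplicates(subset="id").set_index("id")
    ref = structures["additive"]
    ids = [i for i in ref.ids if i in df.index]
    sub = df.loc[ids]
    y1 = sub[trait1].to_numpy(dtype=float)
    y2 = sub[trait2].to_numpy(dtype=float)
    obs1, obs2 = np.isfinite(y1), np.isfinite(y2)
    if np.nanvar(y1[obs1]) <= 0 or np.nanvar(y2[obs2]) <= 0:
        raise ValueError("a trait with zero variance cannot be analysed")
    n_ind = len(ids)
    map1 = np.full(n_ind, -1)
    map2 = np.full(n_ind, -1)
    map1[obs1] = np.arange(obs1.sum())
    map2[obs2] = obs1.sum() + np.arange(obs2.sum())
    N = int(obs1.sum() + obs2.sum())

    y = np.concatenate([y1[obs1], y2[obs2]])
    cov_cols = [np.ones(n_ind)] + [sub[c].to_numpy(dtype=float) for c in fixed_effects]
    Xi = np.column_stack(cov_cols)
    p1 = Xi.shape[1]
    X = np.zeros((N, 2 * p1))
    X[: obs1.sum(), :p1] = Xi[obs1]
    X[obs1.sum():, p1:] = Xi[obs2]
    xnames = [f"{trait1}:{c}" for c in ("intercept", *fixed_effects)] + [
        f"{trait2}:{c}" for c in ("intercept", *fixed_effects)
    ]

    comp_all = list(components) + ["residual"]
    derivs: list[sp.csr_matrix] = []
    param_names: list[str] = []
    pair_counts: dict[str, int] = {}
    for name in comp_all:
        if name == "residual":
            K = sp.identity(n_ind, format="csr")
        else:
            K = sp.csr_matrix(structures[name].submatrix(ids))
            pair_counts[name] = _count_pairs(sp.csr_matrix(K - sp.diags(K.diagonal())))
        derivs.extend(_stack_component(K, map1, map2, N))
        param_names.extend([f"{name}:{w}" for w in ("var1", "cov", "var2")])

    nq = len(param_names)
    theta0 = np.zeros(nq)
    lower = np.full(nq, -np.inf)
    v1 = float(np.var(y1[obs1]))
    v2 = float(np.var(y2[obs2]))
    ncomp = len(comp_all)
    for k, name in enumerate(comp_all):
        theta0[3 * k] = v1 / ncomp
        theta0[3 * k + 2] = v2 / ncomp
        lower[3 * k] = 0.0
        lower[3 * k + 2] = 0.0
    if theta_start is not None:
        theta0 = np.asarray(theta_start, dtype=float).copy()
    lower[3 * (ncomp - 1)] = 1e-8 * v1
    lower[3 * (ncomp - 1) + 2] = 1e-8 * v2

    free = np.ones(nq, dtype=bool)
    if constraint is not None:
        if constraint == "rg":
            target = "additive"
        elif constraint == "r_env":
            env = [c for c in components if c != "additive"]
            if not env:
                raise ValueError("no shared-environment component to constrain")
            target = env[0]
        elif constraint in components:
            target = constraint
        else:
            raise ValueError(f"unknown constraint {constraint!r}")
        k = comp_all.index(target)
        theta0[3 * k + 1] = 0.0
        free[3 * k + 1] = False

    problem = BlockedREML(y, X, derivs, param_names=param_names)
    res = problem.fit(theta0, lower=lower, free=free, max_iter=max_iter, tol=tol)

    blocks: dict[str, np.ndarray] = {}
    for k, name in enumerate(comp_all):
        c11, c12, c22 = res.theta[3 * k: 3 * k + 3]
        blocks[name] = np.array([[c11, c12], [c12, c22]])

    idx = {nm: i for i, nm in enumerate(param_names)}

    def cidx(name):
        return idx[f"{name}:var1"], idx[f"{name}:cov"], idx[f"{name}:var2"]

    rg = _corr_and_se(res.theta, res.theta_cov, *cidx("additive"))
    r_env = {
        name: _corr_and_se(res.theta, res.theta_cov, *cidx(name))
        for name in components
        if name != "additive"
    }
    # total (phenotypic) correlation from summed blocks, delta method
    T = sum(blocks.values())
    t11, t12, t22 = T[0, 0], T[0, 1], T[1, 1]
    denom = np.sqrt(max(t11 * t22, 1e-300))
    rp = t12 / denom
    grad = np.zeros(nq)
    for name in comp_all:
        i11, i12, i22 = cidx(name)
        grad[i11] = -0.5 * rp / max(t11, 1e-300)
        grad[i22] = -0.5 * rp / max(t22, 1e-300)
        grad[i12] = 1.0 / denom
    rp_se = float(np.sqrt(max(grad @ res.theta_cov @ grad, 0.0)))

    return BivariateFit(
        components=blocks,
        rg=rg,
        r_env=r_env,
        r_phenotypic=(float(np.clip(rp, -1, 1)), rp_se),
        log_likelihood=res.log_likelihood,
        n_used=N,
        n_individuals=n_ind,
        n_pairs_informative=pair_counts,
        converged=res.converged,
        constraint=constraint,
        theta=res.theta,
        theta_cov=res.theta_cov,
        param_names=param_names,
        fixed_effects=dict(zip(xnames, map(float, res.beta))),
    )


def constrained_fit(
    phenotypes: pd.DataFrame,
    trait1: str,
    trait2: str,
    structures: dict[str, RelationshipStructure],
    constraint: str,
    components: tuple[str, ...] = ("additive", "spouse"),
    **kwargs,
) -> BivariateFit:
    """Null fit with the named cross-trait covariance pinned at zero
    (``"rg"`` for the genetic block, ``"r_env"`` for the shared
    environment); every other parameter stays free."""
    return fit_bivariate_reml(
        phenotypes, trait1, trait2, structures,
        components=components, constraint=constraint, **kwargs,
    )


def correlation_significance(full: BivariateFit, null: BivariateFit) -> LRTResult:
    """Chi-squared(1) likelihood-ratio test of a pinned correlation."""
    return likelihood_ratio_test(full.log_likelihood, null.log_likelihood, df=1)


def adjusted_phenotypic_correlation(
    fit_or_phenotypes,
    trait1: str | None = None,
    trait2: str | None = None,
    structures: dict[str, RelationshipStructure] | None = None,
    **kwargs,
) -> dict[str, float]:
    """Fixed-effect-adjusted phenotypic correlation with its z-test.

    Accepts an existing :class:`BivariateFit`, or raw inputs which are
    fitted first (additive + residual).  The estimate is the correlation
    of the summed component covariance; significance is the estimate /
    SE ratio against a standard normal, two tailed.
    """
    if isinstance(fit_or_phenotypes, BivariateFit):
        fit = fit_or_phenotypes
    else:
        fit = fit_bivariate_reml(
            fit_or_phenotypes, trait1, trait2, structures,
            components=kwargs.pop("components", ("additive",)), **kwargs,
        )
    est, se = fit.r_phenotypic
    if se <= 0:
        raise ValueError("degenerate fit: zero standard error for the correlation")
    z = est / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return {"estimate": est, "se": se, "z": float(z), "p_value": p}
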