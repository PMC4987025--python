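"""Univariate variance-component models over pedigree structures.

The response (an ordinal pain grade fitted as a numeric working score, a
binary disease indicator, or a Gaussian trait) is decomposed into an
additive genetic part, optional shared-environment parts (spouse /
sibship / household), and a residual.  Two backends estimate the
components: Gaussian AI-REML (this module) and an ordinal-probit Gibbs
sampler (:mod:`pedmix.gibbs`).  Model comparison follows a forward
stepwise procedure over the shared-environment candidates, judged either
by likelihood-ratio tests (REML) or by DIC (MCMC).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .relatedness import RelationshipStructure
from .reml import BlockedREML

__all__ = [
    "MCMCControl",
    "FAST_MCMC",
    "MixedModelSpec",
    "VarianceComponentFit",
    "LRTResult",
    "fit_reml",
    "variance_proportions",
    "likelihood_ratio_test",
    "dic_from_trace",
    "stepwise_model_selection",
    "SelectionStep",
    "SelectionResult",
]


@dataclass(frozen=True)
class MCMCControl:
    """Chain settings for the Gibbs backend (defaults follow common
    practice for Bayesian pedigree models: long chains, heavy thinning)."""

    iterations: int = 85_000
    burn_in: int = 15_000
    thin: int = 50
    chains: int = 3

    def __post_init__(self):
        if min(self.iterations, self.burn_in, self.thin, self.chains) <= 0:
            raise ValueError("MCMC control values must be positive")
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")


#: short-chain profile for tests and quick runs
FAST_MCMC = MCMCControl(iterations=5_000, burn_in=1_000, thin=5, chains=1)


@dataclass(frozen=True)
class MixedModelSpec:
    """What to fit: response column + scale, fixed effects, and the named
    random components (keys into a structures dict)."""

    response: str
    scale: str = "gaussian"  # gaussian | ordinal | binary
    fixed_effects: tuple[str, ...] = ("sex", "age", "age2")
    random_components: tuple[str, ...] = ("additive",)
    priors: dict | None = None
    mcmc: MCMCControl = field(default_factory=MCMCControl)

    def __post_init__(self):
        if not self.random_components:
            raise ValueError("at least one random component is required")
        if self.scale not in ("gaussian", "ordinal", "binary"):
            raise ValueError(f"unknown response scale {self.scale!r}")

    def with_components(self, components: tuple[str, ...]) -> "MixedModelSpec":
        return replace(self, random_components=tuple(components))


@dataclass
class VarianceComponentFit:
    """Estimated variance components and derived quantities.

    ``estimates`` includes the residual; ``proportions`` maps each
    component (and ``residual``) to (point, lower95, upper95) shares of
    the total variance.  REML fits carry ``log_likelihood``; MCMC fits
    carry ``dic`` plus posterior draws in ``posterior``.
    """

    backend: str
    estimates: dict[str, float]
    se: dict[str, float]
    proportions: dict[str, tuple[float, float, float]]
    fixed_effects: dict[str, tuple[float, float]]
    n_used: int
    converged: bool
    log_likelihood: float | None = None
    dic: float | None = None
    theta_cov: np.ndarray | None = None
    component_order: list[str] = field(default_factory=list)
    posterior: dict[str, np.ndarray] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    @property
    def heritability(self) -> tuple[float, float, float]:
        return self.proportions["additive"]


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p_value: float
    boundary: bool = False


# ---------------------------------------------------------------------
# data preparation shared by both backends


def build_design(
    spec: MixedModelSpec,
    phenotypes: pd.DataFrame,
    structures: dict[str, RelationshipStructure],
):
    """Align phenotypes with the structures' id order and assemble the
    response vector, fixed-effects design (with intercept), and the
    per-component covariance submatrices over complete cases."""
    for name in spec.random_components:
        if name not in structures:
            raise ValueError(f"random component {name!r} has no structure")
    df = phenotypes.copy()
    if "id" not in df.columns:
        raise ValueError("phenotype table must contain an 'id' column")
    df["id"] = df["id"].astype(str)
    if "age2" in spec.fixed_effects and "age2" not in df.columns and "age" in df.columns:
        df["age2"] = df["age"].astype(float) ** 2
    cols = [spec.response, *spec.fixed_effects]
    missing_cols = [c for c in cols if c not in df.columns]
    if missing_cols:
        raise ValueError(f"phenotype table lacks column(s) {missing_cols}")
    df = df.dropna(subset=cols).drop_duplicates(subset="id").set_index("id")

    ref = structures[spec.random_components[0]]
    ids = [i for i in ref.ids if i in df.index]
    if not ids:
        raise ValueError("no phenotyped individuals overlap the pedigree structures")
    sub = df.loc[ids]
    y = sub[spec.response].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(ids))] + [sub[c].to_numpy(dtype=float) for c in spec.fixed_effects]
    )
    xnames = ["intercept", *spec.fixed_effects]
    mats = {
        name: sp.csr_matrix(structures[name].submatrix(ids))
        for name in spec.random_components
    }
    return ids, y, X, xnames, mats


def _proportions_delta(
    names: list[str], theta: np.ndarray, theta_cov: np.ndarray
) -> dict[str, tuple[float, float, float]]:
    total = float(theta.sum())
    out = {}
    for k, name in enumerate(names):
        prop = theta[k] / total
        grad = -theta[k] / total**2 * np.ones(len(theta))
        grad[k] += 1.0 / total
        var = float(grad @ theta_cov @ grad)
        se = np.sqrt(max(var, 0.0))
        out[name] = (
            float(prop),
            float(max(prop - 1.96 * se, 0.0)),
            float(min(prop + 1.96 * se, 1.0)),
        )
    return out


# ---------------------------------------------------------------------
# REML backend


def fit_reml(
    spec: MixedModelSpec,
    phenotypes: pd.DataFrame,
    structures: dict[str, RelationshipStructure],
    max_iter: int = 100,
    tol: float = 1e-6,
    theta0: dict[str, float] | None = None,
) -> VarianceComponentFit:
    """AI-REML fit of the variance components.

    Ordinal and binary responses are fitted as numeric working scores
    under this backend (the model-comparison role); the Gibbs backend
    models them on the liability scale.  ``theta0`` optionally warm
    starts named components (useful for nested-model comparisons).
    """
    ids, y, X, xnames, mats = build_design(spec, phenotypes, structures)
    names = list(spec.random_components) + ["residual"]
    n = len(y)
    derivs = [mats[c] for c in spec.random_components] + [sp.identity(n, format="csr")]
    vary = float(np.var(y))
    if vary <= 0:
        raise ValueError("response has zero variance")
    problem = BlockedREML(y, X, derivs, param_names=names)
    theta_init = np.full(len(names), vary / len(names))
    if theta0:
        for k, nm in enumerate(names):
            if nm in theta0:
                theta_init[k] = max(float(theta0[nm]), 1e-8 * vary)
    theta0 = theta_init
    lower = np.zeros(len(names))
    lower[-1] = 1e-8 * vary
    res = problem.fit(theta0, lower=lower, max_iter=max_iter, tol=tol)
    estimates = dict(zip(names, map(float, res.theta)))
    se = dict(zip(names, map(float, res.theta_se)))
    beta_se = np.sqrt(np.clip(np.diag(res.beta_cov), 0.0, None))
    return VarianceComponentFit(
        backend="reml",
        estimates=estimates,
        se=se,
        proportions=_proportions_delta(names, res.theta, res.theta_cov),
        fixed_effects={nm: (float(b), float(s)) for nm, b, s in zip(xnames, res.beta, beta_se)},
        n_used=res.n_used,
        converged=res.converged,
        log_likelihood=res.log_likelihood,
        theta_cov=res.theta_cov,
        component_order=names,
    )


def variance_proportions(fit: VarianceComponentFit) -> dict[str, tuple[float, float, float]]:
    """Each component's share of the total variance with a 95% interval
    (posterior percentiles under MCMC, delta method under REML)."""
    total = sum(fit.estimates.values())
    if total <= 0:
        raise ValueError("degenerate fit: total variance is zero")
    if fit.backend == "gibbs" and "theta" in fit.posterior:
        draws = fit.posterior["theta"]  # (nsamples, ncomp) incl residual
        shares = draws / draws.sum(axis=1, keepdims=True)
        out = {}
        for k, name in enumerate(fit.component_order):
            lo, hi = np.percentile(shares[:, k], [2.5, 97.5])
            out[name] = (float(shares[:, k].mean()), float(lo), float(hi))
        return out
    names = fit.component_order or list(fit.estimates)
    theta = np.array([fit.estimates[n] for n in names])
    return _proportions_delta(names, theta, fit.theta_cov)


# ---------------------------------------------------------------------
# model comparison


def likelihood_ratio_test(
    fit_full: VarianceComponentFit | float,
    fit_null: VarianceComponentFit | float,
    df: int = 1,
    boundary: bool = False,
) -> LRTResult:
    """2 * (logL_full - logL_null) against a chi-squared with ``df``
    degrees of freedom; optionally the boundary-corrected equal mixture
    of chi2(df) and chi2(df-1) (a point mass at zero when df = 1)."""
    ll_full = fit_full if isinstance(fit_full, (int, float)) else fit_full.log_likelihood
    ll_null = fit_null if isinstance(fit_null, (int, float)) else fit_null.log_likelihood
    if ll_full is None or ll_null is None:
        raise ValueError("both fits must carry a REML log-likelihood")
    stat = 2.0 * (ll_full - ll_null)
    if stat < -1e-6:
        raise ValueError(
            f"full model log-likelihood ({ll_full:.6f}) is below the null's "
            f"({ll_null:.6f}); the models are not nested on the same data"
        )
    stat = max(stat, 0.0)
    if boundary:
        upper = stats.chi2.sf(stat, df)
        lower_tail = stats.chi2.sf(stat, df - 1) if df > 1 else float(stat <= 0.0)
        p = 0.5 * (upper + lower_tail)
    else:
        p = float(stats.chi2.sf(stat, df))
    return LRTResult(statistic=float(stat), df=df, p_value=float(p), boundary=boundary)


def dic_from_trace(deviance: np.ndarray, deviance_at_mean: float) -> float:
    """DIC = mean deviance + p_D with p_D = mean deviance - deviance at
    the posterior means."""
    deviance = np.asarray(deviance, dtype=float)
    if deviance.size == 0:
        raise ValueError("empty deviance trace")
    dbar = float(deviance.mean())
    return dbar + (dbar - float(deviance_at_mean))


def dic(fit: VarianceComponentFit) -> float:
    """DIC of a Gibbs fit, recomputed from its stored deviance trace."""
    if "deviance" not in fit.posterior or "deviance_at_mean" not in fit.diagnostics:
        raise ValueError("fit carries no deviance trace; refit with the Gibbs backend")
    return dic_from_trace(fit.posterior["deviance"], fit.diagnostics["deviance_at_mean"])


@dataclass
class SelectionStep:
    components: tuple[str, ...]
    criterion_value: float  # DIC, or LRT p-value vs the current model
    fit: VarianceComponentFit
    accepted: bool


@dataclass
class SelectionResult:
    best_components: tuple[str, ...]
    best_fit: VarianceComponentFit
    trace: list[SelectionStep]
    criterion: str


def stepwise_model_selection(
    spec: MixedModelSpec,
    phenotypes: pd.DataFrame,
    structures: dict[str, RelationshipStructure],
    candidates: tuple[str, ...] = ("spouse", "sib", "household"),
    criterion: str = "LRT",
    alpha: float = 0.05,
    dic_margin: float = 5.0,
    seed: int | None = None,
) -> SelectionResult:
    """Forward selection of shared-environment components.

    Start from the additive-only model; fit it plus each single
    candidate; keep the best candidate if it improves the criterion
    (LRT p < alpha against the current model, or a DIC drop larger than
    ``dic_margin``); then try adding one more, stopping when no
    addition improves.  The DIC margin treats differences within the
    Monte Carlo uncertainty of the estimated deviance (a few units per
    model) as ties, and ties keep the smaller model.
    """
    from .gibbs import fit_gibbs_ordinal  # local import to avoid a cycle

    if criterion not in ("LRT", "DIC"):
        raise ValueError("criterion must be 'LRT' or 'DIC'")

    def _fit(
        components: tuple[str, ...],
        chain_seed: int | None,
        warm: VarianceComponentFit | None = None,
    ) -> VarianceComponentFit:
        s = spec.with_components(components)
        if criterion == "LRT":
            # warm start from the current model (new component near zero)
            # so the candidate's likelihood cannot fall below the null's
            theta0 = None
            if warm is not None:
                theta0 = dict(warm.estimates)
                for c in components:
                    theta0.setdefault(c, 0.0)
            return fit_reml(replace(s, scale="gaussian"), phenotypes, structures,
                            theta0=theta0, tol=1e-9)
        return fit_gibbs_ordinal(s, phenotypes, structures, seed=chain_seed)

    rng = np.random.default_rng(seed)

    def _next_seed():
        return int(rng.integers(2**31 - 1)) if criterion == "DIC" else None

    current = tuple(spec.random_components)
    current_fit = _fit(current, _next_seed())
    current_value = current_fit.dic if criterion == "DIC" else np.nan
    trace = [SelectionStep(current, current_value if criterion == "DIC" else np.nan,
                           current_fit, accepted=True)]
    remaining = [c for c in candidates if c not in current]
    while remaining:
        best = None
        for cand in remaining:
            comps = current + (cand,)
            try:
                fit = _fit(comps, _next_seed(), warm=current_fit)
                if criterion == "LRT":
                    lrt = likelihood_ratio_test(fit, current_fit, df=1)
            except Exception as err:  # failed fit or comparison: skip candidate
                import warnings

                warnings.warn(f"candidate {cand!r} skipped: {err}")
                continue
            if criterion == "LRT":
                value = lrt.p_value
                improves = value < alpha
                rank = lrt.statistic
            else:
                value = fit.dic
                improves = value < (current_fit.dic - dic_margin)
                rank = -value
            trace.append(SelectionStep(comps, value, fit, accepted=False))
            if improves and (best is None or rank > best[0]):
                best = (rank, cand, fit)
        if best is None:
            break
        _, cand, fit = best
        current = current + (cand,)
        current_fit = fit
        for step in trace:
            if step.components == current:
                step.accepted = True
        remaining = [c for c in remaining if c != cand]
    return SelectionResult(
        best_components=current, best_fit=current_fit, trace=trace, criterion=criterion
    )
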