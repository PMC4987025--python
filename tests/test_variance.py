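"""Univariate variance components: REML oracle checks, LRT and DIC
arithmetic, proportions, and stepwise selection mechanics."""

import numpy as np
import pytest
import scipy.sparse as sp

from pedmix import (
    CohortDesign,
    MixedModelSpec,
    SimulationTruth,
    additive_relationship_matrix,
    dic_from_trace,
    fit_reml,
    group_covariance_matrix,
    likelihood_ratio_test,
    simulate_pedigree,
    simulate_phenotypes,
    variance_proportions,
)
from pedmix.relatedness import RelationshipStructure
from pedmix.reml import BlockedREML, DesignError
from pedmix.variance import (
    VarianceComponentFit,
    _proportions_delta,
    stepwise_model_selection,
)
import pandas as pd


def _group_structure(n_groups: int, k: int) -> RelationshipStructure:
    ids = tuple(f"I{g}_{j}" for g in range(n_groups) for j in range(k))
    mat = sp.block_diag([np.ones((k, k))] * n_groups).tocsr()
    return RelationshipStructure(ids=ids, matrix=mat, kind="household_share")


class TestREML:
    def test_balanced_oneway_anova_oracle(self):
        """On a balanced one-way design the REML estimates equal the
        classical expected-mean-squares solution."""
        g, k = 60, 5
        rng = np.random.default_rng(42)
        effects = rng.normal(0, np.sqrt(2.0), g)
        y = np.repeat(effects, k) + rng.normal(0, 1.0, g * k)
        struct = _group_structure(g, k)
        df = pd.DataFrame({"id": struct.ids, "y": y})
        spec = MixedModelSpec(response="y", fixed_effects=(),
                              random_components=("group",))
        fit = fit_reml(spec, df, {"group": struct}, tol=1e-10)
        ybar = y.reshape(g, k).mean(axis=1)
        msb = k * np.sum((ybar - ybar.mean()) ** 2) / (g - 1)
        msw = np.sum((y.reshape(g, k) - ybar[:, None]) ** 2) / (g * (k - 1))
        assert fit.estimates["residual"] == pytest.approx(msw, abs=1e-6)
        assert fit.estimates["group"] == pytest.approx((msb - msw) / k, abs=1e-6)

    def test_null_additive_component(self, small_cohort):
        rng = np.random.default_rng(3)
        phe = small_cohort["phenotypes"].copy()
        phe["noise"] = rng.normal(size=len(phe))
        spec = MixedModelSpec(response="noise", random_components=("additive",))
        fit = fit_reml(spec, phe, small_cohort["structures"])
        est, se = fit.estimates["additive"], fit.se["additive"]
        assert est < max(2 * se, 0.1)

    def test_sibship_heritability_recovery(self):
        """200 sibships of four, truth h2 = 0.5: the mean REML estimate
        over 20 seeds recovers the simulated heritability within 0.05."""
        truth = SimulationTruth(var_additive=0.5, var_spouse=0.0,
                                var_residual=0.5)
        design = CohortDesign(n_families=134, generations=2,
                              mean_offspring=4, offspring_dist="constant")
        h2s = []
        for seed in range(20):
            ped = simulate_pedigree(design, seed=100 + seed)
            A = additive_relationship_matrix(ped)
            phe = simulate_phenotypes(ped, truth, seed=200 + seed)
            spec = MixedModelSpec(response="liability_pain",
                                  random_components=("additive",))
            fit = fit_reml(spec, phe, {"additive": A})
            h2s.append(fit.proportions["additive"][0])
        assert abs(np.mean(h2s) - 0.5) < 0.05

    def test_singular_design_rejected(self, small_cohort):
        phe = small_cohort["phenotypes"].copy()
        phe["age_copy"] = phe["age"]
        spec = MixedModelSpec(response="liability_pain",
                              fixed_effects=("age", "age_copy"),
                              random_components=("additive",))
        with pytest.raises(DesignError):
            fit_reml(spec, phe, small_cohort["structures"])

    def test_non_psd_structure_rejected(self):
        y = np.array([1.0, 2.0, 1.5, 0.5])
        X = np.ones((4, 1))
        bad = sp.csr_matrix(-np.eye(4))
        problem = BlockedREML(y, X, [bad, sp.identity(4, format="csr")])
        with pytest.raises(ValueError, match="singular"):
            problem.fit(np.array([0.5, 0.5]))


class TestLRT:
    def test_zero_difference(self):
        r = likelihood_ratio_test(-10.0, -10.0, df=1)
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_chi2_oracle(self):
        r = likelihood_ratio_test(-8.0, -10.0, df=1)
        assert r.statistic == pytest.approx(4.0)
        assert r.p_value == pytest.approx(0.0455, abs=2e-4)

    def test_boundary_mixture(self):
        r = likelihood_ratio_test(-8.0, -10.0, df=1, boundary=True)
        assert r.p_value == pytest.approx(0.0228, abs=2e-4)

    def test_nesting_violation(self):
        with pytest.raises(ValueError, match="not nested"):
            likelihood_ratio_test(-10.0, -9.0, df=1)


class TestDIC:
    def test_constant_chain(self):
        assert dic_from_trace(np.full(10, 7.5), 7.5) == pytest.approx(7.5)

    def test_hand_built_chain(self):
        # mean deviance 11, p_D = 11 - 9 = 2, DIC = 13
        assert dic_from_trace(np.array([10.0, 12.0]), 9.0) == pytest.approx(13.0)

    def test_empty_trace(self):
        with pytest.raises(ValueError):
            dic_from_trace(np.array([]), 0.0)


class TestProportions:
    def test_reported_decomposition_normalizes(self):
        theta = np.array([0.384, 0.187, 0.429])
        props = _proportions_delta(["additive", "spouse", "residual"],
                                   theta, np.zeros((3, 3)))
        assert props["additive"][0] == pytest.approx(0.384)
        assert props["spouse"][0] == pytest.approx(0.187)
        assert props["residual"][0] == pytest.approx(0.429)

    def test_single_component_is_total(self):
        props = _proportions_delta(["residual"], np.array([2.3]), np.eye(1))
        assert props["residual"][0] == pytest.approx(1.0)

    def test_sum_to_one_property(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            q = rng.integers(2, 6)
            theta = rng.uniform(0.01, 3.0, q)
            props = _proportions_delta([f"c{k}" for k in range(q)],
                                       theta, np.diag(rng.uniform(0, 0.1, q)))
            assert sum(p[0] for p in props.values()) == pytest.approx(1.0)

    def test_zero_total_variance(self):
        fit = VarianceComponentFit(
            backend="reml", estimates={"residual": 0.0}, se={"residual": 0.0},
            proportions={}, fixed_effects={}, n_used=10, converged=True,
            theta_cov=np.zeros((1, 1)), component_order=["residual"],
        )
        with pytest.raises(ValueError, match="degenerate"):
            variance_proportions(fit)


class TestStepwiseLRT:
    def test_recovers_spouse_component(self):
        ped = simulate_pedigree(CohortDesign(n_families=250), seed=31)
        st = {"additive": additive_relationship_matrix(ped),
              "spouse": group_covariance_matrix(ped, "spouse_share"),
              "sib": group_covariance_matrix(ped, "sib_share"),
              "household": group_covariance_matrix(ped, "household_share")}
        phe = simulate_phenotypes(ped, SimulationTruth(), seed=32)
        spec = MixedModelSpec(response="liability_pain",
                              random_components=("additive",))
        sel = stepwise_model_selection(spec, phe, st, criterion="LRT")
        assert "spouse" in sel.best_components
        assert len(sel.trace) >= 4  # base + three single-candidate fits

    def test_ties_keep_smaller_model(self, small_cohort):
        """Identical candidate (duplicated structure) cannot beat the
        model it duplicates; the smaller model must win."""
        st = dict(small_cohort["structures"])
        st["spouse_copy"] = st["spouse"]
        phe = small_cohort["phenotypes"]
        spec = MixedModelSpec(response="liability_pain",
                              random_components=("additive", "spouse"))
        sel = stepwise_model_selection(
            spec, phe, st, candidates=("spouse_copy",), criterion="LRT"
        )
        assert sel.best_components == ("additive", "spouse")

    def test_invalid_criterion(self, small_cohort):
        spec = MixedModelSpec(response="liability_pain")
        with pytest.raises(ValueError):
            stepwise_model_selection(spec, small_cohort["phenotypes"],
                                     small_cohort["structures"],
                                     criterion="AIC")
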