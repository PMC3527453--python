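"""Logistic fits, covariate-adjusted ORs and stratum-heterogeneity tests."""

import numpy as np
import pandas as pd
import pytest

from snpcombo import adjusted_or, fit_logistic, interaction_test, two_by_two, odds_ratio_ci
from snpcombo.simulate import (
    PlantedEffect,
    SimulationConfig,
    SiteConfounder,
    simulate_cohort,
    simulate_smoker_contrast,
)


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        fit = fit_logistic(y, pd.DataFrame(index=range(100)))
        assert fit.converged
        assert fit.params["const"] == pytest.approx(np.log(30 / 70), rel=1e-8)

    def test_single_binary_exposure_matches_crude_or(self, planted_cohort,
                                                     session_combination):
        counts = two_by_two(planted_cohort, session_combination)
        crude = odds_ratio_ci(counts)[0]
        or_adj, (lo, hi), fit = adjusted_or(planted_cohort, session_combination,
                                            covariates=())
        assert fit.converged
        assert or_adj == pytest.approx(crude, abs=1e-6)
        assert lo < or_adj < hi

    def test_perfect_separation_is_flagged_not_silent(self):
        y = np.r_[np.ones(6), np.zeros(6)]
        X = pd.DataFrame({"x": y.copy()})
        fit = fit_logistic(y, X)
        assert fit.separation
        assert not fit.converged

    def test_rank_deficiency_rejected(self):
        y = np.r_[np.ones(5), np.zeros(5)]
        X = pd.DataFrame({"x": np.ones(10)})  # collinear with the constant
        with pytest.raises(ValueError, match="rank"):
            fit_logistic(y, X)


class TestAdjustedOR:
    def test_constant_exposure_errors(self, null_cohort):
        from snpcombo import Combination, RiskIndicator

        never = Combination((RiskIndicator("rs11892031", (2,)),))
        cohort = null_cohort.subset(null_cohort.genotypes("rs11892031") != 2)
        with pytest.raises(ValueError, match="constant"):
            adjusted_or(cohort, never, covariates=())

    def test_confounded_crude_or_is_biased_adjusted_or_recovers(self,
                                                                session_combination):
        """A site that both enriches the risk genotypes and raises baseline
        risk biases the crude OR upward; adjusting for site recovers the
        planted conditional OR."""
        cfg = SimulationConfig(
            stratum_sizes={"non": (1500, 1500)},
            planted=[PlantedEffect(session_combination, "all", 2.0)],
            confounder=SiteConfounder(allele_shift=0.2, logit_shift=1.5),
        )
        cohort = simulate_cohort(cfg, seed=31)
        crude = odds_ratio_ci(two_by_two(cohort, session_combination))[0]
        or_adj, (lo, hi), _ = adjusted_or(cohort, session_combination,
                                          covariates=("site",))
        assert lo < 2.0 < hi
        assert abs(np.log(or_adj / 2.0)) < abs(np.log(crude / 2.0))

    def test_independent_covariates_leave_or_near_crude(self, planted_cohort,
                                                        session_combination):
        crude = odds_ratio_ci(two_by_two(planted_cohort, session_combination))[0]
        or_adj, _, _ = adjusted_or(planted_cohort, session_combination,
                                   covariates=("gender", "site"))
        assert or_adj == pytest.approx(crude, rel=0.05)


class TestInteractionTest:
    def test_identical_strata_give_zero_interaction(self, session_combination):
        cfg = SimulationConfig(stratum_sizes={"non": (200, 200)},
                               planted=[PlantedEffect(session_combination, "all", 2.0)])
        cohort = simulate_cohort(cfg, seed=8)
        dup = cohort.table.copy()
        dup["smoking"] = "current"
        dup["id"] = dup["id"] + "_dup"
        from snpcombo import CohortData

        both = CohortData(pd.concat([cohort.table, dup], ignore_index=True))
        res = interaction_test(both, session_combination, strata=("non", "current"))
        assert res.beta_int == pytest.approx(0.0, abs=1e-6)
        assert res.or_by_stratum["non"] == pytest.approx(res.or_by_stratum["current"])

    def test_interaction_equals_log_ratio_of_stratum_ors(self, session_combination):
        cfg = SimulationConfig(
            stratum_sizes={"non": (700, 700), "current": (700, 700)},
            planted=[PlantedEffect(session_combination, "non", 2.0),
                     PlantedEffect(session_combination, "current", 1.0)],
        )
        cohort = simulate_smoker_contrast(cfg, seed=13)
        res = interaction_test(cohort, session_combination, strata=("non", "ever"))
        ratio = res.or_by_stratum["ever"] / res.or_by_stratum["non"]
        assert np.exp(res.beta_int) == pytest.approx(ratio, rel=1e-6)

    def test_overlapping_strata_rejected(self, planted_cohort, session_combination):
        with pytest.raises(ValueError, match="overlap"):
            interaction_test(planted_cohort, session_combination,
                             strata=("current", "ever"))

    def test_type_one_error_calibrated(self, session_combination):
        """Equal planted ORs in both strata: the interaction p-value
        rejects at ~5%; 1,000 replicates give a 2-SE band of +/- 1.4%."""
        hits = 0
        n_rep = 1000
        for r in range(n_rep):
            cfg = SimulationConfig(
                stratum_sizes={"non": (300, 300), "current": (300, 300)},
                planted=[PlantedEffect(session_combination, "all", 1.5)],
            )
            cohort = simulate_cohort(cfg, seed=50_000 + r)
            res = interaction_test(cohort, session_combination, strata=("non", "ever"))
            hits += res.p_int <= 0.05
        rate = hits / n_rep
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) <= 2 * se + 1e-12

    def test_power_against_planted_heterogeneity(self, session_combination):
        """OR 2.0 vs 1.0 across strata at n = 1,500 per arm is detected in
        the majority of replicates."""
        sig = 0
        for r in range(10):
            cfg = SimulationConfig(
                stratum_sizes={"non": (750, 750), "current": (750, 750)},
                planted=[PlantedEffect(session_combination, "non", 2.0),
                         PlantedEffect(session_combination, "current", 1.0)],
            )
            cohort = simulate_smoker_contrast(cfg, seed=900 + r)
            res = interaction_test(cohort, session_combination, strata=("non", "ever"))
            sig += res.p_int < 0.05
        assert sig >= 8
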