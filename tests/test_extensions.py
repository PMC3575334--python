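from dataclasses import replace

import numpy as np
import pytest

from p53lcm import published
from p53lcm.dataset import ConfigError, pattern_table
from p53lcm.extensions import (
    DependenceSpec,
    InconsistentFitError,
    dependence_screen,
    fit_lcm_dependent,
    fit_lcm_outcome,
    fit_lcm_stratified_accuracy,
    likelihood_ratio_test,
    odds_ratio_from_risks,
)
from p53lcm.lcm import fit_lcm
from p53lcm.simulate import GeneratorConfig, generate


class TestOddsRatioFromRisks:
    def test_published_worked_examples(self):
        # risks 0.090 vs 0.050 -> OR 1.879, printed as 1.89
        res = odds_ratio_from_risks(0.090, 0.050)
        assert res.odds_ratio == pytest.approx(1.879, abs=1e-3)
        # risks 0.054 vs 0.050 -> OR 1.085, printed as 1.09 (the study
        # evidently used unrounded risks)
        res2 = odds_ratio_from_risks(0.054, 0.050)
        assert res2.odds_ratio == pytest.approx(1.0846, abs=1e-3)
        assert abs(res2.odds_ratio - 1.09) < 0.015

    def test_equal_risks_give_unity(self):
        for p in (0.01, 0.3, 0.9):
            assert odds_ratio_from_risks(p, p).odds_ratio == pytest.approx(1.0)

    def test_reference_swap_reciprocal(self):
        ab = odds_ratio_from_risks(0.09, 0.05).odds_ratio
        ba = odds_ratio_from_risks(0.05, 0.09).odds_ratio
        assert ab * ba == pytest.approx(1.0)

    def test_boundary_risk_rejected(self):
        with pytest.raises(ValueError, match="boundary"):
            odds_ratio_from_risks(0.0, 0.05)
        with pytest.raises(ValueError, match="boundary"):
            odds_ratio_from_risks(0.1, 1.0)

    def test_ci_contains_point_estimate(self):
        res = odds_ratio_from_risks(0.09, 0.05, 0.015, 0.017)
        assert res.ci_low < res.odds_ratio < res.ci_high
        assert res.ci_high - res.odds_ratio == pytest.approx(res.odds_ratio - res.ci_low)


class TestOutcomeModel:
    def test_without_outcome_reduces_to_model1(self, study_panel, fast_spec3):
        base = fit_lcm(study_panel.without_outcome(), fast_spec3, compute_se=False)
        reduced = fit_lcm_outcome(study_panel.without_outcome(), fast_spec3,
                                  compute_se=False)
        assert reduced.lcm.loglik == pytest.approx(base.loglik, abs=1e-9)
        assert np.abs(reduced.lcm.theta - base.theta).max() < 1e-12
        assert np.abs(reduced.lcm.prevalence - base.prevalence).max() < 1e-12
        assert np.isnan(reduced.rho).all()

    def test_risk_recovery(self, fast_spec3):
        cfg = GeneratorConfig(n_subjects=20000, missing_rates=(0, 0, 0, 0), seed=123)
        panel, _ = generate(cfg)
        fit = fit_lcm_outcome(panel, fast_spec3)
        assert np.abs(fit.rho - np.array(published.SIL_RISKS)).max() < 0.015
        assert (fit.se_rho > 0).all()
        assert fit.odds_ratios[3].odds_ratio == 1.0  # reference class
        or1 = fit.odds_ratios[1]
        assert or1.ci_low < or1.odds_ratio < or1.ci_high

    def test_no_cases_flags_boundary(self, fast_spec3):
        cfg = GeneratorConfig(n_subjects=500, outcome_risks=(0.0, 0.0, 0.0),
                              missing_rates=(0, 0, 0, 0), seed=4)
        panel, _ = generate(cfg)
        with pytest.warns(UserWarning, match="boundary"):
            fit = fit_lcm_outcome(panel, fast_spec3, compute_se=False)
        assert fit.boundary_rho.all()
        assert np.isnan(fit.odds_ratios[1].odds_ratio)


class TestStratifiedAccuracy:
    def test_recovers_stratum_difference(self, fast_spec3, interior_thetas):
        theta_sil = interior_thetas.copy()
        # degrade one cell of DHPLC accuracy among cases by 0.15
        theta_sil[0, 0, 0] -= 0.15
        theta_sil[0, 1, 0] += 0.15
        parts = []
        for thetas, n, outcome in ((interior_thetas, 8000, 1), (theta_sil, 8000, 2)):
            cfg = GeneratorConfig(n_subjects=n, thetas=thetas, outcome_risks=None,
                                  missing_rates=(0, 0, 0, 0), seed=60 + outcome)
            panel, _ = generate(cfg)
            parts.append((panel.calls, np.full(n, outcome)))
        from p53lcm.dataset import TestPanelDataset
        data = TestPanelDataset(
            subject_id=np.arange(16000),
            calls=np.vstack([p[0] for p in parts]),
            test_names=published.TEST_NAMES,
            category_labels=published.CATEGORY_LABELS,
            outcome=np.concatenate([p[1] for p in parts]),
        )
        fit = fit_lcm_stratified_accuracy(data, fast_spec3)
        assert fit.converged
        assert np.abs(fit.theta[1] - interior_thetas).max() < 0.04
        assert np.abs(fit.theta[2] - theta_sil).max() < 0.04

    def test_null_strata_lrt_calibrated(self, fast_spec3, interior_thetas):
        # same accuracy in both strata: stratified model should rarely win
        nonsig = 0
        reps = 15
        for i in range(reps):
            cfg = GeneratorConfig(n_subjects=4000, thetas=interior_thetas,
                                  outcome_risks=(0.3, 0.3, 0.3),
                                  missing_rates=(0, 0, 0, 0), seed=700 + i)
            panel, _ = generate(cfg)
            pooled = fit_lcm(panel.without_outcome(), fast_spec3, compute_se=False)
            strat = fit_lcm_stratified_accuracy(panel, fast_spec3)
            res = likelihood_ratio_test(pooled, strat)
            nonsig += res.p_value >= 0.05
        assert nonsig >= int(0.9 * reps)

    def test_tiny_stratum_completes_unconverged(self, fast_spec3):
        cfg = GeneratorConfig(n_subjects=200, outcome_risks=(0.05, 0.05, 0.05),
                              missing_rates=(0, 0, 0, 0), seed=11)
        panel, _ = generate(cfg)
        assert 0 < (panel.outcome == 2).sum() < 30
        with pytest.warns(UserWarning, match="not identified"):
            fit = fit_lcm_stratified_accuracy(panel, fast_spec3)
        assert fit.converged is False

    def test_requires_outcome_and_nonempty_strata(self, study_panel, fast_spec3):
        with pytest.raises(ConfigError):
            fit_lcm_stratified_accuracy(study_panel.without_outcome(), fast_spec3)


class TestDependence:
    def test_zero_lambda_reduces_to_independence(self, fast_spec3, study_panel):
        from p53lcm.extensions import _dep_class_lik
        from p53lcm.lcm import _class_lik
        patterns, counts = pattern_table(study_panel.without_outcome())
        base = fit_lcm((patterns, counts), fast_spec3, compute_se=False)
        pi, th = np.clip(base.prevalence, 1e-12, None), np.clip(base.theta, 1e-12, None)
        f_ind = _class_lik(patterns, pi, th)
        f_dep = _dep_class_lik(patterns, pi, th, [(0, 1)], np.zeros((1, 3)))
        assert np.abs(f_ind - f_dep).max() < 1e-14
        fit = fit_lcm_dependent((patterns, counts), fast_spec3,
                                DependenceSpec((("DHPLC", "DBH"),)), compute_se=False)
        assert fit.loglik >= base.loglik - 1e-6

    def test_power_against_true_association(self, fast_spec3):
        theta = np.tile(0.85 * np.eye(3) + 0.075 * (1 - np.eye(3)), (4, 1, 1))
        dep = DependenceSpec((("DHPLC", "DBH"),))
        rejections = 0
        reps = 10
        for i in range(reps):
            cfg = GeneratorConfig(n_subjects=5000, thetas=theta, outcome_risks=None,
                                  missing_rates=(0, 0, 0, 0),
                                  dependence={("DHPLC", "DBH"): 1.0}, seed=3000 + i)
            panel, _ = generate(cfg)
            pat = pattern_table(panel)
            null = fit_lcm(pat, fast_spec3, compute_se=False)
            alt = fit_lcm_dependent(pat, fast_spec3, dep, compute_se=False)
            rejections += likelihood_ratio_test(null, alt).p_value < 0.05
        assert rejections >= int(0.8 * reps)

    def test_null_association_within_two_se(self, fast_spec3, interior_thetas):
        dep = DependenceSpec((("DHPLC", "DBH"),))
        covered = 0
        reps = 10
        for i in range(reps):
            cfg = GeneratorConfig(n_subjects=5000, thetas=interior_thetas,
                                  outcome_risks=None, missing_rates=(0, 0, 0, 0),
                                  seed=4000 + i)
            panel, _ = generate(cfg)
            fit = fit_lcm_dependent(pattern_table(panel), fast_spec3, dep)
            lam, se = fit.lambdas.ravel()[0], fit.se_lambda.ravel()[0]
            covered += abs(lam) <= 2 * se
        assert covered >= int(0.9 * reps)

    def test_overlapping_pairs_rejected(self):
        with pytest.raises(ConfigError, match="at most one"):
            DependenceSpec((("DHPLC", "DBH"), ("DBH", "RFLP-1")))
        with pytest.raises(ConfigError):
            DependenceSpec((("DHPLC", "DHPLC"),))

    def test_screen_applies_bonferroni(self, fast_spec3, interior_thetas):
        cfg = GeneratorConfig(n_subjects=1500, thetas=interior_thetas,
                              outcome_risks=None, missing_rates=(0, 0, 0, 0), seed=91)
        panel, _ = generate(cfg)
        df = dependence_screen(panel, fast_spec3)
        assert len(df) == 6
        expected = np.minimum(1.0, df["p_value"] * 6)
        assert df["p_adjusted"].to_numpy() == pytest.approx(expected.to_numpy())


class TestLikelihoodRatioTest:
    def test_identical_fits(self, study_panel, fast_spec3):
        free = fit_lcm(study_panel.without_outcome(), fast_spec3, compute_se=False)
        null = fit_lcm(study_panel.without_outcome(),
                       replace(fast_spec3, constraint="equal_accuracy"),
                       compute_se=False)
        same = likelihood_ratio_test(free, replace(free, n_params=free.n_params + 1))
        assert same.stat == 0.0 and same.p_value == pytest.approx(1.0)
        res = likelihood_ratio_test(null, free)
        assert res.stat > 0 and res.df == 18

    def test_inconsistent_fits_raise(self, study_panel, fast_spec3):
        free = fit_lcm(study_panel.without_outcome(), fast_spec3, compute_se=False)
        worse = replace(free, loglik=free.loglik + 5.0)
        with pytest.raises(InconsistentFitError):
            likelihood_ratio_test(worse, replace(free, n_params=free.n_params + 1))

    def test_equal_accuracy_rejected_under_published_truth(self, fast_spec3):
        # tests generated at the published (unequal) classification matrices
        cfg = GeneratorConfig(n_subjects=5000, missing_rates=(0, 0, 0, 0), seed=20130218)
        panel, _ = generate(cfg)
        data = panel.without_outcome()
        free = fit_lcm(data, fast_spec3, compute_se=False)
        null = fit_lcm(data, replace(fast_spec3, constraint="equal_accuracy"),
                       compute_se=False)
        res = likelihood_ratio_test(null, free)
        assert res.df == 18
        assert res.p_value < 1e-6
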