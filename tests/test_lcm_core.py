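import warnings

import numpy as np
import pytest

from p53lcm import published
from p53lcm.dataset import MISSING, ConfigError, TestPanelDataset, pattern_table
from p53lcm.lcm import (
    EQUAL_ACCURACY,
    EmSettings,
    LcmSpec,
    fit_lcm,
    loglik_dataset,
    posterior_class,
    subject_likelihood,
)
from p53lcm.simulate import GeneratorConfig, generate


def brute_likelihood(calls, pi, thetas):
    """Enumeration oracle: explicit sum over latent classes."""
    total = 0.0
    for c in range(len(pi)):
        term = pi[c]
        for t, r in enumerate(calls):
            if r != MISSING:
                term *= thetas[t][r - 1][c]
        total += term
    return total


def random_params(rng, C, T):
    pi = rng.dirichlet(np.ones(C))
    thetas = rng.dirichlet(np.ones(C), size=(T, C)).swapaxes(1, 2)
    return pi, thetas


class TestSubjectLikelihood:
    def test_identity_theta_single_test(self):
        pi = np.array([0.5, 0.3, 0.2])
        theta = np.eye(3)[None]
        assert subject_likelihood([2], pi, theta) == pytest.approx(0.3)

    def test_uniform_symmetry(self):
        pi = np.full(3, 1 / 3)
        thetas = np.full((4, 3, 3), 1 / 3)
        assert subject_likelihood([1, 3, 2, 2], pi, thetas) == pytest.approx((1 / 3) ** 4)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            C = rng.integers(2, 5)
            T = rng.integers(3, 6)
            pi, thetas = random_params(rng, C, T)
            calls = rng.integers(1, C + 1, size=T)
            calls[rng.random(T) < 0.3] = MISSING
            assert subject_likelihood(calls, pi, thetas) == pytest.approx(
                brute_likelihood(calls, pi, thetas), rel=1e-12
            )

    def test_all_missing_contributes_one(self):
        pi = np.array([0.5, 0.3, 0.2])
        thetas = np.full((4, 3, 3), 1 / 3)
        with pytest.warns(UserWarning, match="all calls missing"):
            assert subject_likelihood([0, 0, 0, 0], pi, thetas) == pytest.approx(1.0)


class TestLoglikDataset:
    def _panel(self, calls, outcome=None):
        calls = np.atleast_2d(calls)
        return TestPanelDataset(
            subject_id=np.arange(len(calls)),
            calls=calls,
            test_names=tuple(f"T{i}" for i in range(calls.shape[1])),
            category_labels=published.CATEGORY_LABELS[: calls.max() if calls.max() > 2 else 3],
            outcome=outcome,
        )

    def test_single_subject_identity(self):
        d = self._panel([[3]])
        ll = loglik_dataset(d, np.array([0.5, 0.3, 0.2]), np.eye(3)[None])
        assert ll == pytest.approx(np.log(0.2))

    def test_duplication_additivity(self):
        rng = np.random.default_rng(5)
        calls = rng.integers(1, 4, size=(7, 4))
        pi, thetas = random_params(rng, 3, 4)
        single = loglik_dataset(self._panel(calls), pi, thetas)
        tripled = loglik_dataset(self._panel(np.tile(calls, (3, 1))), pi, thetas)
        assert tripled == pytest.approx(3 * single, rel=1e-12)

    def test_grouped_equals_subject_level(self):
        rng = np.random.default_rng(6)
        calls = rng.integers(1, 4, size=(50, 4))
        calls[rng.random(calls.shape) < 0.1] = MISSING
        pi, thetas = random_params(rng, 3, 4)
        d = self._panel(calls)
        assert loglik_dataset(pattern_table(d), pi, thetas) == pytest.approx(
            loglik_dataset(d, pi, thetas), rel=1e-12
        )


class TestFitLcm:
    def test_perfect_test_limit(self, spec3):
        cfg = GeneratorConfig(
            n_subjects=2000,
            prevalence=(0.4, 0.45, 0.15),
            thetas=np.tile(np.eye(3), (4, 1, 1)),
            outcome_risks=None,
            missing_rates=(0, 0, 0, 0),
            seed=31,
        )
        panel, x = generate(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # exact-boundary fit
            fit = fit_lcm(panel, spec3)
        assert np.abs(fit.theta - np.tile(np.eye(3), (4, 1, 1))).max() < 0.01
        freq = np.bincount(x - 1, minlength=3) / len(x)
        assert np.abs(fit.prevalence - freq).max() < 1e-6

    def test_hui_walter_two_class_recovery(self):
        sens, spec_ = (0.9, 0.8, 0.95), (0.85, 0.9, 0.8)
        thetas = np.array([[[s, 1 - p], [1 - s, p]] for s, p in zip(sens, spec_)])
        cfg = GeneratorConfig(
            n_subjects=10000, prevalence=(0.3, 0.7), thetas=thetas,
            outcome_risks=None, missing_rates=(0, 0, 0),
            test_names=("A", "B", "C"), category_labels=("pos", "neg"), seed=77,
        )
        panel, _ = generate(cfg)
        fit = fit_lcm(panel, LcmSpec(2, ("A", "B", "C")))
        assert np.abs(fit.theta - thetas).max() < 0.03
        assert fit.prevalence[0] == pytest.approx(0.3, abs=0.03)

    def test_em_monotone_loglik(self, study_panel, fast_spec3):
        fit = fit_lcm(study_panel.without_outcome(), fast_spec3, compute_se=False)
        hist = np.array(fit.ll_history)
        assert (np.diff(hist) >= -1e-8 * (np.abs(hist[:-1]) + 1)).all()

    def test_seed_determinism(self, study_panel, fast_spec3):
        a = fit_lcm(study_panel.without_outcome(), fast_spec3, compute_se=False)
        b = fit_lcm(study_panel.without_outcome(), fast_spec3, compute_se=False)
        assert a.loglik == b.loglik
        assert (a.theta == b.theta).all()

    def test_grouped_fit_equals_subject_fit(self, fast_spec3):
        cfg = GeneratorConfig(n_subjects=800, outcome_risks=None, seed=9)
        panel, _ = generate(cfg)
        f1 = fit_lcm(panel, fast_spec3, compute_se=False)
        f2 = fit_lcm(pattern_table(panel), fast_spec3, compute_se=False)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-9)
        assert np.abs(f1.theta - f2.theta).max() < 1e-9

    def test_equal_accuracy_constraint(self):
        spec = LcmSpec(3, published.TEST_NAMES, constraint=EQUAL_ACCURACY,
                       em=EmSettings(n_restarts=3, seed=1))
        shared = 0.9 * np.eye(3) + 0.05 * (1 - np.eye(3))
        cfg = GeneratorConfig(n_subjects=3000, thetas=np.tile(shared, (4, 1, 1)),
                              outcome_risks=None, missing_rates=(0, 0, 0, 0), seed=3)
        panel, _ = generate(cfg)
        fit = fit_lcm(panel, spec)
        assert spec.n_params == 2 + 6
        assert np.abs(fit.theta[0] - fit.theta[3]).max() == 0
        assert np.abs(fit.theta[0] - shared).max() < 0.03

    def test_too_few_tests_rejected(self):
        with pytest.raises(ConfigError, match="three or more"):
            LcmSpec(3, ("A", "B"))

    def test_unidentified_data_flagged(self, fast_spec3):
        cfg = GeneratorConfig(n_subjects=12, outcome_risks=None, seed=2)
        panel, _ = generate(cfg)
        with pytest.warns(UserWarning, match="not identified"):
            fit = fit_lcm(panel, fast_spec3, compute_se=False)
        assert not fit.identified and not fit.converged

    def test_se_scaling_with_sample_size(self, fast_spec3, interior_thetas):
        ses = {}
        for n in (2000, 8000):
            cfg = GeneratorConfig(n_subjects=n, thetas=interior_thetas,
                                  outcome_risks=None, missing_rates=(0, 0, 0, 0), seed=55)
            panel, _ = generate(cfg)
            fit = fit_lcm(panel, fast_spec3)
            ses[n] = np.concatenate([fit.se_prevalence, fit.se_theta.ravel()])
        mask = (ses[2000] > 0) & (ses[8000] > 0)
        ratio = np.median(ses[8000][mask] / ses[2000][mask])
        assert 0.4 < ratio < 0.6


class TestPosterior:
    def test_identity_certainty(self, study_panel, fast_spec3):
        cfg = GeneratorConfig(n_subjects=500, thetas=np.tile(np.eye(3), (4, 1, 1)),
                              outcome_risks=None, missing_rates=(0, 0, 0, 0), seed=13)
        panel, _ = generate(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_lcm(panel, fast_spec3, compute_se=False)
        post = posterior_class(fit, [2, 2, 2, 2])
        assert post[1] == pytest.approx(1.0, abs=1e-9)

    def test_brute_force_normalized(self, study_panel, fast_spec3):
        fit = fit_lcm(study_panel.without_outcome(), fast_spec3, compute_se=False)
        rng = np.random.default_rng(8)
        for _ in range(10):
            calls = rng.integers(1, 4, size=4)
            calls[rng.random(4) < 0.25] = MISSING
            post = posterior_class(fit, calls)
            ref = np.array([
                fit.prevalence[c] * np.prod([
                    fit.theta[t, r - 1, c] for t, r in enumerate(calls) if r != MISSING
                ])
                for c in range(3)
            ])
            assert post == pytest.approx(ref / ref.sum(), abs=1e-12)
            assert post.sum() == pytest.approx(1.0)

    def test_all_missing_returns_prior(self, study_panel, fast_spec3):
        fit = fit_lcm(study_panel.without_outcome(), fast_spec3, compute_se=False)
        assert posterior_class(fit, [0, 0, 0, 0]) == pytest.approx(fit.prevalence)
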