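"""Variational Laplace, Bayesian model reduction and model comparison.

Linear-Gaussian problems admit closed-form posteriors and evidences, which
serve as independent oracles for the iterative scheme.
"""

import itertools

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

import nvcdcm as nd
from nvcdcm import nvc
from nvcdcm.drives import DriveSignal, EventSchedule
from nvcdcm.haemo import HaemoParameters
from nvcdcm.inference import (
    GaussianDensity,
    bayesian_model_reduction,
    compare_models,
    family_posterior,
    prune_parameters,
    reduce_prior,
    variational_laplace,
)


def linear_problem(seed=0, n=30, p=4, noise_sd=0.5):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    theta = np.array([0.5, -0.3, 0.0, 0.2])[:p]
    y = X @ theta + noise_sd * rng.standard_normal(n)
    return X, y, theta


def conjugate_posterior(X, y, prior_var, noise_prec):
    P = noise_prec * X.T @ X + np.diag(1.0 / prior_var)
    S = np.linalg.inv(P)
    m = S @ (noise_prec * X.T @ y)
    cov_y = X @ np.diag(prior_var) @ X.T + np.eye(len(y)) / noise_prec
    log_ev = multivariate_normal.logpdf(y, np.zeros(len(y)), cov_y)
    return m, S, log_ev


class TestVariationalLaplace:
    def test_scalar_conjugate_posterior_and_evidence(self):
        res = variational_laplace(lambda th: np.array([th[0]]), np.array([1.0]),
                                  [0.0], [1.0], fixed_noise_precision=[1.0])
        assert res.posterior.mean[0] == pytest.approx(0.5, abs=1e-9)
        assert res.posterior.cov[0, 0] == pytest.approx(0.5, abs=1e-9)
        assert res.free_energy == pytest.approx(
            norm.logpdf(1.0, 0.0, np.sqrt(2.0)), abs=1e-6)

    def test_multivariate_linear_matches_conjugate_solution(self):
        X, y, _ = linear_problem()
        prior_var = np.ones(4)
        res = variational_laplace(lambda th: X @ th, y, np.zeros(4), prior_var,
                                  fixed_noise_precision=[4.0])
        m, S, log_ev = conjugate_posterior(X, y, prior_var, 4.0)
        assert np.max(np.abs(res.posterior.mean - m)) < 1e-6
        assert np.max(np.abs(res.posterior.cov - S)) < 1e-6
        assert res.free_energy == pytest.approx(log_ev, abs=1e-6)

    def test_zero_free_parameters_returns_log_likelihood(self):
        y = np.array([0.3, -0.2])
        res = variational_laplace(lambda th: np.zeros(2), y, np.zeros(0),
                                  np.zeros(0), fixed_noise_precision=[1.0])
        expect = norm.logpdf(y, 0, 1).sum()
        assert res.free_energy == pytest.approx(expect, abs=1e-12)

    def test_noise_precision_recovered_from_residuals(self):
        X, y, _ = linear_problem(seed=3, n=400, noise_sd=0.25)
        res = variational_laplace(lambda th: X @ th, y, np.zeros(4),
                                  np.ones(4))
        est_sd = np.exp(-res.noise_log_precision[0] / 2)
        assert est_sd == pytest.approx(0.25, rel=0.15)

    def test_trace_of_accepted_steps_is_nondecreasing(self):
        X, y, _ = linear_problem(seed=4)
        res = variational_laplace(lambda th: np.tanh(X @ th), y, np.zeros(4),
                                  np.ones(4))
        assert np.all(np.diff(res.trace) >= -1e-9)


class TestBayesianModelReduction:
    def test_identical_priors_give_zero_change(self):
        X, y, _ = linear_problem()
        prior_var = np.ones(4)
        res = variational_laplace(lambda th: X @ th, y, np.zeros(4), prior_var,
                                  fixed_noise_precision=[4.0])
        prior = GaussianDensity(np.zeros(4), np.diag(prior_var))
        dF, post = bayesian_model_reduction(prior, res.posterior, prior)
        assert dF == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(post.mean, res.posterior.mean, atol=1e-10)

    def test_reduction_matches_direct_inversion_on_linear_model(self):
        X, y, _ = linear_problem()
        full_var = np.ones(4)
        red_var = full_var.copy()
        red_var[2] = 1e-8
        full = variational_laplace(lambda th: X @ th, y, np.zeros(4), full_var,
                                   fixed_noise_precision=[4.0])
        red = variational_laplace(lambda th: X @ th, y, np.zeros(4), red_var,
                                  fixed_noise_precision=[4.0])
        dF, post = bayesian_model_reduction(
            GaussianDensity(np.zeros(4), np.diag(full_var)), full.posterior,
            GaussianDensity(np.zeros(4), np.diag(red_var)))
        assert dF == pytest.approx(red.free_energy - full.free_energy,
                                   abs=1e-6)
        assert np.max(np.abs(post.mean - red.posterior.mean)) < 1e-6

    def test_shrinking_a_prior_pins_the_posterior_mean_at_zero(self):
        X, y, _ = linear_problem()
        full = variational_laplace(lambda th: X @ th, y, np.zeros(4),
                                   np.ones(4), fixed_noise_precision=[4.0])
        prior = GaussianDensity(np.zeros(4), np.eye(4))
        _, post = bayesian_model_reduction(prior, full.posterior,
                                           reduce_prior(prior, [1]))
        assert abs(post.mean[1]) < 1e-3


class TestModelComparison:
    def test_equal_evidence_gives_uniform_probabilities(self):
        comp = compare_models([1.0, 1.0, 1.0, 1.0])
        assert np.allclose(comp.probabilities, 0.25, atol=1e-12)

    def test_three_nat_difference(self):
        comp = compare_models([0.0, 3.0])
        assert comp.probabilities[0] == pytest.approx(1 / (1 + np.e**3),
                                                      rel=1e-9)
        assert comp.probabilities[1] == pytest.approx(
            np.e**3 / (1 + np.e**3), rel=1e-9)

    def test_shift_invariance(self):
        a = compare_models([1.0, 2.5, -0.3]).probabilities
        b = compare_models([101.0, 102.5, 99.7]).probabilities
        assert np.allclose(a, b, atol=1e-12)

    def test_probabilities_sum_to_one(self):
        comp = compare_models(np.random.default_rng(0).standard_normal(16))
        assert comp.probabilities.sum() == pytest.approx(1.0, abs=1e-12)


class TestFamilyPosterior:
    def test_two_equal_families_with_equal_evidence(self):
        fams = family_posterior([0.0, 0.0, 0.0, 0.0],
                                {"a": [0, 1], "b": [2, 3]})
        assert fams["a"] == pytest.approx(0.5, abs=1e-12)

    def test_size_correction_for_unequal_families(self):
        F = np.zeros(16)
        fams = family_posterior(F, {"a": list(range(8)),
                                    "b": list(range(8, 12)),
                                    "c": list(range(12, 16))})
        for v in fams.values():
            assert v == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_dominant_model_carries_its_family(self):
        F = np.zeros(4)
        F[2] = 20.0
        fams = family_posterior(F, {"a": [0, 1], "b": [2, 3]})
        assert fams["b"] > 0.999


class TestPruning:
    def fitted_linear(self, seed=0):
        X, y, _ = linear_problem(seed=seed, n=60)
        prior_var = np.ones(4)
        res = variational_laplace(lambda th: X @ th, y, np.zeros(4), prior_var,
                                  fixed_noise_precision=[4.0])
        prior = GaussianDensity(np.zeros(4), np.diag(prior_var))
        return res, prior

    def test_no_removal_when_every_parameter_contributes(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((80, 3))
        y = X @ np.array([1.0, -1.0, 0.8]) + 0.1 * rng.standard_normal(80)
        res = variational_laplace(lambda th: X @ th, y, np.zeros(3),
                                  np.ones(3), fixed_noise_precision=[100.0])
        prior = GaussianDensity(np.zeros(3), np.eye(3))
        pr = prune_parameters(res, prior,
                              {f"b{i}": np.array([i]) for i in range(3)})
        assert pr.removed == []
        assert pr.free_energy == pytest.approx(res.free_energy)

    def test_greedy_matches_exhaustive_search_on_linear_toy(self):
        res, prior = self.fitted_linear()
        cands = {f"b{i}": np.array([i]) for i in range(4)}
        pr = prune_parameters(res, prior, cands)
        best = 0.0
        for k in range(1, 5):
            for combo in itertools.combinations(range(4), k):
                rp = reduce_prior(prior, np.array(combo))
                dF, _ = bayesian_model_reduction(prior, res.posterior, rp)
                best = max(best, dF)
        assert pr.free_energy - res.free_energy == pytest.approx(best,
                                                                 abs=1e-3)

    def test_null_coupling_weight_is_pruned_across_replicates(self):
        """BOLD simulated with one null weight: reduction should switch that
        weight off in at least nine of ten seeded replicates."""
        rng0 = np.random.default_rng(42)
        tvals = rng0.standard_normal((1, 2, 4, 4))
        tpl = DriveSignal("pre", ("EV",), ("ss", "sp", "ii", "dp"), tvals,
                          dt=0.1)
        onsets = {"EV": np.sort(rng0.uniform(0, 150, 60))}
        sched = EventSchedule(("EV",), onsets, duration=160.0, tr=2.0, dt=0.1)
        spec = nvc.NVCModelSpec("pre", "exclude", False, "direct")
        beta_true = np.array([0.3, -0.25, 0.2, 0.0])
        hp = HaemoParameters(theta_eta=np.zeros(2), theta_tau_h=np.zeros(2),
                             theta_epsilon=np.zeros(2))
        z = nd.shift_and_sum(tpl, sched)
        zj = nvc.combine_drives(z, tpl.channel_names,
                                nvc.NVCParameters(beta_true), spec, dt=0.1)
        noiseless = nd.predict_bold(zj, hp, dt=0.1, tr=2.0)
        pruned = 0
        for r in range(10):
            rng = np.random.default_rng(500 + r)
            bold = noiseless + (noiseless.std(axis=0) / 10) \
                * rng.standard_normal(noiseless.shape)
            fit = nd.invert_fmri(bold, tpl, sched, spec, max_iter=48)
            prior = GaussianDensity(fit.layout.free_means(),
                                    np.diag(fit.layout.free_variances()))
            bidx = fit.layout.free_indices("beta")
            cands = {f"beta{i}": np.array([bidx[i]]) for i in range(4)}
            pr = prune_parameters(fit.result, prior, cands)
            pruned += "beta3" in pr.removed
        assert pruned >= 9


class TestModelRecovery:
    def test_generating_model_attains_highest_evidence(self, recovery_study):
        """Across twenty seeded replicates of the reduced four-model space,
        the generating model wins the evidence comparison in at least 90%."""
        wins = sum(int(np.argmax(rec["free_energies"])
                       == rec["generating_model"])
                   for rec in recovery_study)
        assert wins >= 18
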