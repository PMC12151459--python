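"""Sparse Bayesian row inference: posterior algebra, evidence, learning."""

import math

import numpy as np
import pytest

from bigsm.core import (
    ALPHA_CAP,
    GRNPosterior,
    RowProblem,
    design_from_data,
    infer_grn,
    infer_row,
    init_beta,
    log_evidence,
    point_estimate,
    posterior_update,
    update_hyperparameters,
)
from bigsm.simulator import SimulationConfig, simulate_dataset, steady_state_response

from conftest import log_evidence_woodbury, posterior_oracle, random_row_problem


class TestDesignFromData:
    def test_transpose_and_negate(self):
        assert np.array_equal(
            design_from_data([[1.0, 2.0], [3.0, 4.0]]), [[-1.0, -3.0], [-2.0, -4.0]]
        )

    def test_zero_and_shape(self):
        assert np.array_equal(design_from_data(np.zeros((3, 6))), np.zeros((6, 3)))
        assert design_from_data(np.ones((3, 6))).shape == (6, 3)


class TestPosteriorUpdate:
    def test_scalar_algebra(self):
        prob = RowProblem(H=[[1.0]], p=[1.0])
        mu, sigma = posterior_update(prob, np.array([1.0]), 1.0)
        assert sigma[0, 0] == pytest.approx(0.5)
        assert mu[0] == pytest.approx(0.5)

    def test_prior_dominated_link_is_pruned(self):
        rng = np.random.default_rng(1)
        prob = RowProblem(rng.normal(size=(6, 3)), rng.normal(size=6))
        alpha = np.array([1.0, 1e12, 1.0])
        mu, sigma = posterior_update(prob, alpha, 1.0)
        assert abs(mu[1]) < 1e-4
        assert sigma[1, 1] < 1e-11

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_joint_conditioning_oracle(self, seed):
        rng = np.random.default_rng(seed)
        prob, _ = random_row_problem(rng, n=5)
        alpha = rng.uniform(0.1, 10.0, size=5)
        beta = rng.uniform(0.5, 5.0)
        mu, sigma = posterior_update(prob, alpha, beta)
        mu_o, sigma_o = posterior_oracle(prob.H, prob.p, alpha, beta)
        np.testing.assert_allclose(mu, mu_o, atol=1e-8)
        np.testing.assert_allclose(sigma, sigma_o, atol=1e-8)

    def test_rejects_nonpositive_hyperparameters(self):
        prob = RowProblem(H=[[1.0]], p=[1.0])
        with pytest.raises(ValueError):
            posterior_update(prob, np.array([-1.0]), 1.0)
        with pytest.raises(ValueError):
            posterior_update(prob, np.array([1.0]), 0.0)


class TestLogEvidence:
    def test_standard_normal_at_zero(self):
        prob = RowProblem(H=[[0.0]], p=[0.0])
        assert log_evidence(prob, np.array([1.0]), 1.0) == pytest.approx(
            -0.5 * math.log(2 * math.pi)
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_dual_form_agreement(self, seed):
        rng = np.random.default_rng(seed)
        prob, _ = random_row_problem(rng, n=4, m=7)
        alpha = rng.uniform(0.1, 100.0, size=4)
        beta = rng.uniform(0.1, 10.0)
        direct = log_evidence(prob, alpha, beta)
        woodbury = log_evidence_woodbury(prob.H, prob.p, alpha, beta)
        assert direct == pytest.approx(woodbury, abs=1e-8)

    def test_zero_response_maximizes_quadratic_term(self):
        rng = np.random.default_rng(3)
        H = rng.normal(size=(4, 3))
        alpha = np.ones(3)
        ev_zero = log_evidence(RowProblem(H, np.zeros(4)), alpha, 1.0)
        ev_nonzero = log_evidence(RowProblem(H, rng.normal(size=4)), alpha, 1.0)
        assert ev_zero >= ev_nonzero


class TestHyperparameterUpdate:
    def test_hand_substitution(self):
        prob = RowProblem(H=[[1.0]], p=[1.0])
        alpha_new, beta_new = update_hyperparameters(
            mu=np.array([0.5]), sigma_diag=np.array([0.5]),
            alpha=np.array([1.0]), problem=prob, beta=1.0,
        )
        # gamma = 1 - 1*0.5 = 0.5 -> alpha = 0.5/0.25 = 2
        assert alpha_new[0] == pytest.approx(2.0)
        # residual (1 - 0.5)^2 = 0.25, denominator 1 - 0.5 = 0.5 -> beta = 2
        assert beta_new == pytest.approx(2.0)

    def test_zero_mean_link_jumps_to_cap(self):
        prob = RowProblem(H=[[1.0, 0.0]], p=[1.0])
        alpha_new, _ = update_hyperparameters(
            mu=np.array([0.5, 0.0]), sigma_diag=np.array([0.5, 0.5]),
            alpha=np.array([1.0, 1.0]), problem=prob, beta=1.0,
        )
        assert alpha_new[1] == ALPHA_CAP

    def test_nonpositive_denominator_keeps_beta(self, caplog):
        prob = RowProblem(H=[[1.0]], p=[1.0])
        with caplog.at_level("WARNING", logger="bigsm.core"):
            _, beta_new = update_hyperparameters(
                mu=np.array([1.0]), sigma_diag=np.array([0.0]),
                alpha=np.array([1.0]), problem=prob, beta=7.5,
            )
        assert beta_new == 7.5
        assert any("beta update skipped" in r.message for r in caplog.records)

    @pytest.mark.parametrize("seed", range(5))
    def test_fixed_point_is_evidence_stationary(self, seed):
        rng = np.random.default_rng(seed)
        prob, _ = random_row_problem(rng, n=6, m=12, noise=0.2)
        post = infer_row(prob, max_iter=500, tol=1e-12)
        theta = np.concatenate([post.alpha, [post.beta]])
        h = 1e-5
        for k in range(theta.size):
            up, down = theta.copy(), theta.copy()
            up[k] *= math.exp(h)
            down[k] *= math.exp(-h)
            g = (
                log_evidence(prob, up[:-1], up[-1])
                - log_evidence(prob, down[:-1], down[-1])
            ) / (2 * h)
            assert abs(g) < 1e-4  # derivative wrt log-parameter


class TestInferRow:
    def test_noiseless_exact_recovery(self):
        rng = np.random.default_rng(2)
        n = 8
        H = rng.normal(size=(n, n))
        a_true = np.zeros(n)
        a_true[[1, 4]] = [1.5, -0.7]
        post = infer_row(RowProblem(H, H @ a_true), max_iter=35)
        assert np.linalg.norm(post.mu - a_true) / np.linalg.norm(a_true) < 1e-3

    def test_single_iteration_contract(self):
        rng = np.random.default_rng(5)
        prob, _ = random_row_problem(rng, n=4)
        post = infer_row(prob, max_iter=1)
        beta0 = init_beta(prob.p)
        mu0, sigma0 = posterior_update(prob, np.ones(4), beta0)
        alpha1, beta1 = update_hyperparameters(
            mu0, np.diag(sigma0), np.ones(4), prob, beta=beta0
        )
        np.testing.assert_array_equal(post.mu, mu0)
        np.testing.assert_array_equal(post.alpha, alpha1)
        assert post.beta == beta1
        assert post.iterations_run == 1

    def test_evidence_ascends_on_random_problems(self):
        rises = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            prob, _ = random_row_problem(rng, n=6, m=10, noise=0.3)
            post = infer_row(prob, max_iter=35)
            assert post.evidence_trace[-1] >= post.evidence_trace[0]
            rises += post.evidence_trace[-1] > post.evidence_trace[0]
        assert rises > 40  # learning actually moves on most problems

    def test_early_stop_tolerance(self):
        rng = np.random.default_rng(8)
        prob, _ = random_row_problem(rng, n=5, m=10, noise=0.2)
        post = infer_row(prob, max_iter=500, tol=1e-10)
        assert post.iterations_run < 500


class TestInferGRN:
    def test_identity_system(self):
        post = infer_grn(-np.eye(3), -np.eye(3))
        assert np.max(np.abs(post.mean + np.eye(3))) < 1e-3

    def test_noiseless_simulator_recovery(self):
        cfg = SimulationConfig(n_genes=10, snr=math.inf, seed=4)
        net, design, data = simulate_dataset(cfg)
        post = infer_grn(data.Y, design.values)
        corr = np.corrcoef(post.mean.ravel(), net.weights.ravel())[0, 1]
        assert corr > 0.999

    def test_row_decoupling_under_permutation(self):
        cfg = SimulationConfig(n_genes=8, snr=1.0, seed=6)
        _, design, data = simulate_dataset(cfg)
        perm = np.random.default_rng(0).permutation(8)
        base = infer_grn(data.Y, design.values)
        permuted = infer_grn(data.Y, design.values[perm])
        np.testing.assert_array_equal(permuted.mean, base.mean[perm])

    def test_shape_mismatch_names_both_shapes(self):
        with pytest.raises(ValueError, match=r"\(3, 3\).*\(3, 4\)"):
            infer_grn(np.zeros((3, 3)), np.zeros((3, 4)))

    def test_determinism_bit_identical(self):
        cfg = SimulationConfig(n_genes=8, snr=0.1, seed=11)
        _, design, data = simulate_dataset(cfg)
        a = infer_grn(data.Y, design.values)
        b = infer_grn(data.Y, design.values)
        assert a.mean.tobytes() == b.mean.tobytes()
        assert a.variance.tobytes() == b.variance.tobytes()

    def test_posterior_variance_positive(self):
        cfg = SimulationConfig(n_genes=8, snr=1.0, seed=2)
        _, design, data = simulate_dataset(cfg)
        post = infer_grn(data.Y, design.values)
        assert np.all(post.variance > 0)


class TestPointEstimate:
    def test_mean_accessor(self):
        mean = np.arange(9.0).reshape(3, 3)
        post = GRNPosterior(
            mean=mean, variance=np.ones((3, 3)), row_alphas=np.ones((3, 3)),
            row_betas=np.ones(3), iterations_run=np.ones(3, int), max_iter=35,
        )
        assert np.array_equal(point_estimate(post).weights, mean)

    def test_zero_posterior_gives_zero_network(self):
        post = GRNPosterior(
            mean=np.zeros((2, 2)), variance=np.ones((2, 2)), row_alphas=np.ones((2, 2)),
            row_betas=np.ones(2), iterations_run=np.ones(2, int), max_iter=35,
        )
        assert np.count_nonzero(point_estimate(post).weights) == 0

    def test_sharp_posteriors_mark_true_zeros(self):
        # low-variance posteriors should concentrate on the true non-links
        cfg = SimulationConfig(n_genes=20, snr=0.1, seed=9)
        net, design, data = simulate_dataset(cfg)
        post = infer_grn(data.Y, design.values)
        off = ~np.eye(20, dtype=bool)
        sharp = (post.variance < np.quantile(post.variance[off], 0.25)) & off
        frac_true_zero = np.mean(net.weights[sharp] == 0.0)
        assert frac_true_zero > 0.9
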