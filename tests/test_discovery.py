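"""Discovery-phase EM: E/M steps, inductive conditional estimation, BIC over H."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import multivariate_normal

from damda import DataMatrix, EMControl, count_params, em_discovery, select_H
from damda.discovery import (
    AssemblyError,
    SingularScatterError,
    assemble_known,
    conditional_estimates,
    e_step,
    marginal_extras,
    regularize_scatter,
    scatter_partition,
    update_hidden,
    update_props,
)
from damda.model_core import Responsibilities

from conftest import discovery_instance, random_spd, toy_classifier


# ---------------------------------------------------------------------------
# E-step and simple M-step pieces


class TestEStep:
    def test_single_class_all_ones(self, rng):
        learned = toy_classifier([[0.0]], [np.eye(1)], [1.0])
        fit = em_discovery(DataMatrix(rng.normal(size=(12, 1)), ["v0"]), learned, H=0)
        np.testing.assert_allclose(fit.responsibilities.probs, 1.0)

    def test_symmetric_midpoint(self):
        learned = toy_classifier([[-2.0], [2.0]], [np.eye(1)] * 2, [0.5, 0.5])
        from damda.discovery import align_test
        from damda import init as init_mod

        test = DataMatrix([[0.0], [-2.0], [2.0]], ["v0"])
        aligned, _ = align_test(test, learned)
        am = init_mod.initialize(aligned, learned, H=0)
        # replace proportions with the learned ones for exact symmetry
        am.props = np.array([0.5, 0.5])
        resp = e_step(am, test)
        np.testing.assert_allclose(resp.probs[0], [0.5, 0.5], atol=1e-12)

    def test_three_class_hand_computation(self):
        mus, tau = [-2.0, 0.0, 2.0], [0.2, 0.5, 0.3]
        learned = toy_classifier([[m] for m in mus], [np.eye(1)] * 3, tau)
        from damda import init as init_mod
        from damda.discovery import align_test

        y = 0.7
        test = DataMatrix([[y], [5.0], [-5.0]], ["v0"])
        aligned, _ = align_test(test, learned)
        am = init_mod.initialize(aligned, learned, H=0)
        am.props = np.array(tau)
        resp = e_step(am, test)
        dens = [t * math.exp(-0.5 * (y - m) ** 2) for m, t in zip(mus, tau)]
        np.testing.assert_allclose(resp.probs[0], np.array(dens) / sum(dens), atol=1e-12)


class TestWeightedUpdates:
    def test_hard_weights_recover_group_mle(self, rng):
        Y = rng.normal(size=(30, 3))
        t = np.zeros((30, 2))
        t[:12, 0] = 1
        t[12:, 1] = 1
        g = update_hidden(Y, t, 1)
        rows = Y[12:]
        np.testing.assert_allclose(g.mean, rows.mean(axis=0), atol=1e-12)
        rc = rows - rows.mean(axis=0)
        np.testing.assert_allclose(g.cov, rc.T @ rc / rows.shape[0], atol=1e-12)

    def test_equal_weights_recover_global_mle(self, rng):
        Y = rng.normal(size=(25, 2))
        t = np.full((25, 1), 1.0)
        g = update_hidden(Y, 0.37 * t, 0)  # scale-free in the weights
        np.testing.assert_allclose(g.mean, Y.mean(axis=0), atol=1e-12)
        rc = Y - Y.mean(axis=0)
        np.testing.assert_allclose(g.cov, rc.T @ rc / 25, atol=1e-12)

    def test_soft_weights_match_moment_oracle(self, rng):
        Y = rng.normal(size=(30, 3))
        w = rng.uniform(0.05, 1.0, size=30)
        t = np.column_stack([w, 1 - w])
        g = update_hidden(Y, t, 0)
        mean = sum(w[i] * Y[i] for i in range(30)) / w.sum()
        cov = sum(w[i] * np.outer(Y[i] - mean, Y[i] - mean) for i in range(30)) / w.sum()
        np.testing.assert_allclose(g.mean, mean, atol=1e-10)
        np.testing.assert_allclose(g.cov, cov, atol=1e-10)

    def test_props_from_hard_counts(self):
        t = np.zeros((10, 2))
        t[:3, 0] = 1
        t[3:, 1] = 1
        np.testing.assert_allclose(update_props(t), [0.3, 0.7])

    def test_props_are_column_means(self, rng):
        t = rng.dirichlet(np.ones(4), size=50)
        np.testing.assert_allclose(update_props(t), t.mean(axis=0), atol=1e-12)


class TestScatterPartition:
    def test_single_point_zero_scatter(self):
        Y = np.arange(12.0).reshape(4, 3)
        t = np.array([0.0, 1.0, 0.0, 0.0])
        sp = scatter_partition(Y, t, 2)
        assert np.all(sp.assembled() == 0)
        np.testing.assert_allclose(sp.ybar, Y[1])

    def test_q_zero_full_scatter(self, rng):
        Y = rng.normal(size=(15, 3))
        w = rng.uniform(0.1, 1, 15)
        sp = scatter_partition(Y, w, 3)
        assert sp.V.shape == (3, 0) and sp.U.shape == (0, 0)
        ybar = (w @ Y) / w.sum()
        O = sum(w[i] * np.outer(Y[i] - ybar, Y[i] - ybar) for i in range(15))
        np.testing.assert_allclose(sp.W, O, atol=1e-10)

    def test_blocks_match_outer_product_oracle(self, rng):
        Y = rng.normal(size=(20, 4))
        w = rng.uniform(0, 1, 20)
        sp = scatter_partition(Y, w, 2)
        ybar = (w @ Y) / w.sum()
        O = sum(w[i] * np.outer(Y[i] - ybar, Y[i] - ybar) for i in range(20))
        np.testing.assert_allclose(sp.assembled(), O, atol=1e-10)


# ---------------------------------------------------------------------------
# inductive conditional estimation


def _printed_formulas(sp, sigma_bar):
    """The closed forms exactly as printed, evaluated term by term."""
    Sinv = np.linalg.inv(sigma_bar)
    C = np.linalg.inv(Sinv @ sp.W @ Sinv) @ (Sinv @ sp.V)
    E = (C.T @ Sinv @ sp.W @ Sinv @ C - 2 * sp.V.T @ Sinv @ C + sp.U) / sp.n_eff
    return C, E


def _expected_conditional_loglik(Yp, Yq, t, mu_bar, sigma_bar, C, E, mu_q):
    """Weighted conditional log-likelihood term of the complete data."""
    Sinv = np.linalg.inv(sigma_bar)
    m = mu_q + (Yp - mu_bar) @ Sinv @ C
    mvn = multivariate_normal(np.zeros(E.shape[0]), E)
    return float(np.sum(t * mvn.logpdf(Yq - m)))


class TestConditionalEstimates:
    def test_matches_printed_formulas(self, rng):
        for _ in range(20):
            P, Q = int(rng.integers(1, 4)), int(rng.integers(1, 4))
            Y = rng.normal(size=(25, P + Q))
            w = rng.uniform(0.2, 1, 25)
            sp = scatter_partition(Y, w, P)
            sigma_bar = random_spd(rng, P)
            C1, E1 = conditional_estimates(sp, sigma_bar)
            C2, E2 = _printed_formulas(sp, sigma_bar)
            np.testing.assert_allclose(C1, C2, atol=1e-8)
            np.testing.assert_allclose(E1, E2, atol=1e-8)

    def test_uncorrelated_blocks(self, rng):
        sp = scatter_partition(rng.normal(size=(20, 3)), np.ones(20), 2)
        sp.V[:] = 0.0
        C, E = conditional_estimates(sp, random_spd(rng, 2))
        assert np.all(C == 0)
        np.testing.assert_allclose(E, sp.U / sp.n_k, atol=1e-12)

    def test_unconstrained_marginal_reduces_to_sample_split(self, rng):
        Y = rng.normal(size=(30, 4))
        w = rng.uniform(0.2, 1, 30)
        sp = scatter_partition(Y, w, 2)
        sigma_bar = sp.W / sp.n_k
        C, E = conditional_estimates(sp, sigma_bar)
        np.testing.assert_allclose(C, sp.V / sp.n_k, atol=1e-8)
        schur = (sp.U - sp.V.T @ np.linalg.solve(sp.W, sp.V)) / sp.n_k
        np.testing.assert_allclose(E, schur, atol=1e-8)

    def test_singular_scatter_advises_regularization(self, rng):
        Y = rng.normal(size=(2, 3))  # N < P+1: singular W
        sp = scatter_partition(np.vstack([Y, Y]), np.ones(4), 2)
        with pytest.raises(SingularScatterError, match="regulariz"):
            conditional_estimates(sp, np.eye(2))

    def test_closed_form_maximizes_objective_1d(self, rng):
        # P = Q = 1 toy: compare with a direct numerical maximizer
        Y = rng.normal(size=(12, 2))
        t = rng.uniform(0.2, 1, 12)
        sp = scatter_partition(Y, t, 1)
        sigma_bar = np.array([[1.3]])
        mu_bar = np.array([0.2])
        C, E = conditional_estimates(sp, sigma_bar)
        mu_q, _ = marginal_extras(sp, sigma_bar, mu_bar, C, E)
        obj_closed = _expected_conditional_loglik(
            Y[:, :1], Y[:, 1:], t, mu_bar, sigma_bar, C, E, mu_q
        )

        def neg(v):
            c, loge, m = v
            return -_expected_conditional_loglik(
                Y[:, :1], Y[:, 1:], t, mu_bar, sigma_bar,
                np.array([[c]]), np.array([[math.exp(loge)]]), np.array([m]),
            )

        res = minimize(neg, x0=[0.0, 0.0, float(Y[:, 1].mean())], method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
        assert -res.fun - obj_closed < 1e-4


class TestMarginalExtras:
    def test_zero_cross_gives_weighted_mean(self, rng):
        Y = rng.normal(size=(20, 3))
        w = rng.uniform(0.2, 1, 20)
        sp = scatter_partition(Y, w, 2)
        E = random_spd(rng, 1)
        mu_q, sigma_q = marginal_extras(sp, np.eye(2), np.zeros(2), np.zeros((2, 1)), E)
        np.testing.assert_allclose(mu_q, [(w @ Y[:, 2]) / w.sum()], atol=1e-10)
        np.testing.assert_allclose(sigma_q, E, atol=1e-12)

    def test_unconstrained_marginal_full_mle(self, rng):
        Y = rng.normal(size=(30, 4))
        w = rng.uniform(0.2, 1, 30)
        sp = scatter_partition(Y, w, 2)
        sigma_bar = sp.W / sp.n_k
        C, E = conditional_estimates(sp, sigma_bar)
        mu_q, sigma_q = marginal_extras(sp, sigma_bar, sp.ybar[:2], C, E)
        np.testing.assert_allclose(sigma_q, sp.U / sp.n_k, atol=1e-8)
        np.testing.assert_allclose(mu_q, sp.ybar[2:], atol=1e-8)


class TestAssembleKnown:
    def test_q_zero_reduction(self, rng):
        mu, cov = rng.normal(size=2), random_spd(rng, 2)
        g = assemble_known(mu, cov, np.empty(0), np.empty((2, 0)), np.empty((0, 0)))
        np.testing.assert_array_equal(g.mean, mu)
        np.testing.assert_array_equal(g.cov, cov)

    def test_unconstrained_reduces_to_weighted_mle(self, rng):
        Y = rng.normal(size=(30, 4))
        w = rng.uniform(0.2, 1, 30)
        sp = scatter_partition(Y, w, 2)
        sigma_bar = sp.W / sp.n_k
        C, E = conditional_estimates(sp, sigma_bar)
        mu_q, sigma_q = marginal_extras(sp, sigma_bar, sp.ybar[:2], C, E)
        g = assemble_known(sp.ybar[:2], sigma_bar, mu_q, C, sigma_q)
        np.testing.assert_allclose(g.cov, sp.assembled() / sp.n_k, atol=1e-8)

    def test_assembled_covariance_is_pd(self, rng):
        for _ in range(10):
            Y = rng.normal(size=(40, 5))
            w = rng.uniform(0.1, 1, 40)
            sp = scatter_partition(Y, w, 3)
            sigma_bar = random_spd(rng, 3)
            C, E = conditional_estimates(sp, sigma_bar)
            mu_q, sigma_q = marginal_extras(sp, sigma_bar, sp.ybar[:3], C, E)
            g = assemble_known(sp.ybar[:3], sigma_bar, mu_q, C, sigma_q)
            assert np.linalg.eigvalsh(g.cov).min() > 0

    def test_broken_schur_raises(self, rng):
        sigma_bar = np.eye(2)
        with pytest.raises(AssemblyError):
            assemble_known(
                np.zeros(2), sigma_bar, np.zeros(1),
                np.array([[5.0], [0.0]]), np.array([[1.0]]),
            )


class TestRegularization:
    def test_nu_zero_is_identity(self, rng):
        sp = scatter_partition(rng.normal(size=(10, 3)), np.ones(10), 2)
        sp2 = regularize_scatter(sp, np.eye(3), 0.0)
        np.testing.assert_array_equal(sp2.assembled(), sp.assembled())
        assert sp2.n_eff == sp.n_k

    def test_singular_scatter_becomes_pd(self, rng):
        Y = rng.normal(size=(3, 5))  # N < R: singular scatter
        sp = scatter_partition(Y, np.ones(3), 3)
        psi = np.diag(np.ones(5))
        sp2 = regularize_scatter(sp, psi, nu=7.0)
        assert np.linalg.eigvalsh(sp2.assembled()).min() > 0

    def test_negative_nu_rejected(self, rng):
        sp = scatter_partition(rng.normal(size=(5, 2)), np.ones(5), 1)
        with pytest.raises(ValueError):
            regularize_scatter(sp, np.eye(2), -1.0)

    def test_large_nu_shrinks_to_prior(self, rng):
        Y = rng.normal(size=(30, 3))
        sp = scatter_partition(Y, np.ones(30), 2)
        psi = np.diag([2.0, 3.0, 4.0])
        sp2 = regularize_scatter(sp, psi, nu=1e6)
        C, E = conditional_estimates(sp2, np.eye(2))
        np.testing.assert_allclose(C, 0.0, atol=1e-4)
        np.testing.assert_allclose(E, psi[2:, 2:], rtol=1e-3)


# ---------------------------------------------------------------------------
# parameter count and EM driver


class TestCountParams:
    def test_printed_examples(self):
        assert count_params(2, 1, 2, 1) == 19
        assert count_params(1, 1, 1, 0) == 3

    def test_reduces_to_props_only(self):
        for K in range(1, 5):
            assert count_params(K, 0, 3, 0) == K - 1

    def test_independent_re_evaluation(self):
        from math import comb

        for K in range(1, 5):
            for H in range(0, 4):
                for P in range(1, 6):
                    for Q in range(0, 5):
                        R = P + Q
                        expected = (
                            (H + K - 1) + 2 * H * R + H * comb(R, 2)
                            + 2 * K * Q + K * P * Q + K * comb(Q, 2)
                        )
                        assert count_params(K, H, P, Q) == expected


class TestEMDiscovery:
    def test_h0_q0_only_props_move(self, rng):
        learned, test, _ = discovery_instance(rng, K=2, H=0, P=3, Q=0, N=120)
        fit = em_discovery(test, learned, H=0)
        m = fit.model
        assert m.n_hidden == 0 and m.q_count == 0
        # learned Gaussians untouched, bit for bit
        np.testing.assert_array_equal(m.learned_means, learned.means())
        np.testing.assert_array_equal(m.learned_covs, learned.covs())
        assert len(fit.loglik_trace) >= 1
        diffs = np.diff(fit.loglik_trace)
        assert np.all(diffs >= -1e-8)

    def test_amda_reduction_q0_h1(self, rng):
        learned, test, _ = discovery_instance(rng, K=2, H=1, P=3, Q=0, N=200)
        fit = em_discovery(test, learned, H=1)
        np.testing.assert_array_equal(fit.model.learned_means, learned.means())
        np.testing.assert_array_equal(fit.model.learned_covs, learned.covs())
        assert fit.model.n_hidden == 1

    def test_loglik_trace_monotone_random_instances(self, rng):
        for _ in range(8):
            K = int(rng.integers(1, 4))
            H = int(rng.integers(0, 3))
            P = int(rng.integers(1, 5))
            Q = int(rng.integers(0, 4))
            N = int(rng.integers(60, 300))
            learned, test, _ = discovery_instance(rng, K, H, P, Q, N)
            fit = em_discovery(test, learned, H, ctrl=EMControl(regularize="auto"))
            assert np.all(np.diff(fit.loglik_trace) >= -1e-8)
            assert fit.converged

    def test_learned_blocks_bit_identical_q_positive(self, rng):
        learned, test, _ = discovery_instance(rng, K=2, H=1, P=3, Q=2, N=250)
        fit = em_discovery(test, learned, H=1)
        np.testing.assert_array_equal(fit.model.learned_means, learned.means())
        np.testing.assert_array_equal(fit.model.learned_covs, learned.covs())
        # and the assembled covariances embed them exactly
        for k in range(2):
            np.testing.assert_array_equal(
                fit.model.known_cov(k)[:3, :3], learned.covs()[k]
            )


class TestPropUpdateOptions:
    def test_renormalize_keeps_learned_ratios(self, rng):
        learned, test, _ = discovery_instance(rng, K=2, H=1, P=3, Q=0, N=250)
        fit = em_discovery(
            test, learned, H=1, ctrl=EMControl(prop_update="renormalize")
        )
        tau = fit.model.props
        # known-class proportions keep the learned ratio exactly
        ratio_learned = learned.props[0] / learned.props[1]
        assert tau[0] / tau[1] == pytest.approx(ratio_learned, rel=1e-10)
        assert tau.sum() == pytest.approx(1.0, abs=1e-10)

    def test_invalid_option_rejected(self):
        with pytest.raises(ValueError):
            EMControl(prop_update="nonsense")


class TestSelectH:
    def test_singleton_range_forced(self, rng):
        learned, test, _ = discovery_instance(rng, K=2, H=1, P=3, Q=1, N=200)
        res = select_H(test, learned, EMControl(h_range=(2,)))
        assert res.h_star == 2

    def test_bic_table_complete(self, rng):
        learned, test, _ = discovery_instance(rng, K=2, H=1, P=3, Q=1, N=250)
        res = select_H(test, learned, EMControl(h_range=(0, 1, 2)))
        assert set(res.bic_table) == {0, 1, 2}
        assert res.bic_table[res.h_star] == max(
            b for b in res.bic_table.values() if b is not None
        )
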