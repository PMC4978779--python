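import numpy as np
import pytest

import pofm
from pofm import (
    ModelSpec,
    OrdinalMatrix,
    Parameters,
    Posteriors,
    complete_loglik,
    e_step,
    equal_probability_cutpoints,
    fit,
    incomplete_loglik,
    incomplete_loglik_bicluster,
    incomplete_loglik_row_mixture,
    m_step,
)
from pofm.inference import CapacityError, _empirical_cutpoints
from pofm.po_core import InvalidSpecError
from pofm.simulate import SimulationConfig, generate_dataset

from oracles import loglik_joint_enumeration, loglik_row_enumeration


def _random_instance(rng, n, p, q, R, C):
    data = OrdinalMatrix(rng.integers(1, q + 1, size=(n, p)), q=q)
    mu = np.sort(rng.normal(size=q - 1) * 2)
    mu += np.arange(q - 1) * 1e-3
    alpha = np.concatenate([[0.0], rng.normal(size=R - 1)])
    beta = np.concatenate([[0.0], rng.normal(size=C - 1)])
    pi = rng.dirichlet(np.ones(R))
    kappa = rng.dirichlet(np.ones(C))
    spec = ModelSpec(
        "clustered" if R > 1 else "single",
        "clustered" if C > 1 else "single",
        R=R if R > 1 else None, C=C if C > 1 else None,
    )
    params = Parameters(mu=mu, alpha=alpha, beta=beta,
                        pi=pi if R > 1 else None, kappa=kappa if C > 1 else None)
    return data, spec, params


class TestIncompleteLikelihood:
    def test_row_mixture_matches_assignment_enumeration(self, rng):
        """Marginalising rows by log-sum-exp equals brute-force enumeration."""
        for _ in range(20):
            n, p, q, R = rng.integers(2, 5), rng.integers(2, 4), rng.integers(2, 4), 2
            data, spec, params = _random_instance(rng, n, p, q, R, 1)
            got = incomplete_loglik_row_mixture(data, params, spec)
            want = loglik_row_enumeration(
                data.values, q, params.mu, params.alpha, np.zeros(p, int),
                params.beta, params.pi,
            )
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_degenerate_mixture_reduces_to_plain_loglik(self, small_row_mixture):
        data, spec, params = small_row_mixture
        solo = Parameters(mu=params.mu, alpha=np.zeros(1), beta=np.zeros(1))
        plain, _ = incomplete_loglik(data, solo, ModelSpec())
        degenerate = Parameters(mu=params.mu, alpha=np.array([0.0, 1.2]),
                                beta=np.zeros(1), pi=np.array([1.0, 0.0]))
        got = incomplete_loglik_row_mixture(data, degenerate, spec)
        np.testing.assert_allclose(got, plain, atol=1e-9)

    def test_bicluster_exact_matches_joint_enumeration(self, rng):
        """Summing over column partitions only (with rows marginalised inside)
        reproduces the full joint row x column partition sum."""
        for _ in range(20):
            n, p = rng.integers(2, 5), rng.integers(2, 4)
            q = rng.integers(2, 4)
            data, spec, params = _random_instance(rng, n, p, q, 2, 2)
            got, flag = incomplete_loglik_bicluster(data, params, spec, "exact")
            want = loglik_joint_enumeration(
                data.values, q, params.mu, params.alpha, params.beta, params.pi, params.kappa
            )
            assert flag == "exact"
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_variational_bound_below_exact(self, small_bicluster):
        data, spec, params = small_bicluster
        exact, _ = incomplete_loglik_bicluster(data, params, spec, "exact")
        post = e_step(data, params, spec)
        bound, flag = incomplete_loglik_bicluster(data, params, spec, "bound", post)
        assert flag == "variational_bound"
        assert bound <= exact + 1e-6

    def test_exact_enumeration_guard(self):
        data = OrdinalMatrix(np.ones((2, 30), dtype=int), q=2)
        spec = ModelSpec("clustered", "clustered", R=2, C=3)
        params = Parameters(
            mu=np.zeros(1), alpha=np.zeros(2), beta=np.zeros(3),
            pi=np.full(2, 0.5), kappa=np.full(3, 1 / 3),
        )
        with pytest.raises(CapacityError):
            incomplete_loglik_bicluster(data, params, spec, "exact")


class TestCompleteLikelihood:
    def test_hard_posteriors_give_classified_loglik(self, small_bicluster):
        data, spec, params = small_bicluster
        rg = np.array([0, 0, 1, 1])
        cg = np.array([0, 1, 1])
        post = Posteriors(
            zhat=(rg[:, None] == np.arange(2)).astype(float),
            xhat=(cg[:, None] == np.arange(2)).astype(float),
        )
        got = complete_loglik(data, params, spec, post)
        logth = np.log([
            [pofm.cell_probabilities(params.mu, params.alpha[r] + params.beta[c]) for c in range(2)]
            for r in range(2)
        ])
        want = sum(
            logth[rg[i], cg[j], data.values[i, j] - 1]
            for i in range(data.n) for j in range(data.p)
        )
        want += np.log(params.pi[rg]).sum() + np.log(params.kappa[cg]).sum()
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_entropy_identity_one_mode(self, small_row_mixture):
        """l - l_c equals the membership entropy at the exact posterior."""
        data, spec, params = small_row_mixture
        post = e_step(data, params, spec)
        ll = incomplete_loglik_row_mixture(data, params, spec)
        lc = complete_loglik(data, params, spec, post)
        entropy = -(post.zhat * np.log(post.zhat)).sum()
        np.testing.assert_allclose(ll - lc, entropy, atol=1e-8)

    def test_invalid_posteriors_rejected(self, small_row_mixture):
        data, spec, params = small_row_mixture
        bad = Posteriors(zhat=np.full((3, 2), 0.7))
        with pytest.raises(InvalidSpecError):
            complete_loglik(data, params, spec, bad)


class TestEStep:
    def test_single_component_membership_is_degenerate(self):
        """R=1: every row belongs to the one cluster with probability 1."""
        from pofm.inference import _memberships
        data = OrdinalMatrix(np.array([[1, 2], [2, 1]]), q=2)
        spec = ModelSpec("clustered", "single", R=1)
        Z, X = _memberships(data, spec, None)
        np.testing.assert_array_equal(Z, np.ones((2, 1)))
        np.testing.assert_array_equal(X, np.ones((2, 1)))

    def test_matches_bayes_rule_by_hand(self):
        """1x2 matrix, two components: posterior from two-term arithmetic."""
        data = OrdinalMatrix(np.array([[1, 2]]), q=2)
        spec = ModelSpec("clustered", "single", R=2)
        params = Parameters(mu=np.array([0.5]), alpha=np.array([0.0, 1.0]),
                            beta=np.zeros(1), pi=np.array([0.3, 0.7]))
        post = e_step(data, params, spec)
        from scipy.special import expit
        lik = []
        for a in params.alpha:
            p1 = expit(0.5 - a)
            lik.append(p1 * (1 - p1))
        want = params.pi[0] * lik[0] / (params.pi[0] * lik[0] + params.pi[1] * lik[1])
        np.testing.assert_allclose(post.zhat[0, 0], want, atol=1e-12)

    def test_separated_blocks_recover_hard_memberships(self):
        """A huge effect gap makes the posteriors essentially 0/1."""
        truth = Parameters(mu=equal_probability_cutpoints(3),
                           alpha=np.array([0.0, 8.0]), beta=np.zeros(1),
                           pi=np.array([0.5, 0.5]))
        config = SimulationConfig(20, 50, 3, ModelSpec("clustered", "single", R=2),
                                  truth, "deterministic_blocks")
        data, row_truth, _ = generate_dataset(config, seed=11)
        post = e_step(data, truth, ModelSpec("clustered", "single", R=2))
        hard = np.round(post.zhat)
        assert np.abs(post.zhat - hard).max() < 1e-3
        labels = post.zhat.argmax(axis=1) + 1
        assert np.array_equal(labels, row_truth.labels)

    def test_rows_sum_to_one(self, small_bicluster):
        data, spec, params = small_bicluster
        post = e_step(data, params, spec)
        np.testing.assert_allclose(post.zhat.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(post.xhat.sum(axis=1), 1.0, atol=1e-10)


class TestMStep:
    def test_null_model_closed_form(self, rng):
        """The no-clustering fit reproduces empirical cumulative logits."""
        data = OrdinalMatrix(rng.integers(1, 5, size=(15, 8)), q=4)
        result = fit(data, ModelSpec())
        counts = np.bincount(data.values.ravel(), minlength=5)[1:]
        cum = np.cumsum(counts)[:-1] / data.values.size
        np.testing.assert_allclose(result.params.mu, np.log(cum / (1 - cum)), atol=1e-6)

    def test_mixing_proportions_are_posterior_means(self, small_bicluster):
        data, spec, params = small_bicluster
        post = e_step(data, params, spec)
        new = m_step(data, spec, post, params)
        np.testing.assert_allclose(new.pi, post.zhat.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(new.kappa, post.xhat.mean(axis=0), atol=1e-12)

    def test_recovers_classified_mle_with_true_memberships(self):
        """With memberships fixed at truth, the M-step approaches the truth
        on a large balanced simulation."""
        truth = Parameters(mu=equal_probability_cutpoints(3),
                           alpha=np.array([0.0, 1.0, 2.0]), beta=np.zeros(1),
                           pi=np.full(3, 1 / 3))
        spec = ModelSpec("clustered", "single", R=3)
        config = SimulationConfig(120, 80, 3, spec, truth, "deterministic_blocks")
        data, row_truth, _ = generate_dataset(config, seed=5)
        hard = Posteriors(zhat=(row_truth.labels[:, None] == np.arange(1, 4)).astype(float))
        est = m_step(data, spec, hard, None)
        np.testing.assert_allclose(est.alpha, truth.alpha, atol=0.15)
        np.testing.assert_allclose(est.mu, truth.mu, atol=0.15)

    def test_mstep_never_decreases_complete_loglik(self, small_bicluster):
        data, spec, params = small_bicluster
        post = e_step(data, params, spec)
        before = complete_loglik(data, params, spec, post)
        after = complete_loglik(data, m_step(data, spec, post, params), spec, post)
        assert after >= before - 1e-8


class TestFit:
    def test_objective_trace_is_non_decreasing(self, rng):
        data = OrdinalMatrix(rng.integers(1, 4, size=(12, 6)), q=3)
        for spec in [ModelSpec("clustered", "single", R=2),
                     ModelSpec("clustered", "clustered", R=2, C=2)]:
            result = fit(data, spec, n_starts=3, seed=1)
            diffs = np.diff(result.trace)
            assert np.all(diffs >= -1e-8)

    def test_fit_is_deterministic(self, rng):
        data = OrdinalMatrix(rng.integers(1, 4, size=(10, 5)), q=3)
        spec = ModelSpec("clustered", "clustered", R=2, C=2)
        a = fit(data, spec, n_starts=3, seed=42)
        b = fit(data, spec, n_starts=3, seed=42)
        assert a.loglik == b.loglik
        np.testing.assert_array_equal(a.params.mu, b.params.mu)
        np.testing.assert_array_equal(a.posteriors.zhat, b.posteriors.zhat)

    def test_loglik_matches_reported_operation(self, rng):
        data = OrdinalMatrix(rng.integers(1, 4, size=(10, 5)), q=3)
        result = fit(data, ModelSpec("clustered", "single", R=2), n_starts=2, seed=0)
        direct = incomplete_loglik_row_mixture(data, result.params, result.spec)
        np.testing.assert_allclose(result.loglik, direct, atol=1e-8)
        assert result.loglik_flag == "exact"
        assert result.entropy >= -1e-8

    def test_bicluster_recovery_on_separated_data(self):
        """Strong block structure at n=99, p=100 is recovered almost exactly."""
        truth = Parameters(
            mu=equal_probability_cutpoints(3),
            alpha=np.array([0.0, 1.0, 2.0]), beta=np.array([0.0, -1.0]),
            pi=np.full(3, 1 / 3), kappa=np.array([0.5, 0.5]),
        )
        spec = ModelSpec("clustered", "clustered", R=3, C=2)
        config = SimulationConfig(99, 100, 3, spec, truth, "deterministic_blocks")
        data, row_truth, _ = generate_dataset(config, seed=17)
        result = fit(data, spec, n_starts=5, seed=2, tol=1e-7)
        labels = pofm.hard_assignment(result.posteriors.zhat)
        assert pofm.rand_index(labels, row_truth) >= 0.9

    def test_category_reversal_symmetry(self, rng):
        """Reversing the category order and negating the scale leaves the
        maximised likelihood unchanged (palindromic invariance)."""
        data = OrdinalMatrix(rng.integers(1, 4, size=(10, 6)), q=3)
        rev = OrdinalMatrix(4 - data.values, q=3)
        spec = ModelSpec("clustered", "single", R=2)
        a = fit(data, spec, n_starts=4, seed=9)
        b = fit(rev, spec, n_starts=4, seed=9)
        np.testing.assert_allclose(a.loglik, b.loglik, atol=1e-5)

    def test_empirical_cutpoints_handle_empty_category(self):
        data = OrdinalMatrix(np.array([[1, 3], [3, 1]]), q=3)
        mu = _empirical_cutpoints(data)
        assert np.all(np.diff(mu) > 0)
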