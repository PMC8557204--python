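"""Spearman correlations, constrained Gaussian MLE, EBIC and model search."""

import numpy as np
import pandas as pd
import pytest

from _oracles import (
    constrained_mle_oracle,
    partial_corr_residual,
    random_pd_correlation,
    random_structure,
)
from sympnet import ggm


def saturated(p):
    return np.ones((p, p), dtype=bool) & ~np.eye(p, dtype=bool)


class TestSpearman:
    def test_self_correlation_is_one(self):
        df = pd.DataFrame({"a": [1, 5, 2, 9, 3], "b": [2, 1, 4, 4, 7]})
        R = ggm.spearman_corr(df)
        assert np.allclose(np.diag(R.matrix), 1.0)

    def test_monotone_transform_invariance(self):
        x = np.array([0.3, 1.2, 2.0, 3.3, 4.1, 5.5])
        df = pd.DataFrame({"x": x, "y": np.exp(x)})
        assert ggm.spearman_corr(df).matrix[0, 1] == pytest.approx(1.0)

    def test_hand_computed_single_swap(self):
        # one adjacent swap in n=5: rho = 1 - 6*2/(5*24) = 0.9
        df = pd.DataFrame({"x": [1, 2, 3, 4, 5], "y": [1, 2, 3, 5, 4]})
        assert ggm.spearman_corr(df).matrix[0, 1] == pytest.approx(0.9)

    def test_listwise_deletion_counts(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4, np.nan], "y": [5, 4, 3, 1, 2]})
        assert ggm.spearman_corr(df).n_effective == 4

    def test_constant_column_raises_with_name(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4], "flat": [2, 2, 2, 2]})
        with pytest.raises(ValueError, match="flat"):
            ggm.spearman_corr(df)


class TestPartialFromPrecision:
    def test_identity_gives_zero_offdiagonals(self):
        W = ggm.partial_from_precision(np.eye(4))
        assert np.allclose(W, 0.0)

    def test_two_variables_partial_equals_marginal(self):
        R = np.array([[1.0, 0.4], [0.4, 1.0]])
        W = ggm.partial_from_precision(np.linalg.inv(R))
        assert W[0, 1] == pytest.approx(0.4)

    def test_exchangeable_closed_form_and_residual_oracle(self, rng):
        # exchangeable rho=0.5: all partials rho/(1+rho) = 1/3
        R = np.full((3, 3), 0.5)
        np.fill_diagonal(R, 1.0)
        W = ggm.partial_from_precision(np.linalg.inv(R))
        assert np.allclose(W[np.triu_indices(3, 1)], 1.0 / 3.0)
        X = rng.multivariate_normal(np.zeros(3), R, size=20000)
        oracle = partial_corr_residual(X[:, 0], X[:, 1], X[:, [2]])
        assert W[0, 1] == pytest.approx(oracle, abs=0.02)

    def test_non_pd_input_rejected(self):
        K = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive definite"):
            ggm.partial_from_precision(K)


class TestConstrainedFit:
    def test_saturated_structure_is_unconstrained_mle(self, rng):
        S = random_pd_correlation(4, rng)
        fit = ggm.fit_constrained_ggm(S, saturated(4), n=100)
        assert np.allclose(fit.precision, np.linalg.inv(S), atol=1e-8)

    def test_empty_structure_is_independence_model(self, rng):
        S = random_pd_correlation(4, rng)
        fit = ggm.fit_constrained_ggm(S, np.zeros((4, 4), dtype=bool), n=100)
        assert np.allclose(fit.precision, np.diag(1.0 / np.diag(S)))

    def test_matches_convex_optimization_oracle(self, rng):
        for _ in range(10):
            S = random_pd_correlation(4, rng)
            adj = random_structure(4, rng)
            fit = ggm.fit_constrained_ggm(S, adj, n=200)
            K_oracle = constrained_mle_oracle(S, adj)
            assert np.abs(fit.precision - K_oracle).max() < 1e-4

    def test_moment_matching_property(self, rng):
        # fitted covariance equals S on the diagonal and on every edge
        for _ in range(10):
            S = random_pd_correlation(5, rng)
            adj = random_structure(5, rng, density=0.4)
            fit = ggm.fit_constrained_ggm(S, adj, n=200)
            W = np.linalg.inv(fit.precision)
            assert np.abs(np.diag(W) - np.diag(S)).max() < 1e-6
            if adj.any():
                assert np.abs(W[adj] - S[adj]).max() < 1e-6
            off = ~adj & ~np.eye(5, dtype=bool)
            assert np.all(fit.precision[off] == 0.0)

    def test_adding_edges_never_decreases_loglik(self, rng):
        S = random_pd_correlation(5, rng)
        adj = random_structure(5, rng, density=0.3)
        base = ggm.fit_constrained_ggm(S, adj, n=100)
        for i in range(5):
            for j in range(i + 1, 5):
                if not adj[i, j]:
                    bigger = adj.copy()
                    bigger[i, j] = bigger[j, i] = True
                    f2 = ggm.fit_constrained_ggm(S, bigger, n=100)
                    assert f2.loglik >= base.loglik - 1e-8


class TestEbic:
    def test_gamma_zero_reduces_to_bic(self, rng):
        S = random_pd_correlation(4, rng)
        fit = ggm.fit_constrained_ggm(S, saturated(4), n=150, gamma=0.0)
        assert fit.ebic == pytest.approx(-2 * fit.loglik + 6 * np.log(150))

    def test_empty_model_is_minus_twice_loglik(self, rng):
        S = random_pd_correlation(3, rng)
        fit = ggm.fit_constrained_ggm(S, np.zeros((3, 3), dtype=bool), n=80)
        assert fit.ebic == pytest.approx(-2 * fit.loglik)

    def test_closed_form_identity_saturated(self):
        # identity S: l = -(n/2) p (1 + log 2 pi)
        gamma = 0.5
        fit = ggm.fit_constrained_ggm(np.eye(3), saturated(3), n=100, gamma=gamma)
        expected = 100 * 3 * (1 + np.log(2 * np.pi)) + 3 * np.log(100) + 12 * gamma * np.log(3)
        assert fit.ebic == pytest.approx(expected)

    def test_reevaluation_at_other_gamma(self, rng):
        S = random_pd_correlation(4, rng)
        fit = ggm.fit_constrained_ggm(S, saturated(4), n=100, gamma=0.5)
        assert ggm.ebic(fit, 0.0) < ggm.ebic(fit, 1.0)


def _simulate_corr(P_true, n, rng):
    """Sample correlation matrix from a known partial-correlation network."""
    K = -P_true.copy()
    np.fill_diagonal(K, 1.0)
    Sigma = np.linalg.inv(K)
    d = np.sqrt(np.diag(Sigma))
    Sigma = Sigma / np.outer(d, d)
    X = rng_mv(Sigma, n, rng)
    return np.corrcoef(X, rowvar=False)


def rng_mv(Sigma, n, rng):
    L = np.linalg.cholesky(Sigma)
    return rng.standard_normal((n, Sigma.shape[0])) @ L.T


class TestModelSearch:
    def test_two_node_equivalence_with_closed_form(self):
        # edge selected iff EBIC(edge) < EBIC(no edge); the loglik difference
        # has the closed form -(n/2) log(1 - r^2)
        n = 400
        for r in (0.05, 0.30):
            R = np.array([[1.0, r], [r, 1.0]])
            fit = ggm.model_search(R, gamma=0.5, n=n)
            delta_pen = np.log(n) + 4 * 0.5 * np.log(2)
            gain = -n * np.log(1 - r**2)
            assert (fit.n_edges == 1) == (gain > delta_pen)

    def test_exhaustive_optimum_on_small_instances(self, rng):
        hits = 0
        for _ in range(10):
            P = np.zeros((4, 4))
            for i in range(4):
                for j in range(i + 1, 4):
                    if rng.random() < 0.5:
                        P[i, j] = P[j, i] = rng.uniform(0.15, 0.35)
            S = _simulate_corr(P, 500, rng)
            found = ggm.model_search(S, gamma=0.5, n=500)
            best = min(
                (
                    ggm.fit_constrained_ggm(S, unpack_structure(mask, 4), n=500).ebic
                    for mask in range(64)
                ),
            )
            if found.ebic <= best + 1e-6:
                hits += 1
        assert hits >= 8

    def test_empty_graph_selects_almost_nothing(self, rng):
        X = rng.standard_normal((5000, 5))
        S = np.corrcoef(X, rowvar=False)
        fit = ggm.model_search(S, gamma=0.5, n=5000)
        assert fit.n_edges <= 1

    def test_chain_recovery(self, rng):
        # 4-node chain with partials 0.4
        P = np.zeros((4, 4))
        for i in range(3):
            P[i, i + 1] = P[i + 1, i] = 0.4
        wins = 0
        for _ in range(3):
            S = _simulate_corr(P, 5000, rng)
            fit = ggm.model_search(S, gamma=0.5, n=5000)
            if np.array_equal(fit.structure, P != 0):
                wins += 1
        assert wins >= 2

    def test_determinism(self, rng):
        S = random_pd_correlation(6, rng)
        f1 = ggm.model_search(S, gamma=0.5, n=300)
        f2 = ggm.model_search(S, gamma=0.5, n=300)
        assert np.array_equal(f1.structure, f2.structure)
        assert f1.ebic == f2.ebic

    def test_search_never_beats_itself(self, rng):
        # returned EBIC is <= both trivial models' EBIC
        S = random_pd_correlation(6, rng)
        fit = ggm.model_search(S, gamma=0.5, n=300)
        empty = ggm.fit_constrained_ggm(S, np.zeros((6, 6), dtype=bool), n=300)
        full = ggm.fit_constrained_ggm(S, saturated(6), n=300)
        assert fit.ebic <= min(empty.ebic, full.ebic) + 1e-9

    def test_requires_more_subjects_than_nodes(self, rng):
        S = random_pd_correlation(5, rng)
        with pytest.raises(ValueError, match="more observations"):
            ggm.model_search(S, n=5)


def unpack_structure(mask: int, p: int) -> np.ndarray:
    adj = np.zeros((p, p), dtype=bool)
    for b, (i, j) in enumerate(zip(*np.triu_indices(p, 1))):
        if mask >> b & 1:
            adj[i, j] = adj[j, i] = True
    return adj
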