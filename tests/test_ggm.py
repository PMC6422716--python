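"""Graphical lasso solver, partial correlations, BIC selection."""

import numpy as np
import pytest

from cognet.ggm import (
    bic_score,
    estimate_network,
    glasso_solve,
    lambda_grid,
    precision_to_partial,
)
from cognet.preprocess import ScoreMatrix


def _random_corr(rng, p=6, n=400):
    X = rng.standard_normal((n, p)) @ rng.standard_normal((p, p))
    return np.corrcoef(X, rowvar=False)


class TestGlassoSolve:
    def test_identity_input_returns_identity(self):
        for lam in (0.0, 0.1, 1.0):
            Theta = glasso_solve(np.eye(4), lam)
            assert np.allclose(Theta, np.eye(4), atol=1e-8)

    def test_full_penalty_gives_empty_network(self, rng):
        S = _random_corr(rng, p=3)
        lam_max = np.abs(S - np.diag(np.diag(S))).max()
        Theta = glasso_solve(S, lam_max)
        assert np.count_nonzero(np.triu(Theta, k=1)) == 0
        # unpenalized diagonal: theta_ii = 1 / S_ii
        assert np.allclose(np.diag(Theta), 1.0 / np.diag(S), atol=1e-8)

    def test_zero_penalty_equals_matrix_inverse(self, rng):
        S = _random_corr(rng, p=5)
        Theta = glasso_solve(S, 0.0)
        assert np.abs(Theta - np.linalg.inv(S)).max() < 1e-4

    @pytest.mark.parametrize("lam", [0.02, 0.1, 0.3])
    def test_kkt_stationarity_of_penalized_objective(self, rng, lam):
        """The solution must satisfy the subgradient conditions of
        log det - tr(S Theta) - lam * sum_{i!=j}|Theta_ij| exactly."""
        S = _random_corr(rng, p=6)
        Theta = glasso_solve(S, lam)
        G = S - np.linalg.inv(Theta)
        p = S.shape[0]
        for i in range(p):
            assert abs(G[i, i]) < 1e-6  # diagonal unpenalized
            for j in range(p):
                if i == j:
                    continue
                if Theta[i, j] != 0:
                    assert abs(G[i, j] + lam * np.sign(Theta[i, j])) < 1e-6
                else:
                    assert abs(G[i, j]) <= lam + 1e-6

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            glasso_solve(np.eye(3), -0.1)
        with pytest.raises(ValueError):
            glasso_solve(np.arange(9.0).reshape(3, 3), 0.1)


class TestPrecisionToPartial:
    def test_identity_gives_zero_matrix(self):
        assert np.all(precision_to_partial(np.eye(3)) == 0)

    def test_two_by_two_hand_value(self):
        W = precision_to_partial(np.array([[2.0, -1.0], [-1.0, 2.0]]))
        assert W[0, 1] == pytest.approx(0.5)

    def test_matches_schur_complement_oracle(self, random_pd_theta):
        """Partial correlations via conditional (Schur-complement)
        covariance of each pair given the rest — an independent route."""
        Theta = random_pd_theta
        C = np.linalg.inv(Theta)
        W = precision_to_partial(Theta)
        p = Theta.shape[0]
        for i in range(p):
            for j in range(i + 1, p):
                rest = [k for k in range(p) if k not in (i, j)]
                pair = [i, j]
                S2 = C[np.ix_(pair, pair)] - C[np.ix_(pair, rest)] @ np.linalg.solve(
                    C[np.ix_(rest, rest)], C[np.ix_(rest, pair)]
                )
                rho = S2[0, 1] / np.sqrt(S2[0, 0] * S2[1, 1])
                assert W[i, j] == pytest.approx(rho, abs=1e-10)

    def test_nonpositive_diagonal_rejected(self):
        with pytest.raises(ValueError):
            precision_to_partial(np.array([[1.0, 0.0], [0.0, -2.0]]))


class TestBicScore:
    def test_identity_case_hand_arithmetic(self):
        # l = (n/2)(logdet I - tr I) = 50*(0 - 2) = -100; E=0 -> BIC = 200
        assert bic_score(np.eye(2), np.eye(2), 100) == pytest.approx(200.0)

    def test_formula_matches_independent_arithmetic(self, random_pd_theta, rng):
        Theta = random_pd_theta
        S = _random_corr(rng, p=4)
        n = 77
        ll = 0.5 * n * (np.log(np.linalg.det(Theta)) - np.trace(S @ Theta))
        E = sum(
            1 for i in range(4) for j in range(i + 1, 4) if Theta[i, j] != 0
        )
        assert bic_score(Theta, S, n) == pytest.approx(-2 * ll + E * np.log(n))

    def test_extra_edge_costs_exactly_log_n(self):
        """Same likelihood, one more nonzero edge -> BIC difference ln(n)."""
        Theta = np.eye(3)
        S = np.eye(3)
        n = 500
        base = bic_score(Theta, S, n)
        eps = 1e-9  # edge so small the likelihood change is negligible
        Theta2 = Theta.copy()
        Theta2[0, 1] = Theta2[1, 0] = eps
        assert bic_score(Theta2, S, n) - base == pytest.approx(np.log(n), abs=1e-6)

    def test_bic_prefers_true_chain_over_full_model(self):
        """On a 3-variable chain, BIC selection picks the 2-edge model
        more often than the saturated 3-edge model."""
        r = 0.4
        P = np.array([[1, -r, 0], [-r, 1, -r], [0, -r, 1]], dtype=float)
        C = np.linalg.inv(P)
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
        L = np.linalg.cholesky(C)
        rng = np.random.default_rng(7)
        true_hits = full_hits = 0
        for _ in range(200):
            X = rng.standard_normal((1000, 3)) @ L.T
            sm = ScoreMatrix("sim", ["a", "b", "c"], X)
            net, _ = estimate_network(sm, n_lambda=40)
            edges = net.edge_set()
            if edges == {("a", "b"), ("b", "c")}:
                true_hits += 1
            elif len(edges) == 3:
                full_hits += 1
        assert true_hits > full_hits


class TestLambdaGrid:
    def test_endpoints_by_definition(self):
        S = np.eye(3)
        S[0, 1] = S[1, 0] = 0.8
        grid = lambda_grid(S, n_lambda=50, ratio=0.01)
        assert grid[0] == pytest.approx(0.8)
        assert grid[-1] == pytest.approx(0.008)

    def test_two_point_grid(self):
        S = np.eye(2)
        S[0, 1] = S[1, 0] = 0.5
        grid = lambda_grid(S, n_lambda=2, ratio=0.1)
        assert grid == pytest.approx([0.5, 0.05])

    def test_strictly_decreasing(self, rng):
        grid = lambda_grid(_random_corr(rng), n_lambda=30)
        assert np.all(np.diff(grid) < 0)

    def test_all_zero_offdiagonals_single_point(self):
        with pytest.warns(UserWarning):
            grid = lambda_grid(np.eye(4))
        assert grid.tolist() == [0.0]


class TestEstimateNetwork:
    def _planted_scores(self, n, seed):
        from cognet.benchmarks import make_twoblock_model, _sample_scores

        return make_twoblock_model(), _sample_scores(
            make_twoblock_model(), n=n, seed=seed
        )

    def test_recovers_all_planted_edges_at_large_n(self):
        model, scores = self._planted_scores(n=5000, seed=21)
        net, _ = estimate_network(scores)
        assert model.edge_set() <= net.edge_set()

    def test_consistency_entrywise_at_large_n(self):
        model, scores = self._planted_scores(n=10_000, seed=22)
        net, _ = estimate_network(scores)
        assert np.abs(net.W - model.partial_correlations()).max() < 0.03

    def test_independent_data_gives_empty_network(self, rng):
        X = rng.standard_normal((10_000, 9))
        sm = ScoreMatrix("null", [f"v{i}" for i in range(9)], X)
        net, _ = estimate_network(sm)
        assert len(net.edge_set()) == 0

    def test_invariant_to_column_rescaling(self, rng):
        _, scores = self._planted_scores(n=300, seed=23)
        scaled = ScoreMatrix(
            scores.group_name, scores.labels,
            scores.X * np.arange(1, 10) + 100.0,
        )
        net_a, _ = estimate_network(scores)
        net_b, _ = estimate_network(scaled)
        assert np.allclose(net_a.W, net_b.W, atol=1e-12)

    def test_edges_weakly_decrease_with_penalty(self, rng):
        S = _random_corr(rng, p=6, n=200)
        lams = [0.02, 0.1, 0.3, 0.6]
        counts = [
            np.count_nonzero(np.triu(glasso_solve(S, lam), k=1)) for lam in lams
        ]
        assert counts == sorted(counts, reverse=True)

    def test_selected_index_minimizes_bic(self):
        _, scores = self._planted_scores(n=400, seed=24)
        net, path = estimate_network(scores)
        assert path.bics[path.selected_index] <= path.bics.min() + 1e-9
        assert net.lambda_selected == path.lambdas[path.selected_index]
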