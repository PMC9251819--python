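import numpy as np
import pytest
from scipy import stats
from scipy.optimize import minimize

from symptomnet import (
    GaussianGraphicalModel,
    SimConfig,
    correlate,
    ebic,
    estimate_network,
    glasso_fit,
    make_ground_truth,
    partial_from_precision,
    sample_cohort,
)
from symptomnet.ggm import _glasso, _polychoric_pair, glasso_objective


def random_correlation(p, n, rng):
    x = rng.normal(size=(n, p)) @ rng.normal(size=(p, p))
    return np.corrcoef(x, rowvar=False)


def brute_force_glasso_objective(S, lam, p, x0=None):
    """Independent maximizer of the penalized likelihood over PD matrices.

    Parametrizes K by its Cholesky factor and smooths |.| with
    sqrt(x^2 + eps); the smoothing error is O(eps) per entry.
    """
    eps = 1e-14
    tril = np.tril_indices(p)

    def neg(theta):
        L = np.zeros((p, p))
        L[tril] = theta
        K = L @ L.T
        sign, logdet = np.linalg.slogdet(K)
        if sign <= 0:
            return 1e10
        off = np.sqrt(K**2 + eps).sum() - np.sqrt(np.diag(K) ** 2 + eps).sum()
        return -(logdet - np.trace(S @ K) - lam * off)

    if x0 is None:
        x0 = np.linalg.cholesky(np.linalg.inv(S + lam * np.eye(p)))
    r1 = minimize(neg, x0[tril], method="L-BFGS-B",
                  options={"maxiter": 20000, "ftol": 1e-16, "gtol": 1e-14})
    # polish with derivative-free methods to get past the kinks of |.|
    r2 = minimize(neg, r1.x, method="Nelder-Mead",
                  options={"maxiter": 50000, "xatol": 1e-10, "fatol": 1e-14})
    r3 = minimize(neg, r2.x, method="Powell",
                  options={"maxiter": 50000, "xtol": 1e-12, "ftol": 1e-14})
    return -min(r1.fun, r2.fun, r3.fun)


class TestCorrelate:
    def test_identical_columns_give_unit_correlation(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=200)
        x = np.column_stack([col, col, rng.normal(size=200)])
        s = correlate(x, "pearson")
        assert s.values[0, 1] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(1)
        n = 100_000
        x = rng.normal(size=(n, 4))
        s = correlate(x, "pearson").values
        off = s[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 3.0 / np.sqrt(n)

    def test_zero_variance_column_named(self, tiny6_schema):
        from symptomnet import CohortTable

        scores = np.ones((10, 6), dtype=np.int64)
        scores[:, :5] = np.random.default_rng(2).integers(1, 8, size=(10, 5))
        table = CohortTable(tiny6_schema, scores, [str(i) for i in range(10)])
        with pytest.raises(ValueError, match="T12"):
            correlate(table, "pearson")

    def test_polychoric_matches_grid_search_oracle(self):
        """Two-step estimate vs a dense rho-grid of the same likelihood."""
        x = np.repeat([0, 0, 1, 1], [40, 10, 10, 40])
        y = np.repeat([0, 1, 0, 1], [40, 10, 10, 40])
        est = _polychoric_pair(x, y)

        from symptomnet.ggm import _bvn_cdf

        def nll(r):
            p11 = _bvn_cdf(0.0, 0.0, r)
            p12 = stats.norm.cdf(0.0) - p11
            p22 = 1.0 - p11 - 2 * p12
            return -(40 * np.log(p11) + 20 * np.log(p12) + 40 * np.log(p22))

        grid = np.arange(-0.99, 0.99, 1e-4)
        oracle = grid[np.argmin([nll(r) for r in grid])]
        assert est == pytest.approx(oracle, abs=1e-3)

    def test_polychoric_recovers_latent_correlation(self):
        rng = np.random.default_rng(3)
        rho = 0.55
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=4000)
        cuts = stats.norm.ppf([0.3, 0.6, 0.85])
        x = np.searchsorted(cuts, z[:, 0])
        y = np.searchsorted(cuts, z[:, 1])
        est = _polychoric_pair(x, y)
        assert est == pytest.approx(rho, abs=0.05)

    def test_polychoric_matrix_shape(self, tiny6_cohort):
        table, _, _ = tiny6_cohort
        s = correlate(table, "polychoric")
        assert s.values.shape == (6, 6)
        np.testing.assert_allclose(np.diag(s.values), 1.0)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            correlate(np.random.default_rng(0).normal(size=(30, 3)), "kendall")


class TestPartialFromPrecision:
    def test_identity_gives_zero(self):
        np.testing.assert_array_equal(partial_from_precision(np.eye(4)), np.zeros((4, 4)))

    def test_two_by_two_closed_form(self):
        K = np.array([[2.0, -1.0], [-1.0, 2.0]])
        assert partial_from_precision(K)[0, 1] == pytest.approx(0.5)

    def test_chain_zero_pattern(self):
        K = np.array([[1.5, -0.4, 0.0], [-0.4, 1.8, -0.3], [0.0, -0.3, 1.2]])
        W = partial_from_precision(K)
        assert W[0, 2] == 0.0
        assert W[0, 1] != 0.0 and W[1, 2] != 0.0

    def test_matches_regression_residual_oracle(self):
        """Partial correlation equals the correlation of regression residuals
        of the pair on all remaining variables (computed from Sigma = K^-1)."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            p = rng.integers(3, 7)
            A = rng.normal(size=(p, p))
            K = A @ A.T + p * np.eye(p)
            W = partial_from_precision(K)
            cov = np.linalg.inv(K)
            for i in range(p):
                for j in range(i + 1, p):
                    others = [k for k in range(p) if k not in (i, j)]
                    coo = cov[np.ix_(others, others)]
                    ci = cov[np.ix_([i], others)]
                    cj = cov[np.ix_([j], others)]
                    sii = cov[i, i] - ci @ np.linalg.solve(coo, ci.T)
                    sjj = cov[j, j] - cj @ np.linalg.solve(coo, cj.T)
                    sij = cov[i, j] - ci @ np.linalg.solve(coo, cj.T)
                    oracle = (sij / np.sqrt(sii * sjj)).item()
                    assert W[i, j] == pytest.approx(oracle, abs=1e-10)

    def test_non_pd_rejected(self):
        with pytest.raises(ValueError):
            partial_from_precision(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestGlasso:
    def test_full_shrinkage_gives_empty_network(self):
        rng = np.random.default_rng(5)
        S = random_correlation(5, 80, rng)
        lam_max = np.abs(S - np.eye(5)).max()
        model = glasso_fit(S, lam_max)
        assert model.n_edges == 0
        np.testing.assert_array_equal(model.weights, np.zeros((5, 5)))

    def test_two_nodes_unpenalized_recovers_marginal(self):
        S = np.array([[1.0, 0.6], [0.6, 1.0]])
        model = glasso_fit(S, 0.0)
        assert model.weights[0, 1] == pytest.approx(0.6, abs=1e-6)

    def test_unpenalized_singular_matrix_advises(self):
        S = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="lambda > 0"):
            glasso_fit(S, 0.0)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            glasso_fit(np.eye(3), -0.1)

    @pytest.mark.parametrize("p,lam,seed", [(4, 0.1, 0), (5, 0.05, 1), (6, 0.2, 2)])
    def test_objective_matches_brute_force(self, p, lam, seed):
        rng = np.random.default_rng(seed)
        S = random_correlation(p, 15 * p, rng)
        K, _, _ = _glasso(S, lam, tol=1e-7)
        mine = glasso_objective(K, S, lam)
        brute = brute_force_glasso_objective(S, lam, p)
        assert mine == pytest.approx(brute, abs=1e-4)

    def test_matches_sklearn_graphical_lasso(self):
        """Independent cross-check against sklearn's implementation."""
        from sklearn.covariance import graphical_lasso as sk_glasso

        rng = np.random.default_rng(6)
        S = random_correlation(8, 200, rng)
        lam = 0.08
        K, _, _ = _glasso(S, lam, tol=1e-8)
        _, K_sk = sk_glasso(S, alpha=lam, mode="cd", tol=1e-10, max_iter=2000)
        assert glasso_objective(K, S, lam) == pytest.approx(
            glasso_objective(K_sk, S, lam), abs=1e-6
        )
        np.testing.assert_allclose(K, K_sk, atol=1e-3)

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        S = random_correlation(7, 150, rng)
        model = glasso_fit(S, 0.05)
        np.testing.assert_allclose(model.weights, model.weights.T, atol=1e-10)
        np.testing.assert_allclose(model.precision, model.precision.T, atol=1e-10)


class TestEbic:
    def test_gamma_zero_reduces_to_bic(self):
        rng = np.random.default_rng(8)
        S = random_correlation(5, 100, rng)
        model = glasso_fit(S, 0.1)
        n = 100
        # independent evaluation of the BIC from first principles
        sign, logdet = np.linalg.slogdet(model.precision)
        ll = 0.5 * n * (logdet - np.trace(S @ model.precision))
        bic = -2 * ll + model.n_edges * np.log(n)
        assert ebic(model, S, n, gamma=0.0) == pytest.approx(bic, rel=1e-12)

    def test_hand_evaluated_formula(self):
        """With l = -100, E = 3, n = 50, p = 5, gamma = 0.5 the criterion is
        200 + 3 log 50 + 6 log 5 (checked by shifting an actual model's value)."""
        rng = np.random.default_rng(9)
        S = random_correlation(5, 50, rng)
        model = glasso_fit(S, 0.15)
        sign, logdet = np.linalg.slogdet(model.precision)
        ll = 0.5 * 50 * (logdet - np.trace(S @ model.precision))
        got = ebic(model, S, 50, gamma=0.5)
        expected_shape = -2 * ll + model.n_edges * np.log(50) \
            + 4 * 0.5 * model.n_edges * np.log(5)
        assert got == pytest.approx(expected_shape, rel=1e-12)
        # the stated arithmetic instance
        assert -2 * (-100) + 3 * np.log(50) + 4 * 0.5 * 3 * np.log(5) \
            == pytest.approx(200 + 3 * np.log(50) + 6 * np.log(5))

    def test_sparser_model_wins_ties(self):
        """Equal likelihood implies the model with fewer edges has lower EBIC."""
        rng = np.random.default_rng(10)
        S = random_correlation(4, 100, rng)
        dense = glasso_fit(S, 0.01)
        sparse = glasso_fit(S, 0.3)
        assert sparse.n_edges < dense.n_edges
        # same K, differing only in edge count -> monotone penalty
        for gamma in (0.0, 0.25, 0.5, 1.0):
            pen_dense = dense.n_edges * (np.log(100) + 4 * gamma * np.log(4))
            pen_sparse = sparse.n_edges * (np.log(100) + 4 * gamma * np.log(4))
            assert pen_sparse < pen_dense


class TestEstimateNetwork:
    def test_monotone_sparsity_along_path(self, tiny6_cohort):
        table, _, _ = tiny6_cohort
        est = GaussianGraphicalModel(n_lambda=30).fit(table)
        edges = [step["n_edges"] for step in est.path_]
        assert all(a <= b for a, b in zip(edges, edges[1:]))

    def test_null_cohort_specificity(self, schema43):
        """On independent blocks most true-zero edges are estimated as zero."""
        cfg = SimConfig(seed=17, between_density=0.0, n_bridges=0)
        truth = make_ground_truth(schema43, cfg)
        table = sample_cohort(truth, schema43, cfg)
        model = estimate_network(table, n_lambda=40)
        iu = np.triu_indices(43, 1)
        true_zero = ~truth.support[iu]
        est_zero = model.weights[iu] == 0.0
        specificity = (true_zero & est_zero).sum() / true_zero.sum()
        assert specificity >= 0.9

    def test_beats_path_endpoints_on_planted_truth(self, default_cohort):
        table, truth, _ = default_cohort
        model = estimate_network(table, n_lambda=40)
        iu = np.triu_indices(43, 1)
        true_support = truth.support[iu]

        def hamming(weights):
            return int(((weights[iu] != 0.0) != true_support).sum())

        s = model.path  # (lam, n_edges, ebic) trace
        assert s is not None and len(s) > 2
        empty = np.zeros_like(model.weights)
        dense = glasso_fit(correlate(table).values, s[-1]["lam"]).weights
        assert hamming(model.weights) < hamming(empty)
        assert hamming(model.weights) < hamming(dense)

    def test_duplicated_rows_leave_weights_unchanged(self, tiny6_cohort):
        from symptomnet import CohortTable

        table, _, _ = tiny6_cohort
        doubled = CohortTable(
            schema=table.schema,
            scores=np.vstack([table.scores, table.scores]),
            participant_ids=[f"d{i}" for i in range(2 * table.n)],
        )
        m1 = estimate_network(table, n_lambda=25)
        m2 = estimate_network(doubled, n_lambda=25)
        np.testing.assert_allclose(m1.weights, m2.weights, atol=1e-8)

    def test_sklearn_estimator_contract(self, tiny6_cohort):
        """get_params/set_params/clone work and fitted attrs carry underscores."""
        from sklearn.base import clone

        table, _, _ = tiny6_cohort
        est = GaussianGraphicalModel(gamma=0.25, n_lambda=20)
        cloned = clone(est)
        assert cloned.get_params()["gamma"] == 0.25
        est.fit(table.scores)
        for attr in ("precision_", "weights_", "lambda_", "ebic_", "n_edges_"):
            assert hasattr(est, attr)
        est.set_params(gamma=0.5)
        assert est.gamma == 0.5

    def test_adaptive_variant_runs(self, tiny6_cohort):
        table, _, _ = tiny6_cohort
        model = estimate_network(table, n_lambda=20, adaptive=True)
        assert model.weights.shape == (6, 6)
        np.testing.assert_allclose(model.weights, model.weights.T, atol=1e-10)
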