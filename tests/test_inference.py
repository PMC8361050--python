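"""Tests for RPKM, variance filtering, moment estimation, and the
from-scratch graphical lasso (checked against ADMM and sklearn oracles)."""

import numpy as np
import pytest
from scipy import integrate, stats

from grntopo.containers import CovarianceModel, ExpressionMatrix
from grntopo.inference import (
    ConvergenceError,
    estimate_covariance,
    glasso_kkt_gap,
    glasso_objective,
    graphical_lasso,
    infer_network,
    interactions_from_precision,
    model_log_density,
    rpkm_normalize,
    select_penalty,
    select_top_variance_genes,
)
from grntopo.synthetic import PrecisionSpec, generate_sparse_precision, sample_expression
from oracles import admm_graphical_lasso, random_spd


def expr_from(values, gene_ids=None):
    values = np.asarray(values, dtype=float)
    g, s = values.shape
    return ExpressionMatrix(
        gene_ids=gene_ids or [f"g{i}" for i in range(g)],
        sample_ids=[f"s{j}" for j in range(s)],
        values=values,
    )


class TestRpkm:
    def test_direct_formula(self):
        counts = np.array([[10.0]])
        out = rpkm_normalize(counts, np.array([1000]))
        assert out.values[0, 0] == pytest.approx(1e6)

    def test_zero_count_stays_zero(self):
        counts = np.array([[0.0], [5.0]])
        out = rpkm_normalize(counts, np.array([100, 200]))
        assert out.values[0, 0] == 0.0

    def test_matches_elementwise_recomputation(self, rng):
        counts = rng.integers(0, 100, size=(4, 3)).astype(float)
        counts[0, 0] += 1  # guard against a zero library
        lengths = rng.integers(200, 5000, size=4)
        out = rpkm_normalize(counts, lengths)
        for g in range(4):
            for s in range(3):
                expected = 1e9 * counts[g, s] / (lengths[g] * counts[:, s].sum())
                assert out.values[g, s] == pytest.approx(expected)

    def test_rejects_zero_library_and_zero_length(self):
        with pytest.raises(ValueError):
            rpkm_normalize(np.zeros((2, 2)), np.array([100, 100]))
        with pytest.raises(ValueError):
            rpkm_normalize(np.ones((2, 2)), np.array([0, 100]))


class TestVarianceFilter:
    def test_identity_when_k_equals_gene_count(self, rng):
        expr = expr_from(rng.standard_normal((5, 20)))
        out = select_top_variance_genes(expr, 5)
        assert set(out.gene_ids) == set(expr.gene_ids)

    def test_selects_largest_variances_in_descending_order(self):
        values = np.array(
            [[0.0] * 4, [0, 1, 0, 1], [0, 2, 0, 2], [0, 3, 0, 3], [0, 4, 0, 4]]
        )
        out = select_top_variance_genes(expr_from(values), 2)
        assert out.gene_ids == ["g4", "g3"]

    def test_k_above_positive_variance_count_rejected(self):
        values = np.vstack([np.ones(4), np.arange(4.0)])
        with pytest.raises(ValueError, match="positive variance"):
            select_top_variance_genes(expr_from(values), 2)

    def test_tie_break_keeps_input_order(self):
        values = np.array([[0, 1, 0, 1], [1, 0, 1, 0], [0, 5, 0, 5]])
        out = select_top_variance_genes(expr_from(values), 3)
        assert out.gene_ids == ["g2", "g0", "g1"]


class TestCovariance:
    def test_hand_computed_two_gene_case(self):
        expr = expr_from(np.array([[0.0, 2.0], [0.0, 2.0]]))
        model = estimate_covariance(expr)
        assert model.mean == pytest.approx([1.0, 1.0])
        assert model.covariance == pytest.approx(np.ones((2, 2)))

    def test_constant_gene_dropped_with_warning_or_raises(self):
        expr = expr_from(np.vstack([np.ones(5), np.arange(5.0), np.arange(5.0) ** 2]))
        with pytest.warns(UserWarning, match="zero-variance"):
            model = estimate_covariance(expr)
        assert model.gene_ids == ["g1", "g2"]
        with pytest.raises(ValueError, match="constant"):
            estimate_covariance(expr, drop_constant=False)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            estimate_covariance(expr_from(np.array([[1.0], [2.0]])))

    def test_matches_two_pass_brute_force_loop(self, rng):
        values = rng.standard_normal((4, 50))
        model = estimate_covariance(expr_from(values))
        n = 50
        means = [sum(values[g]) / n for g in range(4)]
        for a in range(4):
            for b in range(4):
                cab = sum(
                    (values[a, s] - means[a]) * (values[b, s] - means[b])
                    for s in range(n)
                ) / n  # ML divisor n, not n-1
                assert model.covariance[a, b] == pytest.approx(cab)


class TestGraphicalLasso:
    def test_full_shrinkage_gives_diagonal_inverse_variances(self, rng):
        S = random_spd(5, rng)
        lam = 1.1 * np.abs(S - np.diag(np.diag(S))).max()
        res = graphical_lasso(S, lam, tol=1e-10)
        assert np.allclose(res.precision, np.diag(1.0 / np.diag(S)), atol=1e-8)

    def test_zero_penalty_recovers_matrix_inverse(self, rng):
        S = random_spd(6, rng)
        res = graphical_lasso(S, 0.0, tol=1e-10)
        assert np.allclose(res.precision, np.linalg.inv(S), atol=1e-7)

    @pytest.mark.parametrize("p,lam", [(3, 0.1), (5, 0.05), (8, 0.2), (10, 0.02)])
    def test_kkt_conditions_and_spd(self, rng, p, lam):
        S = random_spd(p, rng)
        res = graphical_lasso(S, lam, tol=1e-10)
        assert np.linalg.eigvalsh(res.precision).min() > 0
        assert glasso_kkt_gap(res.precision, S, lam) < 1e-6

    def test_objective_matches_admm_oracle(self, rng):
        for p in (3, 5, 8):
            S = random_spd(p, rng)
            lam = 0.1
            mine = graphical_lasso(S, lam, tol=1e-10)
            oracle = admm_graphical_lasso(S, lam)
            f_mine = glasso_objective(mine.precision, S, lam)
            f_oracle = glasso_objective(oracle, S, lam)
            assert abs(f_mine - f_oracle) < 1e-6

    def test_objective_matches_sklearn(self, rng):
        from sklearn.covariance import graphical_lasso as sk_glasso

        S = random_spd(5, rng)
        lam = 0.08
        mine = graphical_lasso(S, lam, tol=1e-10)
        with np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, prec = sk_glasso(S, alpha=lam, tol=1e-10, max_iter=5000)
        assert glasso_objective(mine.precision, S, lam) <= (
            glasso_objective(prec, S, lam) + 1e-6
        )

    def test_sparsity_non_increasing_in_penalty(self, rng):
        S = random_spd(8, rng)
        nnz = []
        for lam in np.logspace(-3, 0.3, 8):
            res = graphical_lasso(S, float(lam), tol=1e-9)
            off = res.precision[~np.eye(8, dtype=bool)]
            nnz.append(int(np.count_nonzero(off)))
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))

    def test_nonconvergence_reported(self, rng):
        S = random_spd(6, rng)
        with pytest.raises(ConvergenceError, match="relative change"):
            graphical_lasso(S, 0.01, tol=1e-14, max_iter=1)
        res = graphical_lasso(
            S, 0.01, tol=1e-14, max_iter=1, raise_on_nonconvergence=False
        )
        assert not res.converged

    def test_invalid_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            graphical_lasso(np.array([[1.0, 2.0], [0.0, 1.0]]), 0.1)
        with pytest.raises(ValueError):
            graphical_lasso(np.array([[0.0, 0.1], [0.1, 0.0]]), 0.1)


class TestInteractions:
    def test_identity_precision_gives_empty_network(self):
        net = interactions_from_precision(np.eye(3), ["a", "b", "c"])
        assert net.sparsity == 1.0
        assert np.all(net.weights == 0)

    def test_sign_flip_by_definition(self):
        Theta = np.array([[1.0, -0.5], [-0.5, 1.0]])
        net = interactions_from_precision(Theta, ["a", "b"])
        assert net.weights[0, 1] == 0.5

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            interactions_from_precision(np.eye(3), ["a", "b"])

    def test_support_recovery_improves_with_samples(self):
        spec = PrecisionSpec(n_genes=30, edge_density=0.1, seed=5)
        theta = generate_sparse_precision(spec)
        truth = theta[np.triu_indices(30, k=1)] != 0

        def f1_at(n, seed):
            expr = sample_expression(theta, n, seed=seed)
            net = infer_network(expr, penalty=0.02, tol=1e-8)
            est = net.weights[np.triu_indices(30, k=1)] != 0
            tp = np.sum(est & truth)
            prec = tp / max(est.sum(), 1)
            rec = tp / truth.sum()
            return 0.0 if tp == 0 else 2 * prec * rec / (prec + rec)

        f1_small = np.mean([f1_at(200, s) for s in range(3)])
        f1_large = np.mean([f1_at(5000, s) for s in range(3)])
        assert f1_large > f1_small

    def test_identity_covariance_data_gives_near_empty_network(self):
        expr = sample_expression(np.eye(20), 20000, seed=1)
        net = infer_network(expr, penalty=0.05, tol=1e-8)
        assert net.sparsity > 0.95


class TestModelLogDensity:
    def model(self, cov, mean=None, ids=None):
        cov = np.atleast_2d(np.asarray(cov, dtype=float))
        L = cov.shape[0]
        return CovarianceModel(
            gene_ids=ids or [f"g{i}" for i in range(L)],
            mean=np.zeros(L) if mean is None else mean,
            covariance=cov,
            n_samples_used=10,
        )

    def test_standard_normal_at_mode(self):
        val = model_log_density(self.model([[1.0]]), np.array([0.0]))
        assert val == pytest.approx(np.log(1.0 / np.sqrt(2 * np.pi)))

    def test_matches_scipy_multivariate_normal(self, rng):
        cov = random_spd(4, rng)
        mean = rng.standard_normal(4)
        x = rng.standard_normal(4)
        mine = model_log_density(self.model(cov, mean=mean), x)
        ref = stats.multivariate_normal(mean=mean, cov=cov).logpdf(x)
        assert mine == pytest.approx(ref)

    def test_density_integrates_to_one_in_2d(self, rng):
        cov = np.array([[1.0, 0.4], [0.4, 0.8]])
        m = self.model(cov)
        total, _ = integrate.dblquad(
            lambda y, x: np.exp(model_log_density(m, np.array([x, y]))),
            -8, 8, -8, 8,
        )
        assert total == pytest.approx(1.0, abs=1e-3)

    def test_translation_invariance(self, rng):
        cov = random_spd(3, rng)
        x = rng.standard_normal(3)
        shift = rng.standard_normal(3)
        mean = rng.standard_normal(3)
        a = model_log_density(self.model(cov, mean=mean), x)
        b = model_log_density(self.model(cov, mean=mean + shift), x + shift)
        assert a == pytest.approx(b)

    def test_singular_covariance_rejected(self):
        m = CovarianceModel(
            gene_ids=["a", "b"],
            mean=np.zeros(2),
            covariance=np.array([[1.0, 1.0], [1.0, 1.0]]) + np.eye(2) * 1e-300,
            n_samples_used=5,
        )
        with pytest.raises((ValueError, np.linalg.LinAlgError)):
            model_log_density(m, np.zeros(2))


class TestPenaltySelection:
    def test_heuristic_returns_grid_value_and_is_deterministic(self):
        spec = PrecisionSpec(n_genes=10, edge_density=0.2, seed=2)
        theta = generate_sparse_precision(spec)
        expr = sample_expression(theta, 400, seed=2)
        grid = np.logspace(-2, -0.5, 4)
        pen1 = select_penalty(expr, grid=grid, seed=7)
        pen2 = select_penalty(expr, grid=grid, seed=7)
        assert pen1 == pen2
        assert pen1 in grid
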