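"""Objective, gradients, sigma profile, loading constraint, fit, Laplace."""

import numpy as np
import pytest
from scipy.integrate import quad

from scinsight2 import (
    ModelParams,
    constrain_loadings,
    fit,
    gradients,
    laplace_marginal_loglik,
    objective,
    update_sigma,
)
from scinsight2.estimation import FitOptions
from scinsight2.model_core import SIGMA_FLOOR, ExpressionDataset

from conftest import make_model_dataset


def _random_instance(seed, N=4, M=3, D=2, P=2, sigma=0.7):
    rng = np.random.default_rng(seed)
    Y = rng.poisson(2.0, (N, M))
    X = rng.normal(size=(N, D))
    data = ExpressionDataset(
        counts=Y + (Y.sum(axis=1) == 0)[:, None],  # avoid zero-count cells
        cell_ids=np.arange(N).astype(str),
        gene_ids=np.arange(M).astype(str),
        sample_of_cell=np.zeros(N),
    )
    params = ModelParams(
        beta0=rng.normal(0, 0.5, M),
        B=rng.normal(0, 0.5, (D, M)),
        Lambda=constrain_loadings(rng.normal(0, 0.5, (P, M))),
        sigma=sigma,
        U=rng.normal(0, 0.5, (N, P)),
    )
    return params, data, X


def _scalar_objective(params, data, X):
    """Independent scalar-loop evaluation of Q (the brute-force oracle)."""
    Y = data.dense_counts()
    s = data.size_factors
    N, M = Y.shape
    total = 0.0
    for i in range(N):
        for j in range(M):
            eta = params.beta0[j] + np.log(s[i])
            for d in range(X.shape[1]):
                eta += X[i, d] * params.B[d, j]
            for q in range(params.P):
                eta += params.U[i, q] * params.Lambda[q, j]
            total += np.exp(eta) - Y[i, j] * eta
    for i in range(N):
        total += float(params.U[i] @ params.U[i]) / (2 * params.sigma**2)
    total += N * params.P * np.log(params.sigma)
    return total


class TestObjective:
    def test_all_zero_counts_all_zero_params(self):
        N, M = 2, 3
        data = ExpressionDataset(
            counts=np.zeros((N, M), dtype=int),
            cell_ids=["a", "b"],
            gene_ids=["g1", "g2", "g3"],
            sample_of_cell=["s", "s"],
            library_sizes=np.ones(N, dtype=int),  # placeholder so s_i = 1
        )
        p = ModelParams(beta0=np.zeros(M), B=np.zeros((0, M)),
                        Lambda=np.zeros((1, M)), sigma=1.0, U=np.zeros((N, 1)))
        assert objective(p, data, np.zeros((N, 0))) == pytest.approx(N * M)

    def test_single_cell_single_gene(self):
        data = ExpressionDataset(
            counts=np.array([[1]]), cell_ids=["c"], gene_ids=["g"], sample_of_cell=["s"]
        )
        p = ModelParams(beta0=np.zeros(1), B=np.zeros((0, 1)),
                        Lambda=np.zeros((1, 1)), sigma=1.0, U=np.zeros((1, 1)))
        assert objective(p, data, np.zeros((1, 0))) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_scalar_loop_oracle(self, seed):
        params, data, X = _random_instance(seed)
        assert objective(params, data, X) == pytest.approx(
            _scalar_objective(params, data, X), rel=1e-10
        )

    def test_rejects_nonpositive_sigma(self):
        params, data, X = _random_instance(0)
        with pytest.raises(ValueError):
            ModelParams(beta0=params.beta0, B=params.B, Lambda=params.Lambda,
                        sigma=0.0, U=params.U)


class TestGradients:
    @pytest.mark.parametrize("seed", range(20))
    def test_match_finite_differences(self, seed):
        params, data, X = _random_instance(seed)
        g = gradients(params, data, X)
        h = 1e-6

        def q_at(**over):
            kw = dict(beta0=params.beta0, B=params.B, Lambda=params.Lambda,
                      sigma=params.sigma, U=params.U)
            kw.update(over)
            return objective(ModelParams(**kw), data, X)

        # a few randomly chosen coordinates per block
        rng = np.random.default_rng(1000 + seed)
        for name, arr in [("beta0", params.beta0), ("B", params.B), ("U", params.U)]:
            flat_idx = rng.choice(arr.size, size=min(4, arr.size), replace=False)
            for fi in flat_idx:
                idx = np.unravel_index(fi, arr.shape)
                up, dn = arr.copy(), arr.copy()
                up[idx] += h
                dn[idx] -= h
                fd = (q_at(**{name: up}) - q_at(**{name: dn})) / (2 * h)
                an = g[name][idx] if arr.ndim > 1 else g[name][idx[0]]
                assert an == pytest.approx(fd, rel=1e-5, abs=1e-6)
        # free entries of Lambda (upper block / beyond leading block)
        P, M = params.Lambda.shape
        for p_ in range(P):
            for m in range(M):
                if p_ > m:
                    assert g["Lambda"][p_, m] == 0.0
                    continue
                up, dn = params.Lambda.copy(), params.Lambda.copy()
                up[p_, m] += h
                dn[p_, m] -= h
                fd = (q_at(Lambda=up) - q_at(Lambda=dn)) / (2 * h)
                assert g["Lambda"][p_, m] == pytest.approx(fd, rel=1e-5, abs=1e-6)

    def test_poisson_intercept_mle_is_stationary(self):
        rng = np.random.default_rng(3)
        Y = rng.poisson(4.0, (30, 5))
        Y[Y.sum(axis=1) == 0, 0] = 1
        data = ExpressionDataset(
            counts=Y, cell_ids=np.arange(30).astype(str),
            gene_ids=np.arange(5).astype(str), sample_of_cell=np.zeros(30),
            library_sizes=np.ones(30, dtype=int),
        )
        beta0 = np.log(Y.mean(axis=0))
        p = ModelParams(beta0=beta0, B=np.zeros((0, 5)), Lambda=np.zeros((1, 5)),
                        sigma=1.0, U=np.zeros((30, 1)))
        g = gradients(p, data, np.zeros((30, 0)))
        np.testing.assert_allclose(g["beta0"], 0.0, atol=1e-8)

    def test_zero_counts_push_intercepts_down(self):
        data = ExpressionDataset(
            counts=np.zeros((3, 2), dtype=int), cell_ids=list("abc"),
            gene_ids=list("gh"), sample_of_cell=list("sss"),
            library_sizes=np.ones(3, dtype=int),
        )
        p = ModelParams(beta0=np.zeros(2), B=np.zeros((0, 2)), Lambda=np.zeros((1, 2)),
                        sigma=1.0, U=np.zeros((3, 1)))
        g = gradients(p, data, np.zeros((3, 0)))
        assert np.all(g["beta0"] > 0)


class TestUpdateSigma:
    def test_zero_embeddings_hit_floor(self):
        assert update_sigma(np.zeros((5, 2))) == SIGMA_FLOOR

    def test_hand_example(self):
        assert update_sigma(np.array([[3.0, 4.0]])) == pytest.approx(np.sqrt(12.5))

    def test_homogeneous_in_scale(self):
        rng = np.random.default_rng(0)
        U = rng.normal(size=(7, 3))
        assert update_sigma(3 * U) == pytest.approx(3 * update_sigma(U))

    @pytest.mark.parametrize("seed", [0, 5])
    def test_is_exact_minimizer_of_q(self, seed):
        params, data, X = _random_instance(seed)
        s_star = update_sigma(params.U)

        def q(sig):
            return objective(
                ModelParams(beta0=params.beta0, B=params.B, Lambda=params.Lambda,
                            sigma=sig, U=params.U),
                data, X,
            )

        q0 = q(s_star)
        assert q(1.01 * s_star) >= q0
        assert q(0.99 * s_star) >= q0


class TestConstrainLoadings:
    def test_below_diagonal_zeroed(self):
        raw = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        out = constrain_loadings(raw)
        assert out[1, 0] == 0.0
        assert out[0, 1] == 2.0 and out[0, 2] == 3.0 and out[1, 2] == 6.0

    def test_diagonal_positive_for_any_input(self):
        rng = np.random.default_rng(0)
        out = constrain_loadings(rng.normal(0, 10, (3, 5)))
        assert np.all(np.diag(out[:, :3]) > 0)

    def test_fixed_point_off_diagonal(self):
        out1 = constrain_loadings(np.array([[0.5, -1.0], [9.9, 2.0]]))
        out2 = constrain_loadings(out1)
        # off-diagonal entries are unchanged by a second application
        assert out2[0, 1] == out1[0, 1]
        assert out2[1, 0] == 0.0


class TestFit:
    def test_deterministic_for_fixed_seed(self, tiny_truth):
        opts = FitOptions(max_epochs=50)
        r1 = fit(tiny_truth.dataset, tiny_truth.design, P=2, seed=9, opts=opts)
        r2 = fit(tiny_truth.dataset, tiny_truth.design, P=2, seed=9, opts=opts)
        np.testing.assert_array_equal(r1.objective_trace, r2.objective_trace)
        np.testing.assert_array_equal(r1.params.U, r2.params.U)

    def test_trace_monotone_within_slack(self, tiny_truth):
        r = fit(tiny_truth.dataset, tiny_truth.design, P=2, seed=9,
                opts=FitOptions(max_epochs=300))
        t = r.objective_trace
        assert np.all(np.isfinite(t))
        assert np.all(t[1:] <= t[:-1] + 1e-8 * np.abs(t[:-1]))

    def test_loading_constraint_holds_at_optimum(self, tiny_truth):
        r = fit(tiny_truth.dataset, tiny_truth.design, P=2, seed=9,
                opts=FitOptions(max_epochs=50))
        assert r.params.check_loading_constraint()

    def test_parameter_recovery_and_null_shrinkage(self, model_dataset):
        data, truth = model_dataset
        r = fit(data, truth["X"], P=2, seed=3)
        Bh = r.params.B
        Bt = truth["B_true"]
        for key, row in (("cont", 0), ("binary", 1)):
            genes = truth["affected"][key]
            corr = np.corrcoef(Bh[row, genes], Bt[row, genes])[0, 1]
            assert corr > 0.9
            agree = np.mean(np.sign(Bh[row, genes]) == np.sign(Bt[row, genes]))
            assert agree > 0.95
        aff_mag = np.mean(
            [np.mean(np.abs(Bh[r_, truth["affected"][k]])) for k, r_ in (("cont", 0), ("binary", 1))]
        )
        null_mag = np.mean(np.abs(Bh[truth["null_row"]]))
        assert null_mag < 0.1 * aff_mag

    def test_coefficient_rmse_decreases_with_n(self):
        rmses = []
        for cells in (15, 60):  # N = 150 vs 600 cells over 10 subjects
            data, truth = make_model_dataset(seed=21, cells_per_subject=cells)
            r = fit(data, truth["X"], P=2, seed=5)
            g = truth["affected"]["cont"]
            rmses.append(
                float(np.sqrt(np.mean((r.params.B[0, g] - truth["B_true"][0, g]) ** 2)))
            )
        assert rmses[1] < rmses[0]

    def test_rejects_invalid_p(self, tiny_truth):
        with pytest.raises(ValueError):
            fit(tiny_truth.dataset, tiny_truth.design, P=0, seed=0)


class TestLaplace:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_agrees_with_quadrature(self, seed):
        rng = np.random.default_rng(seed)
        M = 3
        params = ModelParams(
            beta0=np.log(100.0) + rng.normal(0, 0.3, M),
            B=np.zeros((1, M)),
            Lambda=constrain_loadings(rng.normal(0, 0.4, (1, M))),
            sigma=0.8,
            U=np.zeros((1, 1)),
        )
        y = rng.poisson(100.0, M).astype(float)
        approx, internals = laplace_marginal_loglik(params, y, np.zeros(1), 1.0)
        base = params.beta0
        L = params.Lambda
        shift = float(np.sum(y * (base + internals.u_tilde @ L) - internals.W_tilde))

        def integrand(u):
            eta = base + u * L[0]
            return float(np.exp(np.sum(y * eta - np.exp(eta)) - shift
                                - u * u / (2 * params.sigma**2)))

        val, _ = quad(integrand, -8, 8, points=[internals.u_tilde.item()], limit=200)
        exact = (np.log(val) + shift - 0.5 * np.log(2 * np.pi) - np.log(params.sigma))
        assert abs(approx - exact) < 1e-3

    def test_logdet_term_relatively_smaller_for_more_genes(self):
        rng = np.random.default_rng(7)
        ratios = []
        for M in (10, 200):
            params = ModelParams(
                beta0=rng.normal(0.5, 0.3, M), B=np.zeros((0, M)),
                Lambda=constrain_loadings(rng.normal(0, 0.5, (1, M))),
                sigma=0.8, U=np.zeros((1, 1)),
            )
            y = rng.poisson(3.0, M).astype(float)
            _, it = laplace_marginal_loglik(params, y, np.zeros(0), 1.0)
            fit_term = float(np.sum(y * (params.beta0 + it.u_tilde @ params.Lambda) - it.W_tilde))
            ratios.append(abs(it.logdet_term) / abs(fit_term))
        assert ratios[1] < ratios[0]

    def test_exact_for_zero_loadings(self):
        params = ModelParams(
            beta0=np.array([0.1, 0.2]), B=np.zeros((0, 2)),
            Lambda=np.array([[0.0, 0.0]]), sigma=1.0, U=np.zeros((1, 1)),
        )
        y = np.array([1.0, 2.0])
        approx, internals = laplace_marginal_loglik(params, y, np.zeros(0), 1.0)
        # with Lambda = 0 the integrand is Gaussian: u~ = 0 and the
        # approximation equals sum(y eta - mu) exactly
        np.testing.assert_allclose(internals.u_tilde, 0.0)
        mu = np.exp(params.beta0)
        assert approx == pytest.approx(float(np.sum(y * params.beta0 - mu)), abs=1e-12)
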