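"""Backfitting blocks, tuning selection, and the ridge/two-stage estimators."""

import numpy as np
import pytest
from scipy.optimize import minimize

from ncrm.assembly import assemble_operators, combine_sigma, compute_R
from ncrm.data import FunctionalDataset, uniform_grid
from ncrm.kernels import build_decomposition, k1
from ncrm.solver import (
    _project_budget,
    backfit,
    fit_L1_L2,
    fit_L2,
    objective_value,
    predict_f,
    select_tuning,
    threshold_selected,
    update_c,
    update_d,
    update_theta,
)
from ncrm.fpca import project_scores
from ncrm.simulation import gen_covariates


def _random_psd(rng, m):
    A = rng.normal(size=(m, m))
    return A @ A.T / m


class TestUpdateC:
    def test_zero_residual_gives_zero(self, rng):
        m = 6
        Sigma = _random_psd(rng, m)
        T = rng.normal(size=(m, 2))
        d = rng.normal(size=2)
        c = update_c(T @ d, T, d, Sigma, 0.1, 2)
        np.testing.assert_allclose(c, 0.0, atol=1e-9)

    def test_large_penalty_shrinks(self, rng):
        m = 6
        Sigma = _random_psd(rng, m)
        Y = rng.normal(size=m)
        norms = [
            np.linalg.norm(update_c(Y, np.zeros((m, 2)), np.zeros(2), Sigma, tau, 2))
            for tau in (1e-3, 1e-1, 1e1, 1e3)
        ]
        assert all(a > b for a, b in zip(norms, norms[1:]))

    def test_minimizes_c_block_objective(self, rng):
        m = 4
        n = 2
        Sigma = _random_psd(rng, m)
        Y = rng.normal(size=m)
        tau0 = 0.05

        def obj(c):
            r = Y - Sigma @ c
            return r @ r / n + tau0 * c @ Sigma @ c

        c_hat = update_c(Y, np.zeros((m, 2)), np.zeros(2), Sigma, tau0, n)
        res = minimize(obj, np.zeros(m), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000})
        assert obj(c_hat) <= res.fun + 1e-8


class TestUpdateD:
    def test_ols_when_unpenalized(self, rng):
        T = rng.normal(size=(20, 2))
        Y = rng.normal(size=20)
        d = update_d(Y, T, 0.0, (0.0, 1.0), 5)
        np.testing.assert_allclose(d, np.linalg.lstsq(T, Y, rcond=None)[0], atol=1e-10)

    def test_huge_penalty_kills_penalized_coef(self, rng):
        t = uniform_grid(30)
        T = np.column_stack([np.ones(30), k1(t)])
        Y = rng.normal(size=30) + 2.0
        d = update_d(Y, T, 1e6, (0.0, 1.0), 5)
        assert d[1] == 0.0
        # unpenalized constant falls back to its OLS value given d2 = 0
        assert d[0] == pytest.approx(
            np.linalg.lstsq(T[:, :1], Y, rcond=None)[0][0], abs=1e-8
        )

    def test_matches_grid_search_orthonormal(self, rng):
        # orthonormal columns: the weighted lasso has a soft-threshold form
        T = np.linalg.qr(rng.normal(size=(40, 2)))[0]
        Y = rng.normal(size=40)
        n, lam1, w1 = 4, 0.3, (0.7, 1.3)
        d_hat = update_d(Y, T, lam1, w1, n)

        def obj(d):
            r = Y - T @ d
            return r @ r / n + lam1 * (w1[0] * abs(d[0]) + w1[1] * abs(d[1]))

        grid = np.linspace(-3, 3, 1201)
        best = min(
            (obj(np.array([a, b])), a, b)
            for a in grid
            for b in grid[np.abs(grid - d_hat[1]) < 0.05]
        )
        assert obj(d_hat) <= best[0] + 1e-8


class TestProjectBudget:
    @pytest.mark.parametrize("seed", range(5))
    def test_projection_optimality(self, seed):
        rng = np.random.default_rng(seed)
        Q = 8
        y = rng.normal(size=Q) * 3
        w = rng.uniform(0.5, 2.0, size=Q)
        M = 2.0
        p = _project_budget(y, w, M)
        assert np.all(p >= 0) and w @ p <= M + 1e-9
        # no random feasible point is closer to y
        dist = np.sum((p - y) ** 2)
        for _ in range(500):
            z = rng.uniform(0, 1, size=Q)
            z *= M / max(w @ z, 1e-12) * rng.uniform()
            assert np.sum((z - y) ** 2) >= dist - 1e-9

    def test_interior_point_unchanged(self):
        y = np.array([0.1, 0.2])
        assert np.array_equal(_project_budget(y, np.ones(2), 10.0), y)


class TestUpdateTheta:
    def test_zero_budget(self, rng):
        R = rng.normal(size=(6, 3))
        th = update_theta(rng.normal(size=6), np.zeros((6, 2)), np.zeros(2), R,
                          0.1, rng.normal(size=6), 0.0, np.ones(3), 2)
        assert np.array_equal(th, np.zeros(3))

    def test_scalar_closed_form(self, rng):
        # Q = 1: quadratic vertex clipped to [0, M / w2]
        nK, n = 12, 3
        R = rng.normal(size=(nK, 1))
        Y = rng.normal(size=nK)
        c = rng.normal(size=nK)
        tau0 = 0.05
        for M in (10.0, 0.02):
            th = update_theta(Y, np.zeros((nK, 2)), np.zeros(2), R, tau0, c, M,
                              np.ones(1), n)[0]
            a = float(R[:, 0] @ R[:, 0]) / n
            b = 2.0 * float(R[:, 0] @ Y) / n - tau0 * float(R[:, 0] @ c)
            expected = np.clip(b / (2 * a), 0.0, M)
            assert th == pytest.approx(expected, abs=1e-8)

    def test_beats_random_feasible_points(self, rng):
        nK, Q, n = 10, 4, 2
        R = rng.normal(size=(nK, Q))
        Y = rng.normal(size=nK) * 2
        c = rng.normal(size=nK)
        tau0, M = 0.1, 1.5
        w2 = np.ones(Q)

        def obj(th):
            r = Y - R @ th
            return r @ r / n + tau0 * c @ R @ th

        th = update_theta(Y, np.zeros((nK, 2)), np.zeros(2), R, tau0, c, M, w2, n)
        assert np.all(th >= 0) and w2 @ th <= M + 1e-8
        best = obj(th)
        for _ in range(1000):
            z = rng.uniform(size=Q)
            z *= rng.uniform() * M / max(w2 @ z, 1e-12)
            assert obj(z) >= best - 1e-9

    def test_negative_budget_rejected(self, rng):
        with pytest.raises(ValueError):
            update_theta(np.zeros(4), np.zeros((4, 2)), np.zeros(2),
                         rng.normal(size=(4, 2)), 0.1, np.zeros(4), -1.0,
                         np.ones(2), 2)


def test_threshold_selected():
    assert threshold_selected(np.zeros(5)) == []
    assert threshold_selected(np.array([4.157, 0.819, 0.0, 0.0])) == [1, 2]
    assert threshold_selected(np.full(4, 0.3)) == [1, 2, 3, 4]
    # solver fuzz below the relative cut is ignored
    assert threshold_selected(np.array([5.0, 4e-6, 0.0])) == [1]


@pytest.fixture(scope="module")
def null_space_mats():
    """Noiseless data from the unpenalized space: y = 2 + 1.5 k1(t)."""
    t, s = uniform_grid(15), uniform_grid(8)
    rng = np.random.default_rng(11)
    x = gen_covariates(6, t, s, rng)
    y = np.tile(2.0 + 1.5 * k1(t), (6, 1))
    data = FunctionalDataset(t, s, x, y)
    return assemble_operators(data, build_decomposition(2, "full_q2"))


class TestBackfit:
    def test_null_space_recovery(self, null_space_mats):
        fit = backfit(null_space_mats, 0.0, 1e-2, 3.0)
        assert fit.selected == []
        assert fit.d[0] == pytest.approx(2.0, abs=1e-3)
        assert fit.d[1] == pytest.approx(1.5, abs=1e-3)

    def test_monotone_objective_trace(self, tiny_dataset):
        mats = assemble_operators(tiny_dataset, build_decomposition(2, "full_q2"))
        fit = backfit(mats, 0.0, 1e-3, 5.0, max_iter=40)
        trace = np.array(fit.trace)
        assert np.all(np.diff(trace) <= 1e-9 * np.maximum(1.0, np.abs(trace[:-1])))

    def test_deterministic(self, tiny_dataset):
        mats = assemble_operators(tiny_dataset, build_decomposition(2, "full_q2"))
        f1 = backfit(mats, 0.0, 1e-2, 2.0)
        f2 = backfit(mats, 0.0, 1e-2, 2.0)
        np.testing.assert_array_equal(f1.theta, f2.theta)
        np.testing.assert_array_equal(f1.c, f2.c)
        np.testing.assert_array_equal(f1.d, f2.d)

    def test_budget_respected(self, tiny_dataset):
        mats = assemble_operators(tiny_dataset, build_decomposition(2, "full_q2"))
        for M in (0.5, 2.0, 8.0):
            fit = backfit(mats, 0.0, 1e-3, M)
            assert fit.theta.min() >= 0.0
            assert mats.scheme.w2 @ fit.theta <= M + 1e-8

    def test_matches_generic_optimizer_tiny(self):
        """Final objective agrees with a multi-start generic minimizer on a
        tiny instance (n=2, K=1, Q=2 active dimensions of the scheme)."""
        t, s = uniform_grid(5), uniform_grid(4)
        rng = np.random.default_rng(21)
        x = rng.normal(size=(2, 2, 5, 4))
        y = rng.normal(size=(2, 5))
        data = FunctionalDataset(t, s, x, y)
        mats = assemble_operators(data, build_decomposition(2, "full_q2"), efpc_K=1)
        # restrict to two components to keep the search space small
        mats.Sigmas = mats.Sigmas[:2]
        scheme = mats.scheme
        scheme.components = scheme.components[:2]
        scheme.w2 = scheme.w2[:2]
        lam1, tau0, M = 0.05, 1e-2, 1.5
        fit = backfit(mats, lam1, tau0, M, tol=1e-10, max_iter=500)
        obj_fit = objective_value(mats, fit.d, fit.c, fit.theta, lam1, tau0,
                                  (0.0, 1.0), scheme.w2)

        nK = mats.Y.shape[0]

        def full_obj(z):
            d, c, th_raw = z[:2], z[2 : 2 + nK], z[2 + nK :]
            th = np.abs(th_raw)
            if th.sum() > M:
                th = th * (M / th.sum())
            return objective_value(mats, d, c, th, lam1, tau0, (0.0, 1.0), scheme.w2)

        best = np.inf
        gen = np.random.default_rng(0)
        for _ in range(20):
            z0 = gen.normal(size=2 + nK + 2)
            res = minimize(full_obj, z0, method="Nelder-Mead",
                           options={"maxiter": 40000, "xatol": 1e-9, "fatol": 1e-12})
            best = min(best, res.fun)
        assert obj_fit <= best + 1e-6

    def test_scaling_equivariance(self, tiny_dataset):
        """Scaling y by a scales d, c and predictions by a at fixed (tau0, M)
        when lambda1 is scaled by a as well."""
        scheme = build_decomposition(2, "full_q2")
        a = 3.0
        mats1 = assemble_operators(tiny_dataset, scheme)
        data2 = FunctionalDataset(
            tiny_dataset.t_grid, tiny_dataset.s_grid, tiny_dataset.x,
            a * tiny_dataset.y,
        )
        mats2 = assemble_operators(data2, scheme)
        lam1, tau0, M = 0.01, 1e-2, 2.0
        f1 = backfit(mats1, lam1, tau0, M, tol=1e-9, max_iter=500)
        f2 = backfit(mats2, a * lam1, tau0, M, tol=1e-9, max_iter=500)
        np.testing.assert_allclose(f2.d, a * f1.d, rtol=1e-3, atol=1e-6)
        np.testing.assert_allclose(f2.theta, f1.theta, rtol=2e-2, atol=1e-4)
        p1 = predict_f(f1, mats1, tiny_dataset.x)
        p2 = predict_f(f2, mats2, tiny_dataset.x)
        np.testing.assert_allclose(p2, a * p1, rtol=1e-2, atol=1e-4)


class TestPredictConsistency:
    def test_representer_matches_matrices_on_training_data(self, tiny_dataset):
        """Projecting predicted training curves onto the basis reproduces
        T d + Sigma(theta) c."""
        mats = assemble_operators(tiny_dataset, build_decomposition(2, "full_q2"))
        fit = backfit(mats, 0.0, 1e-3, 4.0)
        f_hat = predict_f(fit, mats, tiny_dataset.x)
        nu_hat = project_scores(mats.basis, f_hat)  # (n, K)
        expected_vec = mats.T @ fit.d + combine_sigma(
            mats.Sigmas, fit.theta, mats.scheme.w2
        ) @ fit.c
        n, K = mats.n, mats.K
        expected = expected_vec.reshape(K, n).T
        np.testing.assert_allclose(nu_hat, expected, atol=1e-6)

    def test_theta_zero_ignores_covariates(self, tiny_dataset, rng):
        mats = assemble_operators(tiny_dataset, build_decomposition(2, "full_q2"))
        fit = backfit(mats, 0.0, 1e-2, 0.0)
        x_other = rng.normal(size=tiny_dataset.x.shape)
        p1 = predict_f(fit, mats, tiny_dataset.x)
        p2 = predict_f(fit, mats, x_other)
        np.testing.assert_array_equal(p1, p2)


@pytest.fixture(scope="module")
def small_signal_mats():
    t, s = uniform_grid(12), uniform_grid(8)
    rng = np.random.default_rng(33)
    x = gen_covariates(10, t, s, rng)
    y = 1.0 + np.sin(2 * np.pi * t)[None, :] + 0.1 * rng.normal(size=(10, 12))
    data = FunctionalDataset(t, s, x, y)
    return assemble_operators(data, build_decomposition(2, "full_q2"), efpc_K=4)


class TestFitL2:
    def test_reports_all_components(self, small_signal_mats):
        fit = fit_L2(small_signal_mats, lambda_grid=(1e-3,))
        assert fit.selected == list(range(1, 11))
        assert fit.method == "l2"

    def test_large_lambda_approaches_null_space(self, small_signal_mats):
        mats = small_signal_mats
        fit = fit_L2(mats, lambda_grid=(1e8,))
        Sigma = combine_sigma(mats.Sigmas, np.ones(10), mats.scheme.w2)
        assert np.linalg.norm(Sigma @ fit.c) < 1e-4

    def test_small_lambda_interpolates_tiny_problem(self):
        t, s = uniform_grid(8), uniform_grid(5)
        rng = np.random.default_rng(5)
        x = gen_covariates(3, t, s, rng)
        y = rng.normal(size=(3, 8))
        data = FunctionalDataset(t, s, x, y)
        mats = assemble_operators(data, build_decomposition(2, "full_q2"))
        fit = fit_L2(mats, lambda_grid=(1e-12,))
        resid = mats.Y - mats.T @ fit.d - combine_sigma(
            mats.Sigmas, np.ones(10), mats.scheme.w2
        ) @ fit.c
        assert np.linalg.norm(resid) / np.linalg.norm(mats.Y) < 1e-3


class TestFitL1L2:
    def test_empty_selection_is_null_space_fit(self, small_signal_mats):
        l1 = backfit(small_signal_mats, 0.0, 1e-2, 0.0)
        refit = fit_L1_L2(small_signal_mats, l1_fit=l1, lambda_grid=(1e-3,))
        assert refit.selected == []
        assert np.all(refit.c == 0.0)
        assert refit.method == "l1l2"

    def test_full_selection_equals_fit_l2(self, small_signal_mats):
        l1 = backfit(small_signal_mats, 0.0, 1e-2, 4.0)
        l1.selected = list(range(1, 11))
        refit = fit_L1_L2(small_signal_mats, l1_fit=l1, lambda_grid=(1e-3,))
        direct = fit_L2(small_signal_mats, lambda_grid=(1e-3,))
        np.testing.assert_allclose(refit.d, direct.d, atol=1e-10)
        np.testing.assert_allclose(refit.c, direct.c, atol=1e-10)


class TestSelectTuning:
    def test_single_point_grid(self, small_signal_mats):
        tuning = select_tuning(
            small_signal_mats,
            grids={"lambda1": (0.0,), "tau0": (1e-2,), "M": (2.0,)},
            folds=2,
            seed=0,
        )
        assert tuning["tau0"] == 1e-2 and tuning["M"] == 2.0

    def test_cv_scores_match_independent_recompute(self, small_signal_mats):
        from ncrm.solver import (
            _CV_MAX_ITER,
            _CV_TOL,
            _fold_operators,
            _subject_folds,
            _val_score,
        )

        mats = small_signal_mats
        grids = {"lambda1": (0.0,), "tau0": (1e-2,), "M": (1.0, 4.0)}
        tuning = select_tuning(mats, grids=grids, folds=3, seed=7)
        combos = tuning["cv"]["combos"]
        scores = tuning["cv"]["scores"]
        splits = _subject_folds(mats.n, 3, 7)
        acc = np.zeros(len(combos))
        for tr, va in splits:
            fm = _fold_operators(mats, tr)
            theta0 = d0 = None  # replicate the descending-M warm-start path
            for b in sorted(range(len(combos)), key=lambda b: -combos[b][2]):
                l1, t0, M = combos[b]
                fit = backfit(fm, l1, t0, M, theta0=theta0, d0=d0,
                              tol=_CV_TOL, max_iter=_CV_MAX_ITER)
                theta0, d0 = fit.theta, fit.d
                acc[b] += _val_score(mats, fm, tr, va, fit.d, fit.c, fit.theta)
        np.testing.assert_allclose(scores, acc / 3, rtol=1e-6)

    def test_empty_grid_rejected(self, small_signal_mats):
        with pytest.raises(ValueError):
            select_tuning(small_signal_mats, grids={"M": ()})
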