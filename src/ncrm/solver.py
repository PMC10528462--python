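"""Penalized least-squares solvers for the score-space problem.

The selection estimator minimizes

    (1/n) ||Y - T d - Sigma(theta) c||^2 + lambda1 sum_k w1_k |d_k|
        + tau0 c' Sigma(theta) c,   s.t.  theta >= 0,  w2' theta <= M,

by block backfitting: a ridge-type linear solve in ``c``, a two-coefficient
weighted lasso in ``d``, and a nonnegative budget-constrained quadratic
program in ``theta`` (reduced to nonnegative least squares, which returns
exact zeros at inactive components).  Each block step is an exact minimizer
of its block, so the objective is non-increasing across sweeps.

Also provided: the ridge estimator with all components kept (``fit_L2``),
the two-stage select-then-refit estimator (``fit_L1_L2``), and tuning
selection by subject-level k-fold cross-validation or BIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, lstsq
from sklearn.model_selection import KFold

from .assembly import (
    OperatorMatrices,
    assemble_operators,
    combine_sigma,
    compute_R,
    predict_curves,
    subset_factors,
)
from .fpca import project_scores

__all__ = [
    "FitResult",
    "update_c",
    "update_d",
    "update_theta",
    "backfit",
    "select_tuning",
    "fit_L2",
    "fit_L1_L2",
    "predict_f",
    "threshold_selected",
    "objective_value",
]

_JITTER = 1e-10
DEFAULT_W1 = (0.0, 1.0)  # constant phi_1 unpenalized
DEFAULT_TAU0_GRID = tuple(np.logspace(-4, -1, 7))
DEFAULT_M_FACTORS = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0)
DEFAULT_LAMBDA_GRID = tuple(np.logspace(-4, -1, 5))
SELECT_EPS = 1e-6
# sweep cap while *scoring* tuning candidates; the final fit runs to full
# convergence — CV only needs the relative ranking of candidates
_CV_MAX_ITER = 30
_CV_TOL = 1e-5


@dataclass
class FitResult:
    """Converged coefficients of one fit plus bookkeeping."""

    d: np.ndarray
    c: np.ndarray
    theta: np.ndarray
    tuning: dict
    selected: list[int]  # 1-based component indices
    labels: list[str]
    trace: list[float]
    converged: bool
    method: str
    scheme_id: str
    n: int
    K: int
    seed: int | None = None
    selection_fit: "FitResult | None" = field(default=None, repr=False)

    @property
    def selected_labels(self) -> list[str]:
        return [self.labels[v - 1] for v in self.selected]


def objective_value(mats: OperatorMatrices, d, c, theta, lambda1, tau0, w1, w2):
    """Budget-form objective at the given block coordinates."""
    c = np.asarray(c, float)
    Sigma_c = compute_R(mats.Sigmas, c, w2) @ np.asarray(theta, float)
    r = mats.Y - mats.T @ np.asarray(d, float) - Sigma_c
    pen_d = lambda1 * float(np.abs(np.asarray(d, float)) @ np.asarray(w1, float))
    pen_c = tau0 * float(c @ Sigma_c)
    return float(r @ r) / mats.n + pen_d + pen_c


def update_c(Y, T, d, Sigma_theta, tau0, n) -> np.ndarray:
    """Ridge-stabilized c-step: solve ``(Sigma + n tau0 I) c = Y - T d``.

    Equivalent to the normal equations of the c-block objective on the
    column space of ``Sigma``; a small diagonal jitter keeps the solve
    well-posed when ``Sigma`` is singular.
    """
    rhs = np.asarray(Y, float) - np.asarray(T, float) @ np.asarray(d, float)
    if not np.all(np.isfinite(rhs)):
        raise ValueError("non-finite values in the c-step right-hand side")
    A = Sigma_theta + (n * tau0 + _JITTER) * np.eye(Sigma_theta.shape[0])
    try:
        return cho_solve(
            cho_factor(A, lower=True, check_finite=False), rhs, check_finite=False
        )
    except np.linalg.LinAlgError:
        return lstsq(A, rhs)[0]


def _soft(z: float, t: float) -> float:
    return np.sign(z) * max(abs(z) - t, 0.0)


def update_d(Y_star, T, lambda1, w1, n) -> np.ndarray:
    """d-step: two-coefficient weighted lasso by coordinate descent."""
    Y_star = np.asarray(Y_star, float)
    T = np.asarray(T, float)
    w1 = np.asarray(w1, float)
    if lambda1 == 0.0:
        return lstsq(T, Y_star)[0]
    G = T.T @ T
    b = T.T @ Y_star
    d = np.zeros(2)
    for _ in range(200):
        d_old = d.copy()
        for j in range(2):
            if G[j, j] <= 0:
                d[j] = 0.0
                continue
            r_j = b[j] - G[j, 1 - j] * d[1 - j]
            d[j] = _soft(r_j, 0.5 * n * lambda1 * w1[j]) / G[j, j]
        if np.max(np.abs(d - d_old)) < 1e-13 * max(1.0, float(np.max(np.abs(d)))):
            break
    return d


def _project_budget(y: np.ndarray, w: np.ndarray, M: float) -> np.ndarray:
    """Euclidean projection onto ``{theta >= 0, w' theta <= M}`` (w > 0)."""
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    yp = np.maximum(y, 0.0)
    if float(w @ yp) <= M:
        return yp
    # budget binds: theta_v = max(0, y_v - mu w_v) with mu > 0 solving
    # sum_v w_v max(0, y_v - mu w_v) = M (piecewise linear, decreasing)
    ratios = y / w
    order = np.argsort(ratios)[::-1]
    ws, ys, rs = w[order], y[order], ratios[order]
    cw2 = np.cumsum(ws * ws)
    cwy = np.cumsum(ws * ys)
    mu = (cwy[-1] - M) / cw2[-1]
    for m in range(len(y)):
        mu_m = (cwy[m] - M) / cw2[m]
        next_r = rs[m + 1] if m + 1 < len(y) else -np.inf
        if next_r <= mu_m <= rs[m]:
            mu = mu_m
            break
    theta = np.maximum(y - mu * w, 0.0)
    tot = float(w @ theta)
    if tot > M > 0:  # round-off safeguard
        theta *= M / tot
    return theta


def update_theta(Y, T, d, R, tau0, c, M, w2, n: int, theta0=None) -> np.ndarray:
    """theta-step: nonnegative, budget-constrained quadratic program.

    Minimizes ``(1/n) ||Y - Td - R theta||^2 + tau0 c' R theta`` over
    ``theta >= 0`` with ``w2' theta <= M``.  Completing the square turns
    the objective into the nonnegative least squares problem
    ``||(Y - Td - (n tau0 / 2) c~) - R theta||^2`` with
    ``c~`` entering through ``R' c``; it is solved with compiled NNLS,
    which returns exact zeros at inactive components.  When the
    unconstrained-budget solution violates the budget, the optimum sits on
    ``w2' theta = M`` and is recovered by re-solving with an escalating
    quadratic penalty row enforcing the budget equality.
    """
    from scipy.optimize import nnls

    R = np.asarray(R, float)
    w2 = np.asarray(w2, float)
    Q = R.shape[1]
    if M < 0:
        raise ValueError("budget M must be nonnegative")
    if M == 0.0:
        return np.zeros(Q)
    r = np.asarray(Y, float) - np.asarray(T, float) @ np.asarray(d, float)
    # linear term tau0 c'R theta folded into the NNLS right-hand side
    r_tilde = r - 0.5 * n * tau0 * np.asarray(c, float)
    # degenerate case: no component carries signal beyond round-off
    scale_ref = max(float(np.linalg.norm(Y)), 1.0)
    if float(np.linalg.norm(R)) <= 1e-12 * scale_ref:
        return np.zeros(Q)
    theta, _ = nnls(R, r_tilde)
    if float(w2 @ theta) <= M:
        return theta
    # budget binds: enforce w2' theta = M by an escalating penalty row
    scale = max(float(np.abs(R).max()), 1e-12) * np.sqrt(R.shape[0])
    rho = scale / max(float(np.abs(w2).max()), 1e-12)
    for _ in range(8):
        A = np.vstack([R, rho * w2[None, :]])
        b = np.concatenate([r_tilde, [rho * M]])
        theta, _ = nnls(A, b)
        tot = float(w2 @ theta)
        if abs(tot - M) <= 1e-10 * max(M, 1.0):
            break
        rho *= 10.0
    tot = float(w2 @ theta)
    if tot > M > 0:  # exact feasibility after the penalty solve
        theta *= M / tot
    return theta


def threshold_selected(theta, eps: float = SELECT_EPS) -> list[int]:
    """Indices (1-based) of components considered selected.

    QP solvers can leave tiny positive values at inactive coordinates;
    anything below ``eps * max(max theta, 1)`` counts as zero.
    """
    theta = np.asarray(theta, float)
    cut = eps * max(float(theta.max(initial=0.0)), 1.0)
    return [int(v) + 1 for v in np.flatnonzero(theta > cut)]


def backfit(
    mats: OperatorMatrices,
    lambda1: float,
    tau0: float,
    M: float,
    w1=DEFAULT_W1,
    w2=None,
    theta0=None,
    d0=None,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> FitResult:
    """Block backfitting over (c, d, theta) until the objective stabilizes.

    Initialization: ``theta0`` = all ones (scaled into the budget when
    infeasible), ``d0`` = OLS of the scores on the null-space design.
    Stops when the relative objective change falls below ``tol`` or after
    ``max_iter`` sweeps (reported via ``converged``).
    """
    w1 = np.asarray(w1, float)
    w2 = mats.scheme.w2 if w2 is None else np.asarray(w2, float)
    n = mats.n
    Q = mats.Q
    theta = np.ones(Q) if theta0 is None else np.asarray(theta0, float).copy()
    theta = _project_budget(theta, w2, M)
    d = lstsq(mats.T, mats.Y)[0] if d0 is None else np.asarray(d0, float).copy()

    trace: list[float] = []
    converged = False
    c = np.zeros(mats.Y.shape[0])
    stack = mats.sigma_stack  # (Q, nK, nK)
    nK = stack.shape[1]
    inv_w2 = 1.0 / w2
    for _ in range(max_iter):
        Sigma_theta = np.tensordot(theta * inv_w2, stack, axes=1)
        c = update_c(mats.Y, mats.T, d, Sigma_theta, tau0, n)
        # R's v-th column is w2_v^{-1} Sigma_v c; one fused matvec
        R = (stack.reshape(Q * nK, nK) @ c).reshape(Q, nK).T * inv_w2[None, :]
        d = update_d(mats.Y - R @ theta, mats.T, lambda1, w1, n)
        theta = update_theta(
            mats.Y, mats.T, d, R, tau0, c, M, w2, n, theta0=theta
        )
        Rtheta = R @ theta
        resid = mats.Y - mats.T @ d - Rtheta
        trace.append(
            float(resid @ resid) / n
            + lambda1 * float(np.abs(d) @ w1)
            + tau0 * float(c @ Rtheta)
        )
        if len(trace) >= 2 and abs(trace[-2] - trace[-1]) <= tol * max(
            1.0, abs(trace[-2])
        ):
            converged = True
            break
    theta = np.where(theta < 1e-14, 0.0, theta)
    return FitResult(
        d=d,
        c=c,
        theta=theta,
        tuning={"lambda1": lambda1, "tau0": tau0, "M": M},
        selected=threshold_selected(theta),
        labels=mats.scheme.labels,
        trace=trace,
        converged=converged,
        method="l1",
        scheme_id=mats.scheme.scheme_id,
        n=n,
        K=mats.K,
    )


# ---------------------------------------------------------------------------
# Ridge (L2) estimation and cross-validation machinery


def _ridge_system(mats: OperatorMatrices, keep: list[int]):
    """Precompute the lam-independent blocks of the joint (d, c) solve."""
    w2_sub = mats.scheme.w2[[v - 1 for v in keep]]
    Sigmas = [mats.Sigmas[v - 1] for v in keep]
    if not Sigmas:
        return None
    Sigma = combine_sigma(Sigmas, np.ones(len(Sigmas)), w2_sub)
    return Sigma, Sigma @ Sigma


def _ridge_solve(mats: OperatorMatrices, lam: float, keep=None, pre=None):
    """Joint minimizer of ``(1/n)||Y - Td - Sigma c||^2 + lam c' Sigma c``
    with theta fixed at one on the kept component subset."""
    keep = list(range(1, mats.Q + 1)) if keep is None else keep
    if pre is None:
        pre = _ridge_system(mats, keep)
    if pre is None:  # no penalized components: null-space OLS
        return lstsq(mats.T, mats.Y)[0], np.zeros(mats.Y.shape[0])
    Sigma, SS = pre
    n = mats.n
    T = mats.T
    nK = Sigma.shape[0]
    A = np.empty((nK + 2, nK + 2))
    A[:2, :2] = T.T @ T
    A[:2, 2:] = T.T @ Sigma
    A[2:, :2] = A[:2, 2:].T
    A[2:, 2:] = SS + n * lam * Sigma
    A[np.diag_indices_from(A)] += _JITTER
    rhs = np.concatenate([T.T @ mats.Y, Sigma @ mats.Y])
    try:
        sol = cho_solve(cho_factor(A, lower=True), rhs)
    except np.linalg.LinAlgError:
        sol = lstsq(A, rhs)[0]
    return sol[:2], sol[2:]


def _subject_folds(n: int, folds: int, seed: int | None):
    if folds < 2:
        raise ValueError("cross-validation needs at least 2 folds")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(kf.split(np.arange(n)))


def _fold_operators(mats: OperatorMatrices, train_idx) -> OperatorMatrices:
    data_tr = mats.data.subset(train_idx)
    n_t = mats.data.t_grid.size
    factors_tr = subset_factors(mats.factors, train_idx, train_idx, n_t)
    return assemble_operators(
        data_tr,
        mats.scheme,
        factors=factors_tr,
        efpc_K=mats.efpc_K,
        efpc_frac=mats.efpc_frac,
        center=mats.center,
    )


def _val_score(mats, fold_mats, train_idx, val_idx, d, c, theta) -> float:
    """Mean squared score-prediction error on held-out subjects.

    Held-out curves are projected onto the training fold's EFPC basis and
    compared with the projection of the predicted curves.
    """
    n_t = mats.data.t_grid.size
    x_val = mats.data.x[val_idx]
    cross = subset_factors(mats.factors, val_idx, train_idx, n_t)
    f_hat = predict_curves(
        fold_mats.scheme,
        d,
        c,
        theta,
        fold_mats.basis,
        fold_mats.data,
        x_val,
        factors_cross=cross,
        center_stats=fold_mats.center_stats,
    )
    nu_hat = project_scores(fold_mats.basis, f_hat)
    nu_true = project_scores(fold_mats.basis, mats.data.y[val_idx])
    return float(np.mean(np.sum((nu_hat - nu_true) ** 2, axis=1)))


def _default_grids(Q: int) -> dict:
    return {
        "lambda1": (0.0,),
        "tau0": DEFAULT_TAU0_GRID,
        "M": tuple(f * np.sqrt(Q) for f in DEFAULT_M_FACTORS),
    }


def select_tuning(
    mats: OperatorMatrices,
    grids: dict | None = None,
    folds: int = 5,
    criterion: str = "cv",
    strategy: str = "grid",
    seed: int | None = 0,
    w1=DEFAULT_W1,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> dict:
    """Choose (lambda1, tau0, M) for the selection estimator.

    ``strategy="grid"`` (default) scores the full Cartesian grid with
    warm-started backfits and returns the CV argmin, breaking ties toward
    smaller M and then larger tau0 (sparser, smoother fits).
    ``strategy="grid_1se"`` instead applies a one-standard-error parsimony
    rule on the same grid: among candidates statistically indistinguishable
    from the minimum it returns the one selecting the fewest components.
    ``strategy="two_stage"`` first picks ``tau0`` by CV of the
    all-components ridge fit (theta = 1), then ``M`` by CV argmin.  Folds
    are at subject level so that all K scores of a curve stay together.
    """
    grids = dict(grids or {})
    defaults = _default_grids(mats.Q)
    lam1_grid = tuple(grids.get("lambda1", defaults["lambda1"]))
    tau0_grid = tuple(grids.get("tau0", defaults["tau0"]))
    M_grid = tuple(grids.get("M", defaults["M"]))
    if not lam1_grid or not tau0_grid or not M_grid:
        raise ValueError("tuning grids must be non-empty")
    if criterion not in ("cv", "bic"):
        raise ValueError("criterion must be 'cv' or 'bic'")
    if criterion == "bic":
        return _select_bic(mats, lam1_grid, tau0_grid, M_grid, w1, tol, max_iter)

    fold_splits = _subject_folds(mats.n, folds, seed)
    fold_mats = [_fold_operators(mats, tr) for tr, _ in fold_splits]

    if strategy not in ("two_stage", "grid", "grid_1se"):
        raise ValueError(f"unknown tuning strategy {strategy!r}")
    stage1 = None
    if strategy == "two_stage" and len(tau0_grid) > 1:
        per_fold = np.zeros((len(fold_splits), len(tau0_grid)))
        theta_ones = np.ones(mats.Q)
        for fi, (fm, (tr, va)) in enumerate(zip(fold_mats, fold_splits)):
            pre = _ridge_system(fm, list(range(1, fm.Q + 1)))
            for a, tau0 in enumerate(tau0_grid):
                d, c = _ridge_solve(fm, tau0, pre=pre)
                per_fold[fi, a] = _val_score(mats, fm, tr, va, d, c, theta_ones)
        scores = per_fold.mean(axis=0)
        se = per_fold.std(axis=0, ddof=1) / np.sqrt(len(fold_splits))
        # one-standard-error rule: the largest (most regularizing) tau0
        # whose CV score is within one SE of the minimum; selection is the
        # goal here and under-smoothing lets spurious components survive
        a_min = int(np.argmin(scores))
        cut = scores[a_min] + se[a_min]
        admissible = [a for a in range(len(tau0_grid)) if scores[a] <= cut]
        best = max(admissible, key=lambda a: tau0_grid[a])
        tau0_sel = (tau0_grid[best],)
        stage1 = {
            "tau0_grid": list(tau0_grid),
            "tau0_cv": scores.tolist(),
            "tau0_cv_se": se.tolist(),
        }
    else:
        tau0_sel = tau0_grid

    combos = [(l1, t0, M) for l1 in lam1_grid for t0 in tau0_sel for M in M_grid]
    # evaluation order: descending M within each (lambda1, tau0) for warm starts
    order = sorted(
        range(len(combos)), key=lambda b: (combos[b][0], combos[b][1], -combos[b][2])
    )
    nf = len(fold_splits)
    cv_fold = np.zeros((nf, len(combos)))
    nsel_fold = np.zeros((nf, len(combos)))
    for fi, (fm, (tr, va)) in enumerate(zip(fold_mats, fold_splits)):
        prev_key = None
        theta0 = d0 = None
        for b in order:
            l1, t0, M = combos[b]
            if (l1, t0) != prev_key:
                theta0 = d0 = None
                prev_key = (l1, t0)
            fit = backfit(
                fm, l1, t0, M, w1=w1, theta0=theta0, d0=d0,
                tol=max(tol, _CV_TOL),
                max_iter=min(max_iter, _CV_MAX_ITER),
            )
            theta0, d0 = fit.theta, fit.d
            cv_fold[fi, b] = _val_score(mats, fm, tr, va, fit.d, fit.c, fit.theta)
            nsel_fold[fi, b] = len(fit.selected)
    cv = cv_fold.mean(axis=0)
    se = cv_fold.std(axis=0, ddof=1) / np.sqrt(nf)
    nsel = nsel_fold.mean(axis=0)
    if strategy == "grid_1se":
        # parsimony within one standard error: among candidates whose CV
        # score is statistically indistinguishable from the minimum, keep
        # the one selecting the fewest components (then larger tau0, then
        # smaller M) — the sparsest model that predicts as well as the best
        cut = float(cv.min())
        admissible = [b for b in range(len(combos)) if cv[b] - se[b] <= cut]
        key = sorted(
            admissible, key=lambda b: (nsel[b], -combos[b][1], combos[b][2], cv[b])
        )[0]
    else:
        # argmin with ties toward smaller M then larger tau0
        key = sorted(
            range(len(combos)), key=lambda b: (cv[b], combos[b][2], -combos[b][1])
        )[0]
    l1, t0, M = combos[key]
    return {
        "lambda1": l1,
        "tau0": t0,
        "M": M,
        "cv": {
            "combos": combos,
            "scores": cv.tolist(),
            "se": se.tolist(),
            "n_selected": nsel.tolist(),
            "stage1": stage1,
            "folds": folds,
            "seed": seed,
        },
    }


def _select_bic(mats, lam1_grid, tau0_grid, M_grid, w1, tol, max_iter) -> dict:
    """BIC variant: full-data fits scored by nK log(RSS/nK) + df log(nK),
    with df counted as the number of surviving components plus nonzero d."""
    w2 = mats.scheme.w2
    nK = mats.Y.shape[0]
    best = None
    table = []
    for l1 in lam1_grid:
        for t0 in tau0_grid:
            for M in M_grid:
                fit = backfit(mats, l1, t0, M, w1=w1, tol=tol, max_iter=max_iter)
                r = (
                    mats.Y
                    - mats.T @ fit.d
                    - compute_R(mats.Sigmas, fit.c, w2) @ fit.theta
                )
                rss = float(r @ r)
                df = len(fit.selected) + int(np.sum(np.abs(fit.d) > 1e-12))
                bic = nK * np.log(max(rss, 1e-300) / nK) + df * np.log(nK)
                table.append({"lambda1": l1, "tau0": t0, "M": M, "bic": bic})
                if best is None or (bic, M, -t0) < (best[3], best[2], -best[1]):
                    best = (l1, t0, M, bic)
    return {
        "lambda1": best[0],
        "tau0": best[1],
        "M": best[2],
        "cv": {"criterion": "bic", "table": table},
    }


def fit_L2(
    mats: OperatorMatrices,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    folds: int = 5,
    seed: int | None = 0,
    theta_mask=None,
) -> FitResult:
    """Ridge estimator with all (or a masked subset of) components kept.

    theta is fixed at one on the kept components; the single smoothing
    parameter is chosen by subject-level k-fold CV over ``lambda_grid``.
    """
    lambda_grid = tuple(lambda_grid)
    if not lambda_grid:
        raise ValueError("lambda_grid must be non-empty")
    keep = (
        list(range(1, mats.Q + 1))
        if theta_mask is None
        else sorted(int(v) for v in theta_mask)
    )
    theta = np.zeros(mats.Q)
    theta[[v - 1 for v in keep]] = 1.0

    if len(lambda_grid) > 1 and keep:
        fold_splits = _subject_folds(mats.n, folds, seed)
        scores = np.zeros(len(lambda_grid))
        for tr, va in fold_splits:
            fm = _fold_operators(mats, tr)
            pre = _ridge_system(fm, keep)
            for a, lam in enumerate(lambda_grid):
                d, c = _ridge_solve(fm, lam, keep=keep, pre=pre)
                scores[a] += _val_score(mats, fm, tr, va, d, c, theta)
        scores /= len(fold_splits)
        best = len(lambda_grid) - 1 - int(np.argmin(scores[::-1]))
        lam = lambda_grid[best]
        cv_info = {"lambda_grid": list(lambda_grid), "cv": scores.tolist()}
    else:
        lam = lambda_grid[0]
        cv_info = {"lambda_grid": list(lambda_grid)}

    d, c = _ridge_solve(mats, lam, keep=keep)
    return FitResult(
        d=d,
        c=c,
        theta=theta,
        tuning={"lambda": lam, **cv_info, "folds": folds, "seed": seed},
        selected=keep,
        labels=mats.scheme.labels,
        trace=[],
        converged=True,
        method="l2",
        scheme_id=mats.scheme.scheme_id,
        n=mats.n,
        K=mats.K,
    )


def fit_L1_L2(
    mats: OperatorMatrices,
    grids: dict | None = None,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    folds: int = 5,
    seed: int | None = 0,
    tol: float = 1e-6,
    max_iter: int = 200,
    l1_fit: FitResult | None = None,
) -> FitResult:
    """Two-stage estimator: L1 selection, then ridge refit on the survivors.

    If no component survives selection, the refit degenerates to the
    null-space regression.  A pre-computed selection fit can be passed to
    avoid repeating the first stage.
    """
    if l1_fit is None:
        tuning = select_tuning(
            mats, grids=grids, folds=folds, seed=seed, tol=tol, max_iter=max_iter
        )
        l1_fit = backfit(
            mats,
            tuning["lambda1"],
            tuning["tau0"],
            tuning["M"],
            tol=tol,
            max_iter=max_iter,
        )
        l1_fit.tuning["cv"] = tuning["cv"]
    refit = fit_L2(
        mats,
        lambda_grid=lambda_grid,
        folds=folds,
        seed=seed,
        theta_mask=l1_fit.selected,
    )
    refit.method = "l1l2"
    refit.selection_fit = l1_fit
    return refit


def predict_f(fit: FitResult, mats: OperatorMatrices, x_new: np.ndarray) -> np.ndarray:
    """Evaluate a fitted regression function on new covariate surfaces."""
    return predict_curves(
        mats.scheme, fit.d, fit.c, fit.theta, mats.basis, mats.data, x_new,
        center_stats=mats.center_stats,
    )
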