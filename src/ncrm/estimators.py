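"""Scikit-learn style estimators for functional concurrent regression.

:class:`FunctionalANOVARegressor` fits the nonparametric concurrent
regression model ``y_i(t) = f(t, x_i(t, .)) + eps_i(t)`` with an SS-ANOVA
decomposition of ``f`` over a tensor-product RKHS.  Three penalties are
available:

``penalty="l1"``
    Component-selection estimator: budget-constrained backfitting that
    drives the per-component scales ``theta_v`` of inactive components to
    zero.
``penalty="l2"``
    Ridge-type estimator keeping every component (no selection).
``penalty="l1l2"``
    Two-stage estimator: L1 selection followed by a ridge refit restricted
    to the selected components.

``X`` is an ``(n, q, |t|, |s|)`` array of covariate surfaces and ``y`` an
``(n, |t|)`` array of response curves on common grids; ``predict`` returns
fitted curves on the training t-grid.  The estimator composes with sklearn
model selection through ``get_params`` / ``set_params``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import solver
from .assembly import assemble_operators
from .data import FunctionalDataset, uniform_grid
from .kernels import build_decomposition

__all__ = ["FunctionalANOVARegressor"]

_SCHEME_Q = {"full_q2": 2, "full_q3": 3, "merged_q3": 3}


class FunctionalANOVARegressor(BaseEstimator, RegressorMixin):
    """Concurrent functional regression with SS-ANOVA component selection.

    Parameters
    ----------
    penalty : {"l1", "l2", "l1l2"}, default "l1"
        Estimation strategy (selection, ridge, or select-then-refit).
    scheme : {"full_q2", "full_q3", "merged_q3"}, default "full_q2"
        ANOVA decomposition of the tensor-product space.
    t_grid, s_grid : arrays or None
        Observation grids in [0, 1]; inferred as equispaced when omitted.
    lambda1 : float, default 0.0
        L1 penalty on the null-space coefficients ``d`` (the constant is
        never penalized under the default weights ``w1 = (0, 1)``).
    tau0, M : float or "cv"
        Roughness penalty and theta budget of the selection estimator;
        ``"cv"`` tunes them by subject-level k-fold cross-validation.
    lam : float or "cv"
        Smoothing parameter of the ridge (re)fit.
    tau0_grid, M_grid, lambda_grid : sequences or None
        Candidate grids for cross-validation (package defaults when None).
    tuning_strategy : {"two_stage", "grid"}, default "two_stage"
        CV search strategy for (tau0, M).
    efpc_K : int or None
        Cap on the number of empirical principal components of the
        response curves; None keeps all (up to numerical rank).
    efpc_frac : float or None
        Optional cumulative-eigenvalue truncation fraction.
    cv : int, default 5
        Number of subject-level folds.
    tol, max_iter : backfitting convergence control.
    random_state : int or None
        Seed for fold assignment (the fit itself is deterministic).

    Attributes
    ----------
    scheme_ : DecompositionScheme
    basis_ : EFPCBasis of the training curves.
    d_, c_, theta_ : fitted coefficients.
    selected_components_ : 1-based indices of surviving components.
    selected_labels_ : their labels.
    result_ : full :class:`~ncrm.solver.FitResult` (for "l1l2" this is the
        refit; the selection stage is in ``result_.selection_fit``).
    """

    def __init__(
        self,
        penalty: str = "l1",
        scheme: str = "full_q2",
        t_grid=None,
        s_grid=None,
        lambda1: float = 0.0,
        tau0="cv",
        M="cv",
        lam="cv",
        tau0_grid=None,
        M_grid=None,
        lambda_grid=None,
        tuning_strategy: str = "grid",
        efpc_K=None,
        efpc_frac=None,
        center: bool = True,
        cv: int = 5,
        tol: float = 1e-6,
        max_iter: int = 200,
        random_state=None,
    ):
        self.penalty = penalty
        self.scheme = scheme
        self.t_grid = t_grid
        self.s_grid = s_grid
        self.lambda1 = lambda1
        self.tau0 = tau0
        self.M = M
        self.lam = lam
        self.tau0_grid = tau0_grid
        self.M_grid = M_grid
        self.lambda_grid = lambda_grid
        self.tuning_strategy = tuning_strategy
        self.efpc_K = efpc_K
        self.efpc_frac = efpc_frac
        self.center = center
        self.cv = cv
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    # -- helpers ---------------------------------------------------------

    def _validate(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 4:
            raise ValueError("X must have shape (n, q, |t|, |s|)")
        if self.penalty not in ("l1", "l2", "l1l2"):
            raise ValueError(f"unknown penalty {self.penalty!r}")
        if self.scheme not in _SCHEME_Q:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if X.shape[1] != _SCHEME_Q[self.scheme]:
            raise ValueError(
                f"scheme {self.scheme!r} expects q={_SCHEME_Q[self.scheme]} "
                f"covariates, X has {X.shape[1]}"
            )
        t_grid = (
            uniform_grid(X.shape[2]) if self.t_grid is None else np.asarray(self.t_grid)
        )
        s_grid = (
            uniform_grid(X.shape[3]) if self.s_grid is None else np.asarray(self.s_grid)
        )
        if y is not None:
            y = np.asarray(y, dtype=float)
            if y.shape != (X.shape[0], t_grid.size):
                raise ValueError("y must have shape (n, |t|)")
        return X, y, t_grid, s_grid

    def _grids_dict(self, Q: int) -> dict:
        g = solver._default_grids(Q)
        if self.tau0_grid is not None:
            g["tau0"] = tuple(self.tau0_grid)
        if self.M_grid is not None:
            g["M"] = tuple(self.M_grid)
        g["lambda1"] = (self.lambda1,)
        if self.tau0 != "cv":
            g["tau0"] = (float(self.tau0),)
        if self.M != "cv":
            g["M"] = (float(self.M),)
        return g

    # -- sklearn API -----------------------------------------------------

    def fit(self, X, y):
        X, y, t_grid, s_grid = self._validate(X, y)
        if y is None:
            raise ValueError("y is required")
        self.scheme_ = build_decomposition(X.shape[1], self.scheme)
        data = FunctionalDataset(t_grid, s_grid, X, y)
        mats = assemble_operators(
            data, self.scheme_, efpc_K=self.efpc_K, efpc_frac=self.efpc_frac,
            center=self.center,
        )
        self.basis_ = mats.basis
        self._mats = mats
        lam_grid = (
            solver.DEFAULT_LAMBDA_GRID
            if self.lambda_grid is None
            else tuple(self.lambda_grid)
        )
        if self.lam != "cv":
            lam_grid = (float(self.lam),)
        seed = self.random_state

        if self.penalty == "l2":
            result = solver.fit_L2(mats, lambda_grid=lam_grid, folds=self.cv, seed=seed)
        else:
            grids = self._grids_dict(mats.Q)
            if len(grids["tau0"]) == 1 and len(grids["M"]) == 1:
                tuning = {
                    "lambda1": self.lambda1,
                    "tau0": grids["tau0"][0],
                    "M": grids["M"][0],
                    "cv": None,
                }
            else:
                tuning = solver.select_tuning(
                    mats,
                    grids=grids,
                    folds=self.cv,
                    strategy=self.tuning_strategy,
                    seed=seed,
                    tol=self.tol,
                    max_iter=self.max_iter,
                )
            l1 = solver.backfit(
                mats,
                tuning["lambda1"],
                tuning["tau0"],
                tuning["M"],
                tol=self.tol,
                max_iter=self.max_iter,
            )
            l1.tuning["cv"] = tuning["cv"]
            l1.seed = seed
            if self.penalty == "l1":
                result = l1
            else:
                result = solver.fit_L1_L2(
                    mats,
                    lambda_grid=lam_grid,
                    folds=self.cv,
                    seed=seed,
                    l1_fit=l1,
                )
        result.seed = seed
        self.result_ = result
        self.d_ = result.d
        self.c_ = result.c
        self.theta_ = result.theta
        self.selected_components_ = result.selected
        self.selected_labels_ = result.selected_labels
        self.converged_ = result.converged
        self.objective_trace_ = result.trace
        return self

    def predict(self, X):
        check_is_fitted(self, "result_")
        X, _, t_grid, s_grid = self._validate(X, None)
        if X.shape[2] != self._mats.data.t_grid.size or X.shape[3] != self._mats.data.s_grid.size:
            raise ValueError("X must be sampled on the training grids")
        return solver.predict_f(self.result_, self._mats, X)

    def predict_with(self, fit_result, X):
        """Predict using an alternative fit (e.g. the L1 selection stage)."""
        check_is_fitted(self, "result_")
        X, _, _, _ = self._validate(X, None)
        return solver.predict_f(fit_result, self._mats, X)
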