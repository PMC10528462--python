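"""Finite-dimensional operators of the score-space penalized least squares.

After projecting the functional model onto the EFPC basis, the fit reduces
to vectors and matrices indexed by the (subject, score) pair ``(i, k)`` in
the order ``i + (k - 1) n`` (i fastest):

* ``Y``    — length-``nK`` vector of scores ``nu_ik``;
* ``T``    — ``nK x 2`` null-space design, ``a_ikj = int phi_j eta_k dt``
  (no i-dependence, so rows repeat across subjects);
* ``Sigma_v`` — ``nK x nK`` Gram blocks,
  ``b_ikjl^v = int eta_k(t) xi_jl^v(t, x_i(t,.)) dt`` with
  ``xi_jl^v(t, x) = int K_v((t, x), (t', x_j(t',.))) eta_l(t') dt'``;
* ``Sigma(theta) = sum_v w2_v^{-1} theta_v Sigma_v`` and the theta-design
  ``R`` whose v-th column is ``w2_v^{-1} Sigma_v c``.

All integrals use the composite trapezoid rule on the stored grids.  The
assembly is vectorized: each component kernel evaluated on the flattened
point set ``(i, t)`` factorizes into a t-factor Gram (tiled across
subjects) times Gaussian covariate factors, and the double quadrature
against the basis is a pair of tensor contractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import FunctionalDataset
from .fpca import EFPCBasis, augment_basis_with_null, compute_efpc
from .kernels import (
    Component,
    DecompositionScheme,
    gaussian_gram,
    t_factor_gram,
    trapz_weights,
)

__all__ = [
    "OperatorMatrices",
    "gaussian_factors",
    "subset_factors",
    "assemble_operators",
    "compute_T",
    "compute_xi",
    "compute_sigma_v",
    "combine_sigma",
    "compute_R",
    "component_cross_gram",
]


def gaussian_factors(
    x1: np.ndarray, x2: np.ndarray, s_grid: np.ndarray
) -> dict[int, np.ndarray]:
    """Per-covariate Gaussian kernel matrices on the flattened (i, t) points.

    ``x1``/``x2`` have shape ``(n, q, |t|, |s|)``; the result maps covariate
    index ``j`` to the ``(n1 |t1|) x (n2 |t2|)`` matrix
    ``B_j[(i,t),(i',t')] = exp(-||x1_ij(t,.) - x2_i'j(t',.)||^2 / 2)``.
    """
    q = x1.shape[1]
    out = {}
    for j in range(q):
        U1 = x1[:, j].reshape(-1, x1.shape[3])
        U2 = x2[:, j].reshape(-1, x2.shape[3])
        out[j] = gaussian_gram(U1, U2, s_grid)
    return out


def subset_factors(
    factors: dict[int, np.ndarray], idx1, idx2, n_t: int
) -> dict[int, np.ndarray]:
    """Restrict flattened factor matrices to subject subsets on both axes."""
    idx1 = np.asarray(idx1)
    idx2 = np.asarray(idx2)
    flat1 = (idx1[:, None] * n_t + np.arange(n_t)).ravel()
    flat2 = (idx2[:, None] * n_t + np.arange(n_t)).ravel()
    return {j: B[np.ix_(flat1, flat2)] for j, B in factors.items()}


def center_factors(
    factors: dict[int, np.ndarray]
) -> tuple[dict[int, np.ndarray], dict[int, tuple[np.ndarray, float]]]:
    """Double-center covariate factor Grams over the training points.

    Imposes the empirical SS-ANOVA side condition that every main-effect
    function averages to zero over the observed (subject, t) covariate
    points, and interactions average to zero in each argument.  Without
    it the product kernels contain a large near-constant part and can
    absorb main effects on finite samples, which destroys component
    identifiability.  Returns the centered matrices and, per covariate,
    the (column means, grand mean) needed to center out-of-sample blocks.
    """
    centered = {}
    stats = {}
    for j, B in factors.items():
        col = B.mean(axis=0)
        tot = float(B.mean())
        centered[j] = B - col[None, :] - col[:, None] + tot
        stats[j] = (col, tot)
    return centered, stats


def center_cross_factors(
    factors_cross: dict[int, np.ndarray],
    stats: dict[int, tuple[np.ndarray, float]],
) -> dict[int, np.ndarray]:
    """Center new-vs-train factor blocks with the training statistics."""
    out = {}
    for j, B in factors_cross.items():
        col, tot = stats[j]
        out[j] = B - B.mean(axis=1, keepdims=True) - col[None, :] + tot
    return out


def _component_gram_flat(
    comp: Component,
    factors: dict[int, np.ndarray],
    t1: np.ndarray,
    t2: np.ndarray,
    n1: int,
    n2: int,
) -> np.ndarray:
    """Kernel ``K_v`` on flattened points: ``(n1 |t1|) x (n2 |t2|)``."""
    G = None
    for term in comp.terms:
        A = t_factor_gram(term.t_factor, t1, t2)
        M = np.tile(A, (n1, n2))
        for j in term.u_set:
            M *= factors[j]
        G = M if G is None else G + M
    return G


def _contract_basis(
    G: np.ndarray, Ew1: np.ndarray, Ew2: np.ndarray, n1: int, n2: int
) -> np.ndarray:
    """Double quadrature of a flat kernel matrix against two bases.

    ``Ew[t, k] = w_t eta_k(t)``.  Returns the ``(n1 K1) x (n2 K2)`` matrix in
    the ``i + (k-1) n`` ordering.
    """
    T1, K1 = Ew1.shape
    T2, K2 = Ew2.shape
    Z = G.reshape(n1, T1, n2, T2)
    Z = np.tensordot(Z, Ew2, axes=([3], [0]))  # (n1, T1, n2, K2)
    Z = np.tensordot(Ew1, Z, axes=([0], [1]))  # (K1, n1, n2, K2)
    Z = Z.transpose(0, 1, 3, 2)  # (K1, n1, K2, n2)
    return np.ascontiguousarray(Z.reshape(K1 * n1, K2 * n2))


def _basis_weights(basis: EFPCBasis) -> np.ndarray:
    w = trapz_weights(basis.t_grid)
    return (basis.eta * w).T  # (|t|, K)


@dataclass
class OperatorMatrices:
    """Assembled score-space operators plus the objects they derive from."""

    Y: np.ndarray  # (nK,)
    T: np.ndarray  # (nK, 2)
    Sigmas: list[np.ndarray]  # Q matrices, each (nK, nK)
    scheme: DecompositionScheme
    basis: EFPCBasis
    data: FunctionalDataset
    factors: dict[int, np.ndarray] = field(repr=False, default=None)  # type: ignore[assignment]
    efpc_K: int | None = None
    efpc_frac: float | None = None
    center: bool = True
    center_stats: dict = field(repr=False, default=None)  # type: ignore[assignment]

    _stack: np.ndarray = field(repr=False, default=None, compare=False)  # type: ignore[assignment]

    @property
    def sigma_stack(self) -> np.ndarray:
        """All Gram blocks as one (Q, nK, nK) array (cached)."""
        if self._stack is None or self._stack.shape[0] != len(self.Sigmas):
            self._stack = np.ascontiguousarray(np.stack(self.Sigmas))
        return self._stack

    @property
    def n(self) -> int:
        return self.basis.n

    @property
    def K(self) -> int:
        return self.basis.K

    @property
    def Q(self) -> int:
        return self.scheme.Q


def compute_T(basis: EFPCBasis) -> np.ndarray:
    """Null-space design: ``a_ikj = int phi_j(t) eta_k(t) dt``, row-replicated.

    ``phi_1 = 1`` and ``phi_2 = k1(t)``; the integral has no i-dependence so
    each of the K rows of the 2-column coefficient table repeats n times.
    """
    from .kernels import k1

    w = trapz_weights(basis.t_grid)
    phi = np.column_stack([np.ones_like(basis.t_grid), k1(basis.t_grid)])
    a = (basis.eta * w) @ phi  # (K, 2)
    return np.repeat(a, basis.n, axis=0)


def compute_xi(
    scheme: DecompositionScheme,
    v: int,
    x_i: np.ndarray,
    eta_k: np.ndarray,
    z,
    t_grid: np.ndarray,
    s_grid: np.ndarray,
) -> float:
    """Representer section ``xi_ik^v(z) = int K_v(z, (t', x_i(t',.))) eta_k(t') dt'``.

    ``x_i`` is one subject's surfaces ``(q, |t|, |s|)`` and ``z = (t, u)``
    a single evaluation point.  Direct quadrature; used for small-scale
    checks — the assembly path below computes all sections in one shot.
    """
    from .kernels import eval_component_kernel

    x_i = np.asarray(x_i, dtype=float)
    eta_k = np.asarray(eta_k, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    if x_i.shape[1] != t_grid.size or eta_k.shape != t_grid.shape:
        raise ValueError("x_i / eta_k grids do not match t_grid")
    w = trapz_weights(t_grid)
    vals = np.array(
        [
            eval_component_kernel(scheme, v, z, (t_grid[a], x_i[:, a, :]), s_grid)
            for a in range(t_grid.size)
        ]
    )
    return float(vals @ (w * eta_k))


def compute_sigma_v(
    scheme: DecompositionScheme,
    v: int,
    data: FunctionalDataset,
    basis: EFPCBasis,
    factors: dict[int, np.ndarray] | None = None,
) -> np.ndarray:
    """One Gram block ``Sigma_v`` (symmetrized) for component ``v``."""
    if not 1 <= v <= scheme.Q:
        raise IndexError(f"component index {v} out of range 1..{scheme.Q}")
    if factors is None:
        factors = gaussian_factors(data.x, data.x, data.s_grid)
    n = data.n
    Ew = _basis_weights(basis)
    G = _component_gram_flat(
        scheme.components[v - 1], factors, data.t_grid, data.t_grid, n, n
    )
    S = _contract_basis(G, Ew, Ew, n, n)
    return 0.5 * (S + S.T)


def assemble_operators(
    data: FunctionalDataset,
    scheme: DecompositionScheme,
    basis: EFPCBasis | None = None,
    efpc_K: int | None = None,
    efpc_frac: float | None = None,
    factors: dict[int, np.ndarray] | None = None,
    center: bool = True,
    augment_null: bool = True,
) -> OperatorMatrices:
    """Assemble Y, T and all Gram blocks for one training dataset.

    ``factors`` may carry precomputed *raw* Gaussian factor matrices (e.g.
    sub-blocks of a larger dataset's factors); the empirical centering is
    applied here so that cross-validation folds are centered with their
    own training statistics.  ``augment_null`` extends the score basis so
    that the unpenalized functions 1 and k1(t) are always identified.
    """
    if data.y is None:
        raise ValueError("training data must carry responses")
    if data.q != scheme.q:
        raise ValueError(f"scheme expects q={scheme.q}, data has q={data.q}")
    if basis is None:
        basis = compute_efpc(data.y, data.t_grid, K=efpc_K, frac=efpc_frac)
        if augment_null:
            basis = augment_basis_with_null(basis, data.y)
    if factors is None:
        factors = gaussian_factors(data.x, data.x, data.s_grid)
    if center:
        centered, stats = center_factors(factors)
    else:
        centered, stats = factors, None
    Sigmas = [
        compute_sigma_v(scheme, v, data, basis, factors=centered)
        for v in range(1, scheme.Q + 1)
    ]
    Y = basis.nu.T.reshape(-1)
    return OperatorMatrices(
        Y=Y,
        T=compute_T(basis),
        Sigmas=Sigmas,
        scheme=scheme,
        basis=basis,
        data=data,
        factors=factors,
        efpc_K=efpc_K,
        efpc_frac=efpc_frac,
        center=center,
        center_stats=stats,
    )


def combine_sigma(Sigmas: list[np.ndarray], theta, w2) -> np.ndarray:
    """``Sigma(theta) = sum_v w2_v^{-1} theta_v Sigma_v`` (exact linearity)."""
    theta = np.asarray(theta, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    if theta.shape != (len(Sigmas),) or w2.shape != (len(Sigmas),):
        raise ValueError("theta and w2 must have one entry per component")
    if np.any(theta < 0):
        raise ValueError("theta must be nonnegative")
    out = np.zeros_like(Sigmas[0])
    for Sv, th, wv in zip(Sigmas, theta, w2):
        if th != 0.0:
            out += (th / wv) * Sv
    return out


def compute_R(Sigmas: list[np.ndarray], c: np.ndarray, w2) -> np.ndarray:
    """Theta-design: v-th column ``w2_v^{-1} Sigma_v c`` (an nK x Q matrix)."""
    c = np.asarray(c, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    if c.ndim != 1 or c.shape[0] != Sigmas[0].shape[0]:
        raise ValueError("c length must match the Gram blocks")
    return np.column_stack([(Sv @ c) / wv for Sv, wv in zip(Sigmas, w2)])


def component_cross_gram(
    comp: Component,
    factors_cross: dict[int, np.ndarray],
    t_new: np.ndarray,
    t_train: np.ndarray,
    n_new: int,
    n_train: int,
) -> np.ndarray:
    """Component kernel between new flattened points and training points."""
    return _component_gram_flat(comp, factors_cross, t_new, t_train, n_new, n_train)


def predict_curves(
    scheme: DecompositionScheme,
    d: np.ndarray,
    c: np.ndarray,
    theta: np.ndarray,
    basis: EFPCBasis,
    train: FunctionalDataset,
    x_new: np.ndarray,
    factors_cross: dict[int, np.ndarray] | None = None,
    center_stats: dict | None = None,
) -> np.ndarray:
    """Evaluate the representer-form fit on new covariate surfaces.

    ``f(t, x) = d1 + d2 k1(t) + sum_v w2_v^{-1} theta_v sum_{i,k} c_ik
    xi_ik^v(t, x)``, evaluated on the training t-grid for each row of
    ``x_new`` (shape ``(m, q, |t|, |s|)``).  Components with ``theta_v = 0``
    are skipped.  ``factors_cross``, when given, must be *raw* Gaussian
    blocks; ``center_stats`` (from the training assembly) applies the same
    empirical centering the fit was computed under.
    """
    x_new = np.asarray(x_new, dtype=float)
    if x_new.ndim != 4 or x_new.shape[1] != scheme.q:
        raise ValueError("x_new must have shape (m, q, |t|, |s|)")
    if x_new.shape[2] != train.t_grid.size or x_new.shape[3] != train.s_grid.size:
        raise ValueError("x_new must be sampled on the training grids")
    m = x_new.shape[0]
    n, K = basis.n, basis.K
    n_t = train.t_grid.size
    theta = np.asarray(theta, dtype=float)
    c_mat = np.asarray(c, dtype=float).reshape(K, n).T  # (n, K) from i+(k-1)n order

    if factors_cross is None:
        active = [j for v in np.flatnonzero(theta != 0.0)
                  for term in scheme.components[v].terms for j in term.u_set]
        if active:
            factors_cross = gaussian_factors(x_new, train.x, train.s_grid)
        else:
            factors_cross = {}
    if center_stats is not None and factors_cross:
        factors_cross = center_cross_factors(factors_cross, center_stats)

    w_t = trapz_weights(train.t_grid)
    # c "curve" on the flattened training points: sum_k c_ik eta_k(t') w_t'
    c_curve = ((c_mat @ basis.eta) * w_t).ravel()  # (n |t|,)

    from .kernels import k1

    f_flat = np.zeros(m * n_t)
    for v in np.flatnonzero(theta != 0.0):
        G = component_cross_gram(
            scheme.components[v], factors_cross, train.t_grid, train.t_grid, m, n
        )
        f_flat += (theta[v] / scheme.w2[v]) * (G @ c_curve)
    f = f_flat.reshape(m, n_t)
    f += d[0] + d[1] * k1(train.t_grid)[None, :]
    return f
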