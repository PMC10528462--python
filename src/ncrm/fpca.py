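"""Empirical functional principal components of the response curves.

The observed curves ``y_i(t)`` are expanded on an orthonormal basis
``eta_k`` obtained from the eigen-decomposition of their *uncentered*
quadrature Gram matrix ``M_{ij} = <y_i, y_j>``: the curves are not
mean-centered, so the regression function absorbs the mean and the scores
are plain inner products ``nu_ik = <y_i, eta_k>``.  Working with the n x n
Gram matrix (rather than the grid x grid covariance) is exact on the span
of the data and costs O(n^3) independent of grid resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh

from .kernels import trapz_weights

__all__ = ["EFPCBasis", "compute_efpc", "project_scores", "augment_basis_with_null"]

_RANK_TOL = 1e-12


@dataclass
class EFPCBasis:
    """Orthonormal EFPC basis on a common t-grid.

    Attributes
    ----------
    t_grid : grid the curves were observed on.
    eta : (K, |t|) basis curves, orthonormal in the quadrature L2 inner
        product, ordered by non-increasing eigenvalue.
    nu : (n, K) score matrix, ``nu[i, k] = <y_i, eta_k>``.
    eigvals : (K,) nonnegative eigenvalues of the Gram matrix.
    """

    t_grid: np.ndarray
    eta: np.ndarray
    nu: np.ndarray
    eigvals: np.ndarray

    @property
    def K(self) -> int:
        return self.eta.shape[0]

    @property
    def n(self) -> int:
        return self.nu.shape[0]


def compute_efpc(
    Y: np.ndarray,
    t_grid: np.ndarray,
    K: int | None = None,
    frac: float | None = None,
) -> EFPCBasis:
    """Eigen-decompose the curves' Gram matrix into an EFPC basis.

    Parameters
    ----------
    Y : (n, |t|) response curves on a common grid.
    t_grid : increasing grid in [0, 1].
    K : number of components to keep; defaults to all (up to numerical
        rank).  Must satisfy ``K <= n``.
    frac : optional cumulative-eigenvalue fraction; if given, K is further
        reduced to the smallest number of components whose eigenvalues sum
        to at least ``frac`` of the total.

    The sign of each ``eta_k`` is fixed so that its largest-magnitude grid
    value is positive, making scores reproducible.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    t_grid = np.asarray(t_grid, dtype=float)
    n = Y.shape[0]
    if n < 1 or Y.size == 0:
        raise ValueError("need at least one curve")
    if Y.shape[1] != t_grid.size:
        raise ValueError("curves and t_grid have mismatched lengths")
    if K is not None and K > n:
        raise ValueError(f"K={K} exceeds the number of curves n={n}")

    w = trapz_weights(t_grid)
    M = (Y * w) @ Y.T
    M = 0.5 * (M + M.T)
    evals, evecs = eigh(M)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]

    # numerical rank: drop directions carrying (relatively) no energy
    tot = float(evals.sum())
    rank = int(np.sum(evals > _RANK_TOL * max(tot, 1.0)))
    rank = max(rank, 1)
    keep = rank if K is None else min(K, rank) if K > 0 else 1
    if frac is not None:
        cum = np.cumsum(evals[:rank])
        k_frac = int(np.searchsorted(cum, frac * tot) + 1)
        keep = min(keep, max(k_frac, 1))

    evals = evals[:keep]
    evecs = evecs[:, :keep]
    # eta_k = sum_i u_ik y_i / sqrt(lambda_k); scores nu_ik = u_ik sqrt(lambda_k)
    inv_sqrt = 1.0 / np.sqrt(evals)
    eta = (evecs * inv_sqrt).T @ Y
    nu = evecs * np.sqrt(evals)

    # deterministic sign convention
    for k in range(keep):
        j = int(np.argmax(np.abs(eta[k])))
        if eta[k, j] < 0:
            eta[k] = -eta[k]
            nu[:, k] = -nu[:, k]
    return EFPCBasis(t_grid=t_grid, eta=eta, nu=nu, eigvals=evals)


def augment_basis_with_null(basis: EFPCBasis, Y: np.ndarray) -> EFPCBasis:
    """Extend the basis so its span contains the null-space functions 1, k1(t).

    The score-space reduction of the functional least squares is exact only
    for the part of the model inside ``span{eta}``; when the observed curves
    are (numerically) rank-deficient or truncated, the unpenalized null
    space can fall partly outside that span, leaving its coefficients
    unidentified.  Appending the orthonormalized remainders of ``phi_1 = 1``
    and ``phi_2 = k1`` (with the corresponding scores ``<y_i, eta_new>``)
    restores exact identification of the null-space coefficients and is a
    no-op when the span already contains them.
    """
    from .kernels import k1

    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    t = basis.t_grid
    w = trapz_weights(t)
    eta = basis.eta
    nu = basis.nu
    eigvals = basis.eigvals
    for phi in (np.ones_like(t), k1(t)):
        coefs = (eta * w) @ phi
        resid = phi - coefs @ eta
        norm = np.sqrt(float((resid * resid) @ w))
        if norm > 1e-6:
            new = resid / norm
            eta = np.vstack([eta, new])
            nu = np.column_stack([nu, (Y * w) @ new])
            eigvals = np.append(eigvals, 0.0)
    return EFPCBasis(t_grid=t, eta=eta, nu=nu, eigvals=eigvals)


def project_scores(basis: EFPCBasis, y: np.ndarray) -> np.ndarray:
    """Scores ``<y, eta_k>`` of one curve (or a stack of curves).

    Accepts ``y`` of shape ``(|t|,)`` or ``(m, |t|)``; returns ``(K,)`` or
    ``(m, K)`` accordingly.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[-1] != basis.t_grid.size:
        raise ValueError("curve grid does not match the basis grid")
    w = trapz_weights(basis.t_grid)
    return (y * w) @ basis.eta.T
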