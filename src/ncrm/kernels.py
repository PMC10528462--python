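"""Reproducing kernels for the tensor-product SS-ANOVA decomposition.

The regression function ``f(t, x(t,.))`` lives in a tensor product of

* the second-order Sobolev space on ``t in [0, 1]``, split as
  ``{1} + {t} + H2`` with reproducing kernels ``1``, ``k1(t)k1(t')`` and
  ``K2(t,t') = k2(t)k2(t') - k4(|t-t'|)`` built from the scaled Bernoulli
  polynomials ``k1, k2, k4``; and
* one Gaussian-kernel RKHS per functional covariate ``u_j in L2[0,1]``,
  with ``K(u, u') = exp(-||u - u'||^2 / 2)`` and the L2 norm evaluated by
  quadrature on the stored ``s``-grid.

Expanding the product gives the ANOVA components: main effects of ``t`` and
of each covariate, and every interaction up to the full order.  A
:class:`DecompositionScheme` fixes the ordered list of penalized components
(the null space ``{1} + {t}`` is never penalized) together with the
pre-specified weights ``w2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "k1",
    "k2",
    "k4",
    "sobolev_K2",
    "gaussian_functional_kernel",
    "trapz_weights",
    "ComponentTerm",
    "Component",
    "DecompositionScheme",
    "build_decomposition",
    "eval_component_kernel",
    "eval_combined_kernel",
]

T_FACTORS = ("const", "lin", "nonpar")


def k1(x):
    """First scaled Bernoulli polynomial, ``k1(x) = x - 0.5``."""
    return np.asarray(x, dtype=float) - 0.5


def k2(x):
    """Second scaled Bernoulli polynomial, ``k2 = (k1^2 - 1/6) / 2``."""
    v = k1(x)
    return 0.5 * v * v - 1.0 / 12.0


def k4(x):
    """Fourth scaled Bernoulli polynomial, ``k4 = k1^4/24 - k1^2/2 + 7/240``."""
    v = k1(x)
    v2 = v * v
    return v2 * v2 / 24.0 - 0.5 * v2 + 7.0 / 240.0


def sobolev_K2(t, t2):
    """Reproducing kernel of the nonparametric-in-``t`` Sobolev subspace.

    ``K2(t, t') = k2(t) k2(t') - k4(|t - t'|)``; symmetric and positive
    semi-definite on [0, 1].  Broadcasts over array arguments.
    """
    t = np.asarray(t, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    return k2(t) * k2(t2) - k4(np.abs(t - t2))


def trapz_weights(grid: np.ndarray) -> np.ndarray:
    """Composite-trapezoid quadrature weights for an increasing grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("grid must be 1-d with at least two points")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    w = np.empty_like(grid)
    w[0] = 0.5 * (grid[1] - grid[0])
    w[-1] = 0.5 * (grid[-1] - grid[-2])
    w[1:-1] = 0.5 * (grid[2:] - grid[:-2])
    return w


def functional_sq_norm(u: np.ndarray, s_grid: np.ndarray) -> float:
    """Quadrature evaluation of ``||u||^2 = int_0^1 u(s)^2 ds``."""
    w = trapz_weights(s_grid)
    u = np.asarray(u, dtype=float)
    return float(u * u @ w)


def gaussian_functional_kernel(u, u2, s_grid) -> float:
    """Gaussian kernel between two covariate functions sampled on ``s_grid``.

    ``K(u, u') = exp(-||u - u'||^2 / 2)`` with the squared L2[0,1] distance
    computed by the trapezoid rule.  The bandwidth is fixed at 1.
    """
    u = np.asarray(u, dtype=float)
    u2 = np.asarray(u2, dtype=float)
    s_grid = np.asarray(s_grid, dtype=float)
    if u.shape != u2.shape or u.shape[-1] != s_grid.shape[0]:
        raise ValueError("u, u2 and s_grid must share the sampling grid")
    return float(np.exp(-0.5 * functional_sq_norm(u - u2, s_grid)))


def gaussian_gram(
    U: np.ndarray, U2: np.ndarray, s_grid: np.ndarray
) -> np.ndarray:
    """Gaussian kernel matrix between two stacks of functions (rows).

    Vectorized over all pairs; the weighted squared distance uses the same
    trapezoid rule as :func:`gaussian_functional_kernel`.
    """
    w = trapz_weights(s_grid)
    U = np.asarray(U, dtype=float)
    U2 = np.asarray(U2, dtype=float)
    sq1 = (U * U) @ w
    sq2 = (U2 * U2) @ w
    cross = (U * w) @ U2.T
    d2 = sq1[:, None] + sq2[None, :] - 2.0 * cross
    np.maximum(d2, 0.0, out=d2)
    return np.exp(-0.5 * d2)


# ---------------------------------------------------------------------------
# Decomposition schemes


@dataclass(frozen=True)
class ComponentTerm:
    """One product term: a t-factor times Gaussian factors for ``u_set``.

    ``t_factor`` is one of ``"const"`` (kernel 1), ``"lin"``
    (``k1(t)k1(t')``) or ``"nonpar"`` (``sobolev_K2``); ``u_set`` holds the
    0-based covariate indices whose Gaussian kernels enter the product.
    """

    t_factor: str
    u_set: tuple[int, ...]

    def __post_init__(self):
        if self.t_factor not in T_FACTORS:
            raise ValueError(f"unknown t-factor {self.t_factor!r}")
        object.__setattr__(self, "u_set", tuple(sorted(self.u_set)))


@dataclass(frozen=True)
class Component:
    """A penalized ANOVA component: a sum of one or more product terms."""

    index: int  # 1-based position v in the scheme
    label: str
    terms: tuple[ComponentTerm, ...]


@dataclass
class DecompositionScheme:
    """Ordered penalized components plus the unpenalized null space.

    The null space is spanned by ``phi1(t) = 1`` and ``phi2(t) = k1(t)``
    in every scheme.  ``w2`` are the pre-specified nonnegative component
    weights entering the combined kernel as ``w2_v^{-1} theta_v K_v``.
    """

    q: int
    scheme_id: str
    components: list[Component]
    w2: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.w2 is None:
            self.w2 = np.ones(len(self.components))
        self.w2 = np.asarray(self.w2, dtype=float)
        if self.w2.shape != (len(self.components),) or np.any(self.w2 <= 0):
            raise ValueError("w2 must be positive with one entry per component")

    @property
    def Q(self) -> int:
        return len(self.components)

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.components]

    def null_basis(self, t_grid: np.ndarray) -> np.ndarray:
        """Evaluate ``phi1, phi2`` on a grid; returns shape ``(|t|, 2)``."""
        t_grid = np.asarray(t_grid, dtype=float)
        return np.column_stack([np.ones_like(t_grid), k1(t_grid)])


def _label(term: ComponentTerm) -> str:
    parts = []
    if term.t_factor == "lin":
        parts.append("t_lin")
    elif term.t_factor == "nonpar":
        parts.append("t_np")
    parts.extend(f"u{j + 1}" for j in term.u_set)
    return ":".join(parts) if parts else "const"


def _product_components(q: int) -> list[Component]:
    """Full tensor expansion: all (t-factor, covariate-subset) cells except
    the null ones, ordered by interaction order then the printed numbering
    (t-nonpar main; covariate mains; t-lin x u_j; t-np x u_j; pairs; ...)."""
    comps: list[Component] = []
    v = 1

    def add(t_factor, u_set):
        nonlocal v
        term = ComponentTerm(t_factor, tuple(u_set))
        comps.append(Component(v, _label(term), (term,)))
        v += 1

    from itertools import combinations

    add("nonpar", ())
    for order in range(1, q + 1):
        for t_factor in T_FACTORS:
            for u_set in combinations(range(q), order):
                add(t_factor, u_set)
    return comps


def build_decomposition(q: int, scheme: str = "full_q2") -> DecompositionScheme:
    """Construct a named decomposition scheme.

    ``full_q3`` is the 22-component expansion for three covariates (main
    effects plus all interactions with the three t-factors); ``merged_q3``
    is the 10-component variant that merges the two t-by-covariate
    interaction cells into one component per covariate and keeps only
    covariate-pair interactions; ``full_q2`` is the 10-component full
    expansion for two covariates.
    """
    if scheme in ("full_q2", "full_q3"):
        q_expected = 2 if scheme == "full_q2" else 3
        if q != q_expected:
            raise ValueError(f"scheme {scheme!r} requires q={q_expected}, got {q}")
        return DecompositionScheme(q, scheme, _product_components(q))
    if scheme == "merged_q3":
        if q != 3:
            raise ValueError("scheme 'merged_q3' requires q=3")
        comps: list[Component] = []
        comps.append(Component(1, "t_np", (ComponentTerm("nonpar", ()),)))
        for j in range(3):
            comps.append(
                Component(2 + j, f"u{j + 1}", (ComponentTerm("const", (j,)),))
            )
        for j in range(3):
            comps.append(
                Component(
                    5 + j,
                    f"t:u{j + 1}",
                    (ComponentTerm("lin", (j,)), ComponentTerm("nonpar", (j,))),
                )
            )
        v = 8
        for j in range(3):
            for l in range(j + 1, 3):
                comps.append(
                    Component(v, f"u{j + 1}:u{l + 1}", (ComponentTerm("const", (j, l)),))
                )
                v += 1
        return DecompositionScheme(3, scheme, comps)
    raise ValueError(f"unknown scheme {scheme!r}")


def _check_point(z, q: int, s_grid: np.ndarray):
    t, u = z
    u = np.asarray(u, dtype=float)
    if u.shape != (q, np.asarray(s_grid).shape[0]):
        raise ValueError(
            f"covariate tuple must have shape (q={q}, |s_grid|); got {u.shape}"
        )
    return float(t), u


def _term_value(term: ComponentTerm, t, u, t2, u2, s_grid) -> float:
    if term.t_factor == "const":
        val = 1.0
    elif term.t_factor == "lin":
        val = float(k1(t) * k1(t2))
    else:
        val = float(sobolev_K2(t, t2))
    for j in term.u_set:
        val *= gaussian_functional_kernel(u[j], u2[j], s_grid)
    return val


def eval_component_kernel(
    scheme: DecompositionScheme, v: int, z, z2, s_grid
) -> float:
    """Evaluate component kernel ``K_v(z, z')`` at two points ``(t, u)``."""
    if not 1 <= v <= scheme.Q:
        raise IndexError(f"component index {v} out of range 1..{scheme.Q}")
    t, u = _check_point(z, scheme.q, s_grid)
    t2, u2 = _check_point(z2, scheme.q, s_grid)
    comp = scheme.components[v - 1]
    return sum(_term_value(term, t, u, t2, u2, s_grid) for term in comp.terms)


def eval_combined_kernel(
    scheme: DecompositionScheme, theta, z, z2, s_grid
) -> float:
    """Combined kernel ``K* = sum_v w2_v^{-1} theta_v K_v`` at two points."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (scheme.Q,):
        raise ValueError("theta must have one entry per component")
    if np.any(theta < 0):
        raise ValueError("theta must be nonnegative")
    vals = np.array(
        [eval_component_kernel(scheme, v, z, z2, s_grid) for v in range(1, scheme.Q + 1)]
    )
    return float(np.sum(theta / scheme.w2 * vals))


def t_factor_gram(t_factor: str, t1: np.ndarray, t2: np.ndarray) -> np.ndarray:
    """Gram matrix of a t-factor kernel between two t-grids."""
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    if t_factor == "const":
        return np.ones((t1.size, t2.size))
    if t_factor == "lin":
        return np.outer(k1(t1), k1(t2))
    if t_factor == "nonpar":
        return sobolev_K2(t1[:, None], t2[None, :])
    raise ValueError(f"unknown t-factor {t_factor!r}")
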