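"""Container for functional concurrent-regression data on common grids.

Responses are curves ``y_i(t)`` and covariates are surfaces ``x_ij(t, s)``:
at each observation time ``t`` the j-th covariate of subject ``i`` is itself
a function of ``s`` (e.g. a frequency profile).  All subjects share the same
``t``- and ``s``-grids; irregular designs are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FunctionalDataset", "uniform_grid"]


def uniform_grid(num: int) -> np.ndarray:
    """Equispaced grid of ``num`` points on [0, 1]."""
    return np.linspace(0.0, 1.0, num)


@dataclass
class FunctionalDataset:
    """Functional responses and covariate surfaces on common grids.

    Attributes
    ----------
    t_grid : (T,) increasing observation times in [0, 1].
    s_grid : (S,) increasing inner argument grid in [0, 1].
    x : (n, q, T, S) covariate surfaces.
    y : (n, T) response curves, or None for prediction-only data.
    """

    t_grid: np.ndarray
    s_grid: np.ndarray
    x: np.ndarray
    y: np.ndarray | None = None

    def __post_init__(self):
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        self.s_grid = np.asarray(self.s_grid, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 4:
            raise ValueError("x must have shape (n, q, |t|, |s|)")
        if self.x.shape[2] != self.t_grid.size or self.x.shape[3] != self.s_grid.size:
            raise ValueError("x grid axes do not match t_grid / s_grid")
        if self.y is not None:
            self.y = np.atleast_2d(np.asarray(self.y, dtype=float))
            if self.y.shape != (self.x.shape[0], self.t_grid.size):
                raise ValueError("y must have shape (n, |t|)")

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def q(self) -> int:
        return self.x.shape[1]

    def subset(self, idx) -> "FunctionalDataset":
        """New dataset restricted to the given subject indices."""
        idx = np.asarray(idx)
        return FunctionalDataset(
            self.t_grid,
            self.s_grid,
            self.x[idx],
            None if self.y is None else self.y[idx],
        )
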