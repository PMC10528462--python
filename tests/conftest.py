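import numpy as np
import pytest

from ncrm.data import FunctionalDataset, uniform_grid
from ncrm.kernels import build_decomposition
from ncrm.simulation import gen_covariates


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def grids():
    return uniform_grid(9), uniform_grid(7)  # (t_grid, s_grid)


@pytest.fixture(scope="session")
def scheme_q2():
    return build_decomposition(2, "full_q2")


@pytest.fixture(scope="session")
def scheme_q3():
    return build_decomposition(3, "full_q3")


@pytest.fixture(scope="session")
def scheme_merged():
    return build_decomposition(3, "merged_q3")


def random_points(rng, scheme, s_grid, m):
    """Random (t, u-tuple) evaluation points for kernel property tests."""
    pts = []
    for _ in range(m):
        t = float(rng.uniform())
        u = rng.normal(size=(scheme.q, s_grid.size))
        pts.append((t, u))
    return pts


@pytest.fixture
def tiny_dataset(rng, grids):
    """3 subjects, 2 covariates, small grids, with smooth-ish responses."""
    t_grid, s_grid = grids
    x = gen_covariates(3, t_grid, s_grid, np.random.default_rng(7))
    y = (
        1.0
        + np.sin(2 * np.pi * t_grid)[None, :]
        + 0.5 * np.random.default_rng(8).normal(size=(3, t_grid.size))
    )
    return FunctionalDataset(t_grid, s_grid, x, y)
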