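import warnings

import numpy as np
import pytest

import vbcohort as vb


@pytest.fixture(scope="session")
def small_grid():
    return vb.GridSpec(t_min=0, n_t=6, a_min=1, n_a=4)


@pytest.fixture(scope="session")
def small_dataset(small_grid):
    """Compact trending-environment survey with known truth."""
    return vb.generate_dataset(
        "trending-env", seed=11, grid=small_grid, n_per_cell=80
    )


@pytest.fixture(scope="session")
def small_fits(small_dataset):
    """Constant- and varying-environment fits of the small dataset."""
    ds = small_dataset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        varying = vb.fit_model(ds.observations, ds.grid, env="varying")
        constant = vb.fit_model(ds.observations, ds.grid, env="constant")
    return constant, varying


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_params(grid, *, env_mode="varying", n_groups=1, seed=0):
    """Random valid ModelParams for a grid (positive, realistic scales)."""
    r = np.random.default_rng(seed)
    n_env = 1 if env_mode == "constant" else grid.n_t - 1
    return vb.ModelParams(
        r_b=r.uniform(0.1, 0.6),
        e_first_age=r.uniform(80, 200, grid.n_t),
        v_first_age=r.uniform(100, 900, grid.n_t),
        e_first_time=r.uniform(150, 600, grid.n_a - 1),
        v_first_time=r.uniform(100, 2500, grid.n_a - 1),
        mu_linf=r.uniform(350, 600, (n_env, n_groups)),
        sigma2_linf2=r.uniform(200, 3000, (n_env, n_groups)),
    )
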