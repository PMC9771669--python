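"""Tests of parameterization, starting values and maximum-likelihood fitting."""

import warnings

import numpy as np
import pytest

import vbcohort as vb
from vbcohort.fit import _nll_and_grad, _expand_start
from conftest import random_params


class TestPackUnpack:
    @pytest.mark.parametrize("env_mode,n_groups", [("constant", 1), ("varying", 1), ("varying", 3)])
    def test_roundtrip(self, small_grid, env_mode, n_groups):
        p = random_params(small_grid, env_mode=env_mode, n_groups=n_groups, seed=7)
        q = vb.unpack(vb.pack(p), small_grid, env_mode=env_mode, n_groups=n_groups)
        assert q.r_b == pytest.approx(p.r_b, rel=1e-12)
        for name in ("e_first_age", "v_first_age", "e_first_time", "v_first_time",
                     "mu_linf", "sigma2_linf2"):
            assert np.allclose(getattr(q, name), getattr(p, name), rtol=1e-12)

    def test_parameter_counts_match_inventory_rule(self):
        grid = vb.GridSpec(0, 32, 1, 10)
        constant = random_params(grid, env_mode="constant", seed=1)
        varying = random_params(grid, env_mode="varying", seed=1)
        assert constant.k == 85 and vb.pack(constant).size == 85
        assert varying.k == 145 and vb.pack(varying).size == 145

    def test_vector_length_mismatch_raises(self, small_grid):
        x = vb.pack(random_params(small_grid, seed=2))
        with pytest.raises(ValueError):
            vb.unpack(x[:-1], small_grid)
        with pytest.raises(ValueError):
            vb.unpack(x, small_grid, env_mode="constant")

    def test_zero_variance_product_cannot_be_packed(self, small_grid):
        p = random_params(small_grid, seed=2)
        p.sigma2_linf2[0, 0] = 0.0
        with pytest.raises(ValueError):
            vb.pack(p)


class TestGroupSpec:
    def test_age_classes_are_lower_closed(self):
        spec = vb.GroupSpec("age", (4, 8))
        assert [vb.assign_group(a, 0.0, spec) for a in (3, 4, 8)] == [0, 1, 2]

    def test_mean_length_boundary_goes_to_upper_class(self):
        spec = vb.GroupSpec("mean_length", (250.0,))
        assert vb.assign_group(5, 250.0, spec) == 1
        assert vb.assign_group(5, 249.99, spec) == 0

    def test_single_group(self):
        spec = vb.GroupSpec("age", ())
        assert spec.n_groups == 1
        assert vb.assign_group(99, 1e4, spec) == 0

    def test_parse(self):
        spec = vb.GroupSpec.parse("length:250,400")
        assert spec.mode == "mean_length" and spec.boundaries == (250.0, 400.0)
        with pytest.raises(ValueError):
            vb.GroupSpec.parse("banana:1")

    def test_boundaries_must_ascend(self):
        with pytest.raises(ValueError):
            vb.GroupSpec("age", (8, 4))


class TestInitialParameters:
    def test_recovers_noiseless_growth_curve(self, small_grid):
        e0, mu, r = 130.0, 460.0, 0.33
        rows = []
        for t in small_grid.times:
            for a in small_grid.ages:
                rows.append((t, a, vb.constant_env_mean(a - 1, e0, r, mu)))
        obs = vb.ObservationTable.from_arrays(
            time=[x[0] for x in rows], age=[x[1] for x in rows], length=[x[2] for x in rows]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            start = vb.initial_parameters(obs, small_grid)
        assert start.r_b == pytest.approx(r, rel=0.01)
        assert start.mu_linf[0, 0] == pytest.approx(mu, rel=0.01)
        assert start.e_first_age[0] == pytest.approx(e0, rel=0.01)

    def test_constant_lengths_floor_variances_with_warning(self, small_grid):
        n = 40
        obs = vb.ObservationTable.from_arrays(
            time=np.tile(np.arange(6), 7)[:n],
            age=np.tile(np.arange(1, 5), 10)[:n],
            length=np.full(n, 250.0),
        )
        with pytest.warns(RuntimeWarning):
            start = vb.initial_parameters(obs, small_grid)
        assert np.all(start.v_first_age >= vb.VAR_FLOOR)

    def test_single_age_class_unidentifiable(self, small_grid):
        obs = vb.ObservationTable.from_arrays(
            time=[0, 1, 2], age=[2, 2, 2], length=[200.0, 210.0, 190.0]
        )
        with pytest.raises(ValueError, match="age class"):
            vb.initial_parameters(obs, small_grid)


class TestAnalyticGradient:
    @pytest.mark.parametrize(
        "groups,non_shrink",
        [(None, False), (vb.GroupSpec("age", (3,)), False), (None, True)],
    )
    def test_matches_central_differences(self, small_dataset, groups, non_shrink):
        ds = small_dataset
        grid = ds.grid
        w, s1, s2 = ds.observations.cell_stats(grid)
        ng = groups.n_groups if groups else 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            start = _expand_start(
                vb.initial_parameters(ds.observations, grid), grid, "varying", ng
            )
        x = vb.pack(start)
        x += 0.01 * np.random.default_rng(1).normal(size=x.size)
        args = (w, s1, s2, grid.n_t, grid.n_a, grid.n_t - 1, ng, grid.ages,
                groups, non_shrink, vb.VAR_FLOOR)
        _, grad = _nll_and_grad(x, *args)
        h = 1e-6
        for i in range(0, x.size, 3):
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            num = (_nll_and_grad(xp, *args)[0] - _nll_and_grad(xm, *args)[0]) / (2 * h)
            assert grad[i] == pytest.approx(num, rel=1e-4, abs=1e-5)


class TestFitModel:
    def test_fit_improves_on_start_and_parameters_stay_valid(self, small_fits):
        constant, varying = small_fits
        for fit in small_fits:
            assert fit.stats.nll <= fit.start_nll + 1e-9
            assert fit.params.r_b > 0
            assert np.all(fit.params.v_first_age > 0)
            assert np.all(fit.params.mu_linf > 0)
            assert fit.stats.aic == 2 * fit.stats.k + 2 * fit.stats.nll

    def test_nested_variant_likelihoods(self, small_fits):
        constant, varying = small_fits
        assert varying.stats.nll <= constant.stats.nll + 1e-6
        assert constant.stats.k < varying.stats.k

    def test_single_all_encompassing_group_equals_no_group(self, small_dataset):
        ds = small_dataset
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            plain = vb.fit_model(ds.observations, ds.grid, env="constant")
            grouped = vb.fit_model(
                ds.observations, ds.grid, env="constant", groups=vb.GroupSpec("age", ())
            )
        assert grouped.stats.k == plain.stats.k
        assert grouped.stats.nll == pytest.approx(plain.stats.nll, abs=1e-4)

    def test_scaled_environment_reporting(self, small_dataset):
        ds = small_dataset
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = vb.fit_model(ds.observations, ds.grid, env="constant", l_inf=780.0)
        table = fit.env_table()
        assert table["mu_scaled"].iloc[0] == pytest.approx(
            fit.params.mu_linf[0, 0] / 780.0
        )
        assert table["sigma2_scaled"].iloc[0] == pytest.approx(
            fit.params.sigma2_linf2[0, 0] / 780.0**2
        )

    def test_unknown_options_rejected(self, small_dataset):
        ds = small_dataset
        with pytest.raises(ValueError):
            vb.fit_model(ds.observations, ds.grid, env="sometimes")
        with pytest.raises(ValueError):
            vb.fit_model(ds.observations, ds.grid, method="bfgs")

    def test_mu_trajectory_recovery_on_small_fixture(self, small_dataset, small_fits):
        _, varying = small_fits
        truth = small_dataset.truth
        corr = np.corrcoef(truth.mu_linf[:, 0], varying.params.mu_linf[:, 0])[0, 1]
        assert corr > 0.9
        assert varying.params.r_b == pytest.approx(truth.r_b, rel=0.10)

    def test_varying_fit_is_stable_on_constant_truth(self, small_grid):
        # over-parameterized per-interval fit on time-constant data should
        # produce a nearly flat limitation trajectory
        ds = vb.generate_dataset("constant-env", seed=17, grid=small_grid, n_per_cell=80)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = vb.fit_model(ds.observations, ds.grid, env="varying")
        mu = fit.params.mu_linf[:, 0]
        assert mu.std() / mu.mean() < 0.10

    def test_end_to_end_prediction_matches_truth(self, small_dataset, small_fits):
        _, varying = small_fits
        truth_grid = vb.predict_grid(small_dataset.truth, small_dataset.grid)
        corr = np.corrcoef(
            truth_grid.mean.ravel(), varying.predict().mean.ravel()
        )[0, 1]
        assert corr >= 0.99
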