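"""Unit and property tests for the cohort mean/variance recursions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vbcohort as vb
from conftest import random_params

rates = st.floats(0.01, 3.0)
lengths_mm = st.floats(1.0, 900.0)
variances = st.floats(0.0, 5e4)


class TestGridSpec:
    def test_axes(self):
        g = vb.GridSpec(t_min=1990, n_t=3, a_min=1, n_a=4)
        assert list(g.times) == [1990, 1991, 1992]
        assert list(g.ages) == [1, 2, 3, 4]
        assert g.n_intervals == 2
        assert g.contains(1991, 4) and not g.contains(1993, 1)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(t_min=0, n_t=1, a_min=0, n_a=4),
            dict(t_min=0, n_t=4, a_min=0, n_a=1),
            dict(t_min=0, n_t=4, a_min=-1, n_a=4),
        ],
    )
    def test_degenerate_grids_rejected(self, kwargs):
        with pytest.raises(ValueError):
            vb.GridSpec(**kwargs)


class TestEnvInterval:
    def test_invariants(self):
        with pytest.raises(ValueError):
            vb.EnvInterval(mu_linf=0.0, sigma2_linf2=1.0)
        with pytest.raises(ValueError):
            vb.EnvInterval(mu_linf=400.0, sigma2_linf2=-1.0)


class TestPropagateMean:
    def test_fixed_point_at_asymptote(self):
        env = vb.EnvInterval(380.0, 0.0)
        assert vb.propagate_mean(380.0, 0.7, env) == pytest.approx(380.0, abs=1e-12)

    def test_large_rate_limit(self):
        env = vb.EnvInterval(380.0, 0.0)
        assert vb.propagate_mean(100.0, 50.0, env) == pytest.approx(380.0, abs=1e-9)

    def test_scalar_value(self):
        # 100 e^{-0.3} + 380 (1 - e^{-0.3})
        env = vb.EnvInterval(380.0, 0.0)
        expected = 100 * np.exp(-0.3) + 380 * (1 - np.exp(-0.3))
        got = vb.propagate_mean(100.0, 0.3, env)
        assert got == pytest.approx(expected, rel=1e-14)
        assert got == pytest.approx(172.571, abs=5e-4)

    def test_rejects_nonpositive_rate(self):
        env = vb.EnvInterval(380.0, 0.0)
        for r in (0.0, -0.2):
            with pytest.raises(ValueError):
                vb.propagate_mean(100.0, r, env)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(e=lengths_mm, r=rates, mu=lengths_mm)
    def test_result_between_previous_and_asymptote(self, e, r, mu):
        env = vb.EnvInterval(mu, 0.0)
        out = vb.propagate_mean(e, r, env)
        lo, hi = min(e, mu), max(e, mu)
        assert lo - 1e-9 <= out <= hi + 1e-9

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(e1=lengths_mm, e2=lengths_mm, r=rates, mu=lengths_mm)
    def test_monotone_in_previous_mean_and_asymptote(self, e1, e2, r, mu):
        env = vb.EnvInterval(mu, 0.0)
        lo, hi = sorted((e1, e2))
        assert vb.propagate_mean(lo, r, env) <= vb.propagate_mean(hi, r, env) + 1e-12
        env_hi = vb.EnvInterval(mu + 10.0, 0.0)
        assert vb.propagate_mean(e1, r, env) <= vb.propagate_mean(e1, r, env_hi)


class TestPropagateMeanNonShrink:
    def test_shrink_suppressed_above_asymptote(self):
        env = vb.EnvInterval(380.0, 0.0)
        assert vb.propagate_mean_nonshrink(400.0, 0.3, env) == 400.0

    def test_inactive_below_asymptote(self):
        env = vb.EnvInterval(380.0, 0.0)
        assert vb.propagate_mean_nonshrink(100.0, 0.3, env) == vb.propagate_mean(
            100.0, 0.3, env
        )

    def test_fixed_point_preserved(self):
        env = vb.EnvInterval(380.0, 0.0)
        assert vb.propagate_mean_nonshrink(380.0, 0.3, env) == pytest.approx(380.0)


class TestPropagateVar:
    def test_fixed_point_is_asymptotic_variance(self):
        env = vb.EnvInterval(400.0, 800.0)
        v_inf = vb.asymptotic_variance(0.4, 800.0)
        assert vb.propagate_var(v_inf, 0.4, env) == pytest.approx(v_inf, rel=1e-13)

    def test_no_variance_source(self):
        env = vb.EnvInterval(400.0, 0.0)
        assert vb.propagate_var(0.0, 0.5, env) == 0.0

    def test_scalar_value(self):
        env = vb.EnvInterval(400.0, 1.0)
        expected = (1 - np.exp(-1.0)) / 1.0
        assert vb.propagate_var(0.0, 0.5, env) == pytest.approx(expected, rel=1e-14)
        assert vb.propagate_var(0.0, 0.5, env) == pytest.approx(0.632121, abs=1e-6)

    def test_negative_variance_rejected(self):
        env = vb.EnvInterval(400.0, 1.0)
        with pytest.raises(ValueError):
            vb.propagate_var(-1.0, 0.5, env)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(v1=variances, v2=variances, r=rates, s2=variances)
    def test_exact_contraction_rate(self, v1, v2, r, s2):
        env = vb.EnvInterval(400.0, s2)
        gap = abs(vb.propagate_var(v1, r, env) - vb.propagate_var(v2, r, env))
        assert gap == pytest.approx(np.exp(-2 * r) * abs(v1 - v2), rel=1e-9, abs=1e-9)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(r=st.floats(0.05, 1.5), s2=st.floats(1.0, 1e4))
    def test_monotone_convergence_from_both_sides(self, r, s2):
        env = vb.EnvInterval(400.0, s2)
        v_inf = vb.asymptotic_variance(r, s2)
        for v0, from_below in ((0.0, True), (10 * v_inf, False)):
            v = v0
            for _ in range(60):
                v_next = vb.propagate_var(v, r, env)
                if from_below:
                    assert v_next >= v - 1e-9
                else:
                    assert v_next <= v + 1e-9
                v = v_next
            assert abs(v - v_inf) < abs(v0 - v_inf) + 1e-12


class TestAsymptoticVariance:
    @pytest.mark.parametrize(
        "r, s2, expected", [(0.5, 1.0, 1.0), (0.25, 2.0, 4.0)]
    )
    def test_values(self, r, s2, expected):
        assert vb.asymptotic_variance(r, s2) == pytest.approx(expected)

    def test_iteration_converges_to_formula(self, rng):
        for _ in range(20):
            r = rng.uniform(0.05, 1.0)
            s2 = rng.uniform(1.0, 1e4)
            env = vb.EnvInterval(400.0, s2)
            v = 0.0
            for _ in range(1000):
                v = vb.propagate_var(v, r, env)
            assert v == pytest.approx(vb.asymptotic_variance(r, s2), abs=1e-10)

    def test_rejects_nonpositive_rate(self):
        with pytest.raises(ValueError):
            vb.asymptotic_variance(0.0, 1.0)


class TestConstantEnvMean:
    def test_identity_at_zero_offset(self):
        assert vb.constant_env_mean(0, 120.0, 0.3, 400.0) == pytest.approx(120.0)

    def test_asymptote_at_large_offset(self):
        assert vb.constant_env_mean(500, 120.0, 0.3, 400.0) == pytest.approx(400.0)

    def test_negative_offset_rejected(self):
        with pytest.raises(ValueError):
            vb.constant_env_mean(-1, 120.0, 0.3, 400.0)

    def test_matches_iterated_one_step_updates(self):
        env = vb.EnvInterval(400.0, 0.0)
        e = 120.0
        for k in range(1, 21):
            e = vb.propagate_mean(e, 0.3, env)
            assert e == pytest.approx(
                vb.constant_env_mean(k, 120.0, 0.3, 400.0), abs=1e-12
            )


class TestPredictGrid:
    def test_asymptote_fixed_point_on_grid(self):
        grid = vb.GridSpec(0, 2, 0, 2)
        params = vb.ModelParams(
            r_b=0.4,
            e_first_age=[380.0, 380.0],
            v_first_age=[10.0, 10.0],
            e_first_time=[380.0],
            v_first_time=[10.0],
            mu_linf=[[380.0]],
            sigma2_linf2=[[8.0]],
        )
        cg = vb.predict_grid(params, grid)
        assert cg.mean == pytest.approx(np.full((2, 2), 380.0))

    def test_diagonals_match_closed_form(self):
        grid = vb.GridSpec(0, 8, 0, 8)
        e0, r, mu = 95.0, 0.35, 520.0
        params = vb.ModelParams(
            r_b=r,
            e_first_age=np.full(8, e0),
            v_first_age=np.full(8, 50.0),
            e_first_time=[vb.constant_env_mean(a, e0, r, mu) for a in range(1, 8)],
            v_first_time=np.full(7, 50.0),
            mu_linf=[[mu]],
            sigma2_linf2=[[100.0]],
        )
        cg = vb.predict_grid(params, grid)
        for i in range(8):  # cohort entering at occasion i, age 0
            for k in range(8 - i):
                assert cg.mean[i + k, k] == pytest.approx(
                    vb.constant_env_mean(k, e0, r, mu), abs=1e-12
                )

    def test_cohort_invariance_under_constant_environment(self, small_grid):
        params = random_params(small_grid, env_mode="constant", seed=3)
        params.e_first_age[:] = params.e_first_age[0]
        params.v_first_age[:] = params.v_first_age[0]
        env = vb.EnvInterval(params.mu_linf[0, 0], params.sigma2_linf2[0, 0])
        e, v = params.e_first_age[0], params.v_first_age[0]
        for a in range(1, small_grid.n_a):
            e = vb.propagate_mean(e, params.r_b, env)
            v = vb.propagate_var(v, params.r_b, env)
            params.e_first_time[a - 1] = e
            params.v_first_time[a - 1] = v
        cg = vb.predict_grid(params, small_grid)
        # every cohort shares one length-at-age curve
        for j in range(small_grid.n_a):
            col = cg.mean[:, j]
            assert np.allclose(col, col[0], atol=1e-9)

    def test_variance_never_negative(self, small_grid):
        cg = vb.predict_grid(random_params(small_grid, seed=5), small_grid)
        assert np.all(cg.var >= 0)

    def test_group_count_mismatch_rejected(self, small_grid):
        params = random_params(small_grid, n_groups=2, seed=1)
        with pytest.raises(ValueError):
            vb.predict_grid(params, small_grid)  # no group_spec supplied
        spec3 = vb.GroupSpec("age", (2, 3))
        with pytest.raises(ValueError):
            vb.predict_grid(params, small_grid, group_spec=spec3)

    def test_cell_lookup_outside_grid(self, small_grid):
        cg = vb.predict_grid(random_params(small_grid, seed=2), small_grid)
        with pytest.raises(KeyError):
            cg.cell(small_grid.t_min - 1, small_grid.a_min)
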