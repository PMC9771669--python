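"""Parameterization and maximum-likelihood fitting of the cohort growth model.

Free parameters (all strictly positive, optimized in log space):

* ``r_b`` — Von Bertalanffy rate scalar, per sampling interval (1 value);
* mean and variance of length at the first age class, one pair per
  occasion (2 * n_t values);
* mean and variance of length for each older age class at the first
  occasion (2 * (n_a - 1) values);
* mean asymptotic length ``mu_linf`` (mm) and variance product
  ``sigma2_linf2`` (mm^2 * time) per interval and environment group
  (2 * n_intervals * n_groups values, with n_intervals = 1 when the
  limitation is held constant over time).

The species maximum asymptotic length only ever multiplies the
environmental limitation, so it cannot be estimated here; supplying it as
an external constant merely rescales the reported products into a
dimensionless limitation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import optimize

from .growth import EnvInterval, GridSpec, CohortGrid, _predict_arrays
from .likelihood import (
    VAR_FLOOR,
    FitStatistics,
    ObservationTable,
    _nll_from_stats,
)

__all__ = [
    "GroupSpec",
    "ModelParams",
    "FitResult",
    "pack",
    "unpack",
    "initial_parameters",
    "fit_model",
    "assign_group",
]


@dataclass(frozen=True)
class GroupSpec:
    """Partition of cohorts into environment groups.

    ``mode`` is ``"age"`` (classify by cohort age) or ``"mean_length"``
    (classify by the cohort's *predicted mean* length, never by individual
    lengths).  ``boundaries`` are ascending cut points; classes are
    lower-closed, upper-open, so a value equal to a boundary falls in the
    upper class.  Classification uses the cohort state at the start of each
    interval.
    """

    mode: str
    boundaries: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("age", "mean_length"):
            raise ValueError("mode must be 'age' or 'mean_length'")
        b = tuple(float(x) for x in self.boundaries)
        if any(b2 <= b1 for b1, b2 in zip(b, b[1:])):
            raise ValueError("boundaries must be strictly ascending")
        object.__setattr__(self, "boundaries", b)

    @property
    def n_groups(self) -> int:
        return len(self.boundaries) + 1

    def assign_array(self, ages: np.ndarray, mean_lengths: np.ndarray) -> np.ndarray:
        value = ages if self.mode == "age" else mean_lengths
        return np.digitize(np.asarray(value, dtype=float), self.boundaries, right=False)

    def assign(self, age: float, mean_length: float) -> int:
        return int(self.assign_array(np.array([age]), np.array([mean_length]))[0])

    @classmethod
    def parse(cls, text: str) -> "GroupSpec":
        """Parse ``"age:4,8"`` or ``"length:250,400"`` (CLI syntax)."""
        try:
            mode, cuts = text.split(":", 1)
        except ValueError:
            raise ValueError(f"cannot parse group spec {text!r}; expected 'age:4,8'")
        mode = {"age": "age", "length": "mean_length", "mean_length": "mean_length"}.get(
            mode.strip()
        )
        if mode is None:
            raise ValueError(f"unknown group mode in {text!r}")
        boundaries = tuple(float(x) for x in cuts.split(",") if x.strip())
        return cls(mode=mode, boundaries=boundaries)


def assign_group(age: float, mean_length: float, spec: GroupSpec) -> int:
    """Environment-group index of a cohort with the given state."""
    return spec.assign(age, mean_length)


@dataclass
class ModelParams:
    """All free parameters of the cohort growth model (see module docstring).

    ``mu_linf`` and ``sigma2_linf2`` have shape (n_env, n_groups) with
    n_env = 1 for a time-constant environment or n_t - 1 for a per-interval
    one.  ``sigma2_linf2`` may be zero (a noise-free environment) for
    prediction, but cannot then be packed for optimization.
    """

    r_b: float
    e_first_age: np.ndarray
    v_first_age: np.ndarray
    e_first_time: np.ndarray
    v_first_time: np.ndarray
    mu_linf: np.ndarray
    sigma2_linf2: np.ndarray

    def __post_init__(self) -> None:
        self.r_b = float(self.r_b)
        for name in ("e_first_age", "v_first_age", "e_first_time", "v_first_time"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        self.mu_linf = np.atleast_2d(np.asarray(self.mu_linf, dtype=float))
        self.sigma2_linf2 = np.atleast_2d(np.asarray(self.sigma2_linf2, dtype=float))
        if self.r_b <= 0:
            raise ValueError("r_b must be strictly positive")
        if len(self.e_first_age) != len(self.v_first_age):
            raise ValueError("first-age mean/variance lengths differ")
        if len(self.e_first_time) != len(self.v_first_time):
            raise ValueError("first-occasion mean/variance lengths differ")
        if self.mu_linf.shape != self.sigma2_linf2.shape:
            raise ValueError("mu_linf and sigma2_linf2 shapes differ")
        for arr, name in (
            (self.e_first_age, "e_first_age"),
            (self.v_first_age, "v_first_age"),
            (self.e_first_time, "e_first_time"),
            (self.v_first_time, "v_first_time"),
            (self.mu_linf, "mu_linf"),
        ):
            if np.any(arr <= 0):
                raise ValueError(f"{name} must be strictly positive")
        if np.any(self.sigma2_linf2 < 0):
            raise ValueError("sigma2_linf2 must be non-negative")

    # -- derived structure ----------------------------------------------

    @property
    def n_t(self) -> int:
        return len(self.e_first_age)

    @property
    def n_a(self) -> int:
        return len(self.e_first_time) + 1

    @property
    def n_env_intervals(self) -> int:
        return self.mu_linf.shape[0]

    @property
    def n_groups(self) -> int:
        return self.mu_linf.shape[1]

    @property
    def env_mode(self) -> str:
        return "constant" if self.n_env_intervals == 1 else "varying"

    @property
    def k(self) -> int:
        """Free-parameter count: 1 + 2 n_t + 2 (n_a - 1) + 2 n_env n_groups."""
        return (
            1
            + 2 * self.n_t
            + 2 * (self.n_a - 1)
            + 2 * self.n_env_intervals * self.n_groups
        )

    def env(self, interval_index: int, group: int = 0) -> EnvInterval:
        """EnvInterval for the given within-grid interval and group."""
        ei = interval_index if self.n_env_intervals > 1 else 0
        return EnvInterval(
            mu_linf=float(self.mu_linf[ei, group]),
            sigma2_linf2=float(self.sigma2_linf2[ei, group]),
        )

    def validate_for_grid(self, grid: GridSpec) -> None:
        if self.n_t != grid.n_t:
            raise ValueError(
                f"params describe {self.n_t} occasions, grid has {grid.n_t}"
            )
        if self.n_a != grid.n_a:
            raise ValueError(f"params describe {self.n_a} age classes, grid has {grid.n_a}")
        if self.n_env_intervals not in (1, grid.n_t - 1):
            raise ValueError(
                f"params carry {self.n_env_intervals} environment intervals; "
                f"expected 1 or {grid.n_t - 1}"
            )

    def copy(self) -> "ModelParams":
        return ModelParams(
            r_b=self.r_b,
            e_first_age=self.e_first_age.copy(),
            v_first_age=self.v_first_age.copy(),
            e_first_time=self.e_first_time.copy(),
            v_first_time=self.v_first_time.copy(),
            mu_linf=self.mu_linf.copy(),
            sigma2_linf2=self.sigma2_linf2.copy(),
        )

    def scaled_env(self, l_inf: float) -> tuple[np.ndarray, np.ndarray]:
        """Dimensionless limitation (mu, sigma2) given a species maximum length."""
        if not l_inf > 0:
            raise ValueError("l_inf must be positive")
        return self.mu_linf / l_inf, self.sigma2_linf2 / l_inf**2


def _expected_length(grid: GridSpec, env_mode: str, n_groups: int) -> int:
    n_env = 1 if env_mode == "constant" else grid.n_t - 1
    return 1 + 2 * grid.n_t + 2 * (grid.n_a - 1) + 2 * n_env * n_groups


def pack(params: ModelParams) -> np.ndarray:
    """Flatten to the log-transformed optimization vector.

    Order: log r_b, log E/V at the first age class (per occasion),
    log E/V at the first occasion (per older age), log mu_linf and
    log sigma2_linf2 (interval-major, group-minor).
    """
    if np.any(params.sigma2_linf2 <= 0):
        raise ValueError("cannot log-transform a zero variance product")
    return np.concatenate(
        [
            [np.log(params.r_b)],
            np.log(params.e_first_age),
            np.log(params.v_first_age),
            np.log(params.e_first_time),
            np.log(params.v_first_time),
            np.log(params.mu_linf).ravel(),
            np.log(params.sigma2_linf2).ravel(),
        ]
    )


def _unpack_raw(
    x: np.ndarray, n_t: int, n_a: int, n_env: int, n_groups: int
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    e = np.exp(x)
    i = 1
    e_fa = e[i : i + n_t]
    i += n_t
    v_fa = e[i : i + n_t]
    i += n_t
    e_ft = e[i : i + n_a - 1]
    i += n_a - 1
    v_ft = e[i : i + n_a - 1]
    i += n_a - 1
    mu = e[i : i + n_env * n_groups].reshape(n_env, n_groups)
    i += n_env * n_groups
    s2 = e[i:].reshape(n_env, n_groups)
    return e[0], e_fa, v_fa, e_ft, v_ft, mu, s2


def unpack(
    x: np.ndarray, grid: GridSpec, *, env_mode: str = "varying", n_groups: int = 1
) -> ModelParams:
    """Inverse of :func:`pack` for the given grid and model variant."""
    x = np.asarray(x, dtype=float)
    expected = _expected_length(grid, env_mode, n_groups)
    if x.shape != (expected,):
        raise ValueError(
            f"parameter vector has length {x.size}, expected {expected} for "
            f"{env_mode} environment with {n_groups} group(s) on this grid"
        )
    n_env = 1 if env_mode == "constant" else grid.n_t - 1
    r_b, e_fa, v_fa, e_ft, v_ft, mu, s2 = _unpack_raw(x, grid.n_t, grid.n_a, n_env, n_groups)
    return ModelParams(
        r_b=r_b,
        e_first_age=e_fa,
        v_first_age=v_fa,
        e_first_time=e_ft,
        v_first_time=v_ft,
        mu_linf=mu,
        sigma2_linf2=s2,
    )


# -- starting values ------------------------------------------------------


def _weighted_mean_var(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    wsum = w.sum()
    m = float(np.sum(w * x) / wsum)
    v = float(np.sum(w * (x - m) ** 2) / wsum)
    return m, v


def _vb_curve(age_rel, e0, linf, r_b):
    return linf + (e0 - linf) * np.exp(-r_b * age_rel)


def initial_parameters(
    obs: ObservationTable, grid: GridSpec, *, var_floor: float = VAR_FLOOR
) -> ModelParams:
    """Starting values from a single pooled Von Bertalanffy curve.

    A deterministic growth curve is fitted to all weighted (age, length)
    pairs by weighted least squares, ignoring year and cohort structure.
    The fitted curve seeds the boundary means and the (time-constant)
    asymptotic length; the weighted variances of the youngest and oldest
    age classes seed the boundary variances and — through the stationary
    variance relation — the environmental variance product.
    """
    df = obs.data
    ages = df["age"].to_numpy(dtype=float)
    lengths = df["length"].to_numpy(dtype=float)
    weights = df["weight"].to_numpy(dtype=float)
    keep = weights > 0
    if np.unique(ages[keep]).size < 2:
        raise ValueError(
            "all observations share one age class; growth curve unidentifiable"
        )
    if np.unique(df["time"].to_numpy()[keep]).size < 2:
        raise ValueError("observations span fewer than two occasions")

    a = ages[keep] - grid.a_min
    x = lengths[keep]
    w = weights[keep]

    young = a == a.min()
    old = a == a.max()
    e0_guess, v_young = _weighted_mean_var(x[young], w[young])
    linf_guess, v_old = _weighted_mean_var(x[old], w[old])
    linf_guess = max(linf_guess, e0_guess * 1.05)
    try:
        popt, _ = optimize.curve_fit(
            _vb_curve,
            a,
            x,
            p0=[e0_guess, linf_guess, 0.3],
            sigma=1.0 / np.sqrt(w),
            bounds=([1e-6, 1e-6, 1e-4], [np.inf, np.inf, 20.0]),
            maxfev=20000,
        )
        e0, linf, r_b = (float(v) for v in popt)
    except RuntimeError:
        # Degenerate data (e.g. constant lengths): fall back to a flat curve.
        e0 = float(np.sum(w * x) / w.sum())
        linf, r_b = e0 * 1.001, 0.3
        warnings.warn(
            "pooled growth-curve fit failed; using flat starting curve",
            RuntimeWarning,
            stacklevel=2,
        )

    if v_young < var_floor or v_old < var_floor:
        warnings.warn(
            "age-class variance at or below floor; starting variances clamped",
            RuntimeWarning,
            stacklevel=2,
        )
    v_young = max(v_young, var_floor)
    v_old = max(v_old, var_floor)
    sigma2 = max(2.0 * r_b * v_old, var_floor)

    older = np.arange(1, grid.n_a, dtype=float)
    e_first_time = _vb_curve(older, e0, linf, r_b)
    # Variance seed follows the variance recursion between the two anchors.
    v_first_time = v_old + (v_young - v_old) * np.exp(-2.0 * r_b * older)

    return ModelParams(
        r_b=r_b,
        e_first_age=np.full(grid.n_t, e0),
        v_first_age=np.full(grid.n_t, v_young),
        e_first_time=e_first_time,
        v_first_time=np.maximum(v_first_time, var_floor),
        mu_linf=[[linf]],
        sigma2_linf2=[[sigma2]],
    )


def _expand_start(
    start: ModelParams, grid: GridSpec, env_mode: str, n_groups: int
) -> ModelParams:
    """Tile a (possibly constant, single-group) start to the target variant."""
    n_env = 1 if env_mode == "constant" else grid.n_t - 1
    mu = np.broadcast_to(
        start.mu_linf.mean(axis=0).mean(keepdims=True), (n_env, n_groups)
    ).copy() if start.mu_linf.shape != (n_env, n_groups) else start.mu_linf.copy()
    s2 = np.broadcast_to(
        start.sigma2_linf2.mean(axis=0).mean(keepdims=True), (n_env, n_groups)
    ).copy() if start.sigma2_linf2.shape != (n_env, n_groups) else start.sigma2_linf2.copy()
    out = start.copy()
    out.mu_linf = mu
    out.sigma2_linf2 = s2
    return out


# -- analytic gradient -----------------------------------------------------


def _nll_and_grad(
    x: np.ndarray,
    w_sum: np.ndarray,
    wx_sum: np.ndarray,
    wx2_sum: np.ndarray,
    n_t: int,
    n_a: int,
    n_env: int,
    n_groups: int,
    ages: np.ndarray,
    group_spec: GroupSpec | None,
    non_shrink: bool,
    var_floor: float,
) -> tuple[float, np.ndarray]:
    """Exact NLL gradient in log-parameter space by reverse accumulation.

    The recursions are short linear chains, so their adjoint is cheap and
    exact.  Group membership (a function of cohort age or predicted mean)
    is treated as locally constant: it is piecewise constant in the
    parameters, so this is the correct gradient almost everywhere.
    Variance-floored cells contribute no variance sensitivity.
    """
    r_b, e_fa, v_fa, e_ft, v_ft, mu, s2 = _unpack_raw(x, n_t, n_a, n_env, n_groups)
    decay = np.exp(-r_b)
    decay2 = decay * decay
    gain_m = 1.0 - decay
    gain_v = (1.0 - decay2) / (2.0 * r_b)
    # d/dr of the variance gain (1 - e^(-2r)) / (2r)
    dgain_v = (2.0 * decay2 * 2.0 * r_b - 2.0 * (1.0 - decay2)) / (4.0 * r_b * r_b)
    cohort_ages = ages[:-1]

    mean = np.empty((n_t, n_a))
    var = np.empty((n_t, n_a))
    mean[:, 0] = e_fa
    var[:, 0] = v_fa
    mean[0, 1:] = e_ft
    var[0, 1:] = v_ft
    g_trace: list[np.ndarray | None] = []
    clamp_trace: list[np.ndarray | None] = []
    for i in range(n_t - 1):
        ei = i if n_env > 1 else 0
        prev_m = mean[i, :-1]
        if group_spec is None:
            g = None
            mu_row = mu[ei, 0]
            s2_row = s2[ei, 0]
        else:
            g = group_spec.assign_array(cohort_ages, prev_m)
            mu_row = mu[ei, g]
            s2_row = s2[ei, g]
        nxt = prev_m * decay + mu_row * gain_m
        if non_shrink:
            clamped = prev_m > nxt
            nxt = np.where(clamped, prev_m, nxt)
        else:
            clamped = None
        mean[i + 1, 1:] = nxt
        var[i + 1, 1:] = var[i, :-1] * decay2 + s2_row * gain_v
        g_trace.append(g)
        clamp_trace.append(clamped)

    occupied = w_sum > 0
    v_eff = np.maximum(var, var_floor)
    quad = wx2_sum - 2.0 * mean * wx_sum + mean * mean * w_sum
    nll = 0.5 * float(
        np.sum(
            (w_sum * (np.log(2.0 * np.pi * v_eff)) + quad / v_eff)[occupied]
        )
    )
    gm = np.where(occupied, (mean * w_sum - wx_sum) / v_eff, 0.0)
    gv = np.where(
        occupied & (var >= var_floor),
        0.5 * (w_sum / v_eff - quad / (v_eff * v_eff)),
        0.0,
    )

    grad_mu = np.zeros_like(mu)
    grad_s2 = np.zeros_like(s2)
    grad_r = 0.0
    for i in range(n_t - 2, -1, -1):
        ei = i if n_env > 1 else 0
        gm_next = gm[i + 1, 1:]
        gv_next = gv[i + 1, 1:]
        g = g_trace[i]
        clamped = clamp_trace[i]
        prev_m = mean[i, :-1]
        prev_v = var[i, :-1]
        if g is None:
            mu_row = np.full(n_a - 1, mu[ei, 0])
            s2_row = np.full(n_a - 1, s2[ei, 0])
        else:
            mu_row = mu[ei, g]
            s2_row = s2[ei, g]
        if clamped is None:
            active = np.ones(n_a - 1, dtype=bool)
        else:
            active = ~clamped
        # mean recursion adjoint
        gm[i, :-1] += np.where(active, gm_next * decay, gm_next)
        contrib_mu = np.where(active, gm_next * gain_m, 0.0)
        grad_r += float(
            np.sum(np.where(active, gm_next * decay * (mu_row - prev_m), 0.0))
        )
        # variance recursion adjoint
        gv[i, :-1] += gv_next * decay2
        contrib_s2 = gv_next * gain_v
        grad_r += float(np.sum(gv_next * (-2.0 * decay2 * prev_v + s2_row * dgain_v)))
        if g is None:
            grad_mu[ei, 0] += contrib_mu.sum()
            grad_s2[ei, 0] += contrib_s2.sum()
        else:
            np.add.at(grad_mu[ei], g, contrib_mu)
            np.add.at(grad_s2[ei], g, contrib_s2)

    grad = np.concatenate(
        [
            [grad_r * r_b],
            gm[:, 0] * e_fa,
            gv[:, 0] * v_fa,
            gm[0, 1:] * e_ft,
            gv[0, 1:] * v_ft,
            (grad_mu * mu).ravel(),
            (grad_s2 * s2).ravel(),
        ]
    )
    return nll, grad


# -- fitting ---------------------------------------------------------------


@dataclass
class FitResult:
    """Optimized parameters plus fit statistics and convergence metadata."""

    params: ModelParams
    stats: FitStatistics
    grid: GridSpec
    converged: bool
    n_evaluations: int
    start_nll: float
    env_mode: str
    group_spec: GroupSpec | None = None
    non_shrink: bool = False
    method: str = "powell"
    seed: int | None = None
    l_inf: float | None = None
    message: str = ""
    data_fingerprint: tuple = ()

    def predict(self) -> CohortGrid:
        """Cohort grid predicted by the fitted parameters."""
        from .growth import predict_grid

        return predict_grid(
            self.params,
            self.grid,
            group_spec=self.group_spec,
            non_shrink=self.non_shrink,
        )

    def env_table(self):
        """Per-interval environment estimates, scaled when ``l_inf`` is known.

        The scaled columns divide the fitted products by the supplied
        species maximum length (and its square), turning them into the
        dimensionless limitation and its variance.
        """
        import pandas as pd

        n_env = self.params.n_env_intervals
        times = (
            [self.grid.t_min] if n_env == 1 else list(self.grid.times[:-1])
        )
        rows = []
        for ei, t in enumerate(times):
            for g in range(self.params.n_groups):
                row = {
                    "interval_start": t,
                    "group": g,
                    "mu_linf": self.params.mu_linf[ei, g],
                    "sigma2_linf2": self.params.sigma2_linf2[ei, g],
                }
                if self.l_inf is not None:
                    row["mu_scaled"] = self.params.mu_linf[ei, g] / self.l_inf
                    row["sigma2_scaled"] = (
                        self.params.sigma2_linf2[ei, g] / self.l_inf**2
                    )
                rows.append(row)
        return pd.DataFrame(rows)


def _fingerprint(obs: ObservationTable) -> tuple:
    df = obs.data
    return (
        len(df),
        round(float(df["weight"].sum()), 6),
        round(float((df["weight"] * df["length"]).sum()), 3),
    )


def fit_model(
    obs: ObservationTable,
    grid: GridSpec,
    *,
    env: str = "varying",
    groups: GroupSpec | None = None,
    non_shrink: bool = False,
    method: str = "powell",
    tol: float = 1e-10,
    maxeval: int | None = None,
    restarts: int = 0,
    restart_scale: float = 0.05,
    seed: int | None = None,
    l_inf: float | None = None,
    start: ModelParams | None = None,
    polish: bool = True,
    var_floor: float = VAR_FLOOR,
) -> FitResult:
    """Maximum-likelihood fit of the cohort growth model.

    Runs a derivative-free local optimizer (``"powell"`` or
    ``"nelder-mead"``) in log-parameter space from :func:`initial_parameters`
    (or ``start``).  ``env`` selects a time-constant or per-interval
    environmental limitation; ``groups`` adds separate limitation per
    age/length class; ``non_shrink`` forbids decreasing cohort means.
    ``restarts`` > 0 adds seed-jittered restarts around the starting point
    and keeps the best optimum (off by default).

    With ``polish`` (the default) the derivative-free optimum is refined
    by a quasi-Newton step using the exact analytic gradient of the
    likelihood; this matters in the weakly identified directions that
    arise with sparse or omitted occasions, where simplex- and
    line-search-family optimizers terminate well short of the maximum.
    """
    if env not in ("constant", "varying"):
        raise ValueError("env must be 'constant' or 'varying'")
    if method not in ("powell", "nelder-mead"):
        raise ValueError("method must be 'powell' or 'nelder-mead'")
    n_groups = groups.n_groups if groups is not None else 1

    w_sum, wx, wx2 = obs.cell_stats(grid)
    empty_cells = [
        (int(t + grid.t_min), int(a + grid.a_min))
        for t, a in zip(*np.nonzero(w_sum == 0))
    ]
    if empty_cells:
        warnings.warn(
            f"{len(empty_cells)} grid cells carry zero observation weight; "
            f"their boundary parameters are weakly identified: {empty_cells[:10]}"
            + ("..." if len(empty_cells) > 10 else ""),
            RuntimeWarning,
            stacklevel=2,
        )

    start_params = start if start is not None else initial_parameters(obs, grid, var_floor=var_floor)
    start_params = _expand_start(start_params, grid, env, n_groups)
    x0 = pack(start_params)

    n_env = 1 if env == "constant" else grid.n_t - 1
    n_t, n_a = grid.n_t, grid.n_a
    ages = grid.ages
    n_eval = 0
    best = {"x": x0.copy(), "f": np.inf}

    def objective(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        r_b, e_fa, v_fa, e_ft, v_ft, mu, s2 = _unpack_raw(x, n_t, n_a, n_env, n_groups)
        mean, var = _predict_arrays(
            r_b, e_fa, v_fa, e_ft, v_ft, mu, s2, n_t, n_a, ages, groups, non_shrink
        )
        nll, _ = _nll_from_stats(w_sum, wx, wx2, mean, var, var_floor)
        if not np.isfinite(nll):
            return np.inf
        if nll < best["f"]:
            best["f"] = nll
            best["x"] = x.copy()
        return nll

    f0 = objective(x0)
    if not np.isfinite(f0):
        raise RuntimeError("likelihood is non-finite at the starting values")

    if maxeval is None:
        maxeval = 1500 * x0.size

    def run(x_init: np.ndarray):
        if method == "powell":
            options = {"ftol": tol, "xtol": 1e-8, "maxfev": maxeval}
            return optimize.minimize(objective, x_init, method="Powell", options=options)
        options = {
            "fatol": max(tol * max(1.0, abs(f0)), 1e-12),
            "xatol": 1e-8,
            "maxfev": maxeval,
            "adaptive": True,
        }
        return optimize.minimize(objective, x_init, method="Nelder-Mead", options=options)

    res = run(x0)
    converged = bool(res.success)
    message = str(res.message)
    if restarts > 0:
        rng = np.random.default_rng(seed)
        for _ in range(restarts):
            jitter = rng.normal(0.0, restart_scale, size=x0.size)
            r2 = run(x0 + jitter)
            if r2.fun < res.fun:
                res, converged, message = r2, bool(r2.success), str(r2.message)

    x_best = best["x"] if best["f"] <= res.fun else np.asarray(res.x)

    if polish:
        def value_and_grad(x: np.ndarray):
            nonlocal n_eval
            n_eval += 1
            nll, grad = _nll_and_grad(
                x, w_sum, wx, wx2, n_t, n_a, n_env, n_groups, ages, groups,
                non_shrink, var_floor,
            )
            if nll < best["f"]:
                best["f"] = nll
                best["x"] = x.copy()
            return nll, grad

        pol = optimize.minimize(
            value_and_grad,
            x_best,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 5000, "ftol": 1e-14, "gtol": 1e-9},
        )
        if pol.fun <= best["f"]:
            best["f"] = float(pol.fun)
            best["x"] = np.asarray(pol.x)
        x_best = best["x"]

    params = unpack(x_best, grid, env_mode=env, n_groups=n_groups)
    mean, var = _predict_arrays(
        params.r_b,
        params.e_first_age,
        params.v_first_age,
        params.e_first_time,
        params.v_first_time,
        params.mu_linf,
        params.sigma2_linf2,
        n_t,
        n_a,
        ages,
        groups,
        non_shrink,
    )
    nll, n_floored = _nll_from_stats(w_sum, wx, wx2, mean, var, var_floor)
    stats = FitStatistics(
        nll=nll,
        k=params.k,
        weighted_n=float(w_sum.sum()),
        n_floored_cells=n_floored,
        zero_weight_cells=tuple(empty_cells),
    )
    return FitResult(
        params=params,
        stats=stats,
        grid=grid,
        converged=converged,
        n_evaluations=n_eval,
        start_nll=f0,
        env_mode=env,
        group_spec=groups,
        non_shrink=non_shrink,
        method=method,
        seed=seed,
        l_inf=l_inf,
        message=message,
        data_fingerprint=_fingerprint(obs),
    )
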