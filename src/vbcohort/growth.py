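"""Mean/variance recursions for cohort length-at-age on a time x age lattice.

The model tracks, for every cohort in a population, the Gaussian distribution
of body length at discrete, evenly spaced sampling occasions.  Individual
growth follows a Von Bertalanffy curve whose asymptotic length is the product
of a species maximum and a fluctuating, individually variable environmental
limitation.  Averaging that limitation over one inter-sampling interval gives
closed-form one-step updates for the cohort mean and variance:

    E[l(T+1, a+1)] = E[l(T, a)] * exp(-r_B) + mu_linf * (1 - exp(-r_B))
    V[l(T+1, a+1)] = V[l(T, a)] * exp(-2 r_B)
                     + sigma2_linf2 * (1 - exp(-2 r_B)) / (2 r_B)

where ``mu_linf`` (mm) is the mean asymptotic length over the interval and
``sigma2_linf2`` (mm^2 * time) the corresponding variance product.  Iterating
the variance update converges to the stationary within-cohort variance
``sigma2_linf2 / (2 r_B)``.

All rates are expressed per sampling interval; the interval is the unit of
time throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .fit import GroupSpec, ModelParams

__all__ = [
    "GridSpec",
    "EnvInterval",
    "CohortGrid",
    "propagate_mean",
    "propagate_mean_nonshrink",
    "propagate_var",
    "asymptotic_variance",
    "constant_env_mean",
    "predict_grid",
]


@dataclass(frozen=True)
class GridSpec:
    """Discrete time x age lattice on which cohorts are tracked.

    Occasions run ``t_min .. t_min + n_t - 1`` and age classes
    ``a_min .. a_min + n_a - 1``.  A cohort occupies a diagonal of the
    lattice: one step in time is one step in age.
    """

    t_min: int
    n_t: int
    a_min: int
    n_a: int

    def __post_init__(self) -> None:
        for name in ("t_min", "n_t", "a_min", "n_a"):
            value = getattr(self, name)
            if int(value) != value:
                raise ValueError(f"{name} must be an integer, got {value!r}")
            object.__setattr__(self, name, int(value))
        if self.n_t < 2:
            raise ValueError("need at least two sampling occasions (n_t >= 2)")
        if self.n_a < 2:
            raise ValueError("need at least two age classes (n_a >= 2)")
        if self.a_min < 0:
            raise ValueError("a_min must be non-negative")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.t_min, self.t_min + self.n_t)

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.a_min, self.a_min + self.n_a)

    @property
    def n_intervals(self) -> int:
        """Number of inter-occasion intervals covered by the grid."""
        return self.n_t - 1

    def time_index(self, t) -> np.ndarray:
        return np.asarray(t) - self.t_min

    def age_index(self, a) -> np.ndarray:
        return np.asarray(a) - self.a_min

    def contains(self, t, a) -> np.ndarray:
        ti = self.time_index(t)
        ai = self.age_index(a)
        return (ti >= 0) & (ti < self.n_t) & (ai >= 0) & (ai < self.n_a)


@dataclass(frozen=True)
class EnvInterval:
    """Environmental limitation over one inter-sampling interval.

    ``mu_linf`` is the mean asymptotic length (mm) and ``sigma2_linf2`` the
    variance product (mm^2 * time); both are the only combinations in which
    the dimensionless limitation and the species maximum length enter the
    recursions, so they are treated as single parameters.
    """

    mu_linf: float
    sigma2_linf2: float

    def __post_init__(self) -> None:
        if not self.mu_linf > 0:
            raise ValueError("mu_linf must be positive")
        if self.sigma2_linf2 < 0:
            raise ValueError("sigma2_linf2 must be non-negative")


@dataclass(frozen=True)
class CohortGrid:
    """Predicted cohort mean and variance of length for every lattice cell.

    Cells that the recursion cannot reach from the supplied boundary
    conditions hold NaN ("absent"), never a silent zero.
    """

    mean: np.ndarray
    var: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        shape = (self.grid.n_t, self.grid.n_a)
        if self.mean.shape != shape or self.var.shape != shape:
            raise ValueError(f"mean/var must have shape {shape}")
        present = np.isfinite(self.var)
        if np.any(self.var[present] < 0):
            raise ValueError("negative predicted variance")

    @property
    def present(self) -> np.ndarray:
        return np.isfinite(self.mean) & np.isfinite(self.var)

    def cell(self, t: int, a: int) -> tuple[float, float]:
        """Return (mean, variance) at occasion ``t`` and age class ``a``."""
        if not self.grid.contains(t, a):
            raise KeyError(f"cell (time={t}, age={a}) lies outside the grid")
        ti = int(self.grid.time_index(t))
        ai = int(self.grid.age_index(a))
        return float(self.mean[ti, ai]), float(self.var[ti, ai])

    def to_frame(self):
        """Long-format DataFrame with columns time, age, mean, variance."""
        import pandas as pd

        tt, aa = np.meshgrid(self.grid.times, self.grid.ages, indexing="ij")
        return pd.DataFrame(
            {
                "time": tt.ravel(),
                "age": aa.ravel(),
                "mean": self.mean.ravel(),
                "variance": self.var.ravel(),
            }
        )


def _check_rate(r_b) -> None:
    if not np.all(np.asarray(r_b) > 0):
        raise ValueError("growth rate r_b must be strictly positive")


def propagate_mean(e_prev, r_b, env: EnvInterval):
    """One-interval update of the cohort mean length (mm).

    Relaxes the mean toward the interval's mean asymptotic length at rate
    ``r_b`` per interval; the result always lies between the previous mean
    and ``env.mu_linf``.
    """
    _check_rate(r_b)
    decay = np.exp(-r_b)
    return e_prev * decay + env.mu_linf * (1.0 - decay)


def propagate_mean_nonshrink(e_prev, r_b, env: EnvInterval):
    """Mean update with shrinkage suppressed.

    When the cohort mean exceeds the current asymptotic length the plain
    update would predict shrinking individuals; this variant pins the mean
    at its previous value instead.  Use with care: it inflates the influence
    of young cohorts on the estimated limitation.
    """
    return np.maximum(e_prev, propagate_mean(e_prev, r_b, env))


def propagate_var(v_prev, r_b, env: EnvInterval):
    """One-interval update of the within-cohort length variance (mm^2).

    Variance decays at rate ``2 r_b`` and is replenished by the interval's
    environmental variance product; the update is a contraction with unique
    fixed point :func:`asymptotic_variance`.
    """
    _check_rate(r_b)
    if np.any(np.asarray(v_prev) < 0):
        raise ValueError("variance must be non-negative")
    decay = np.exp(-2.0 * r_b)
    return v_prev * decay + env.sigma2_linf2 * (1.0 - decay) / (2.0 * r_b)


def asymptotic_variance(r_b, sigma2_linf2):
    """Stationary within-cohort length variance, sigma2_linf2 / (2 r_b).

    The variance a cohort would approach after indefinitely long exposure to
    an environment with constant variability; the unique fixed point of
    :func:`propagate_var`.
    """
    _check_rate(r_b)
    if np.any(np.asarray(sigma2_linf2) < 0):
        raise ValueError("sigma2_linf2 must be non-negative")
    return sigma2_linf2 / (2.0 * r_b)


def constant_env_mean(age_offset, e0, r_b, mu_linf):
    """Cohort mean after ``age_offset`` intervals in a constant environment.

    Closed form of the mean recursion with a time-constant asymptotic
    length: ``mu_linf + (e0 - mu_linf) * exp(-r_b * age_offset)``.
    """
    _check_rate(r_b)
    if np.any(np.asarray(age_offset) < 0):
        raise ValueError("age_offset must be non-negative")
    return mu_linf + (e0 - mu_linf) * np.exp(-np.asarray(r_b, dtype=float) * age_offset)


def _predict_arrays(
    r_b: float,
    e_first_age: np.ndarray,
    v_first_age: np.ndarray,
    e_first_time: np.ndarray,
    v_first_time: np.ndarray,
    mu_linf: np.ndarray,
    sigma2_linf2: np.ndarray,
    n_t: int,
    n_a: int,
    ages: np.ndarray,
    group_spec: "GroupSpec | None",
    non_shrink: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Fast recursion core shared by :func:`predict_grid` and the fitter.

    ``mu_linf``/``sigma2_linf2`` have shape (n_env, n_groups) with n_env
    either 1 (time-constant limitation) or n_t - 1 (one entry per interval).
    """
    mean = np.full((n_t, n_a), np.nan)
    var = np.full((n_t, n_a), np.nan)
    mean[:, 0] = e_first_age
    var[:, 0] = v_first_age
    mean[0, 1:] = e_first_time
    var[0, 1:] = v_first_time

    decay = np.exp(-r_b)
    decay2 = decay * decay
    gain_mean = 1.0 - decay
    gain_var = (1.0 - decay2) / (2.0 * r_b)
    n_env = mu_linf.shape[0]
    cohort_ages = ages[:-1]

    for i in range(n_t - 1):
        ei = i if n_env > 1 else 0
        prev_m = mean[i, :-1]
        prev_v = var[i, :-1]
        if group_spec is None:
            mu_row = mu_linf[ei, 0]
            s2_row = sigma2_linf2[ei, 0]
        else:
            g = group_spec.assign_array(cohort_ages, prev_m)
            mu_row = mu_linf[ei, g]
            s2_row = sigma2_linf2[ei, g]
        nxt = prev_m * decay + mu_row * gain_mean
        if non_shrink:
            nxt = np.maximum(nxt, prev_m)
        mean[i + 1, 1:] = nxt
        var[i + 1, 1:] = prev_v * decay2 + s2_row * gain_var
    return mean, var


def predict_grid(
    params: "ModelParams",
    grid: GridSpec,
    *,
    group_spec: "GroupSpec | None" = None,
    non_shrink: bool = False,
) -> CohortGrid:
    """Predict the cohort length distribution for every lattice cell.

    The first occasion row is filled from the first-occasion boundary
    parameters, the first age-class column from the per-occasion boundary
    parameters, and every interior cell (T+1, a+1) is propagated from
    (T, a) along its cohort diagonal using the environmental parameters of
    the interval [T, T+1).  When ``group_spec`` is given, a cohort is
    assigned to an environment group from its age and predicted mean length
    at the start of each interval.
    """
    params.validate_for_grid(grid)
    n_groups = params.n_groups
    if group_spec is None:
        if n_groups != 1:
            raise ValueError(
                f"params carry {n_groups} environment groups but no group_spec was given"
            )
    elif group_spec.n_groups != n_groups:
        raise ValueError(
            f"group_spec defines {group_spec.n_groups} classes, params carry {n_groups}"
        )
    mean, var = _predict_arrays(
        params.r_b,
        params.e_first_age,
        params.v_first_age,
        params.e_first_time,
        params.v_first_time,
        params.mu_linf,
        params.sigma2_linf2,
        grid.n_t,
        grid.n_a,
        grid.ages,
        group_spec,
        non_shrink,
    )
    return CohortGrid(mean=mean, var=var, grid=grid)
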