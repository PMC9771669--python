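"""Weighted Gaussian likelihood of length-at-age observations.

Every lattice cell (occasion, age class) carries an independent Gaussian
length distribution predicted by the cohort recursions.  Observations are
single (age, length) measurements per individual, optionally weighted (for
example by inverse catch-per-unit-effort to undo length-biased catchability).
Weights enter as multiplicities: the weighted log-likelihood is
``sum_i w_i * log N(x_i; E_cell, V_cell)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .growth import CohortGrid, GridSpec

__all__ = [
    "VAR_FLOOR",
    "ObservationTable",
    "FitStatistics",
    "cell_loglik",
    "total_nll",
    "lr_test",
]

#: Variance floor (mm^2) guarding degenerate cells; far below any real
#: measurement variance (lengths are recorded to >= 5 mm).
VAR_FLOOR = 1e-8

_LOG_2PI = float(np.log(2.0 * np.pi))

_COLUMNS = ("time", "age", "length", "weight")


@dataclass
class ObservationTable:
    """Individual length-at-age records: (time, age, length, weight) rows.

    ``time`` is the sampling-occasion index and ``age`` the integer age
    class; ``length`` is in mm and ``weight`` a non-negative sampling weight
    (default 1).  Rows failing validation are moved to ``rejected`` with a
    reason column rather than silently dropped.
    """

    data: pd.DataFrame
    rejected: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"observation table is missing columns: {missing}")
        self.data = self.data.loc[:, list(_COLUMNS)].reset_index(drop=True)
        if len(self.data) == 0:
            raise ValueError("observation table is empty")
        if not self.total_weight > 0:
            raise ValueError("total observation weight must be positive")

    # -- construction ---------------------------------------------------

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, grid: GridSpec | None = None
    ) -> "ObservationTable":
        """Validate a raw DataFrame row by row and keep the clean rows.

        Rejection reasons: non-integer or non-finite time/age, non-positive
        or non-finite length, negative or non-finite weight, and (when a
        grid is supplied) cells off the lattice.
        """
        df = df.copy()
        if "weight" not in df.columns:
            df["weight"] = 1.0
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")

        time = pd.to_numeric(df["time"], errors="coerce")
        age = pd.to_numeric(df["age"], errors="coerce")
        length = pd.to_numeric(df["length"], errors="coerce")
        weight = pd.to_numeric(df["weight"], errors="coerce")

        reason = np.full(len(df), "", dtype=object)

        def flag(mask: np.ndarray, why: str) -> None:
            mask = np.asarray(mask) & (reason == "")
            reason[mask] = why

        flag(~np.isfinite(time) | (time != np.round(time)), "time not an integer")
        flag(~np.isfinite(age) | (age != np.round(age)), "age not an integer")
        flag(~np.isfinite(length) | (length <= 0), "length not positive")
        flag(~np.isfinite(weight) | (weight < 0), "weight negative or non-finite")
        if grid is not None:
            on = grid.contains(time.fillna(-1).to_numpy(), age.fillna(-1).to_numpy())
            flag(~on, "cell outside the grid lattice")

        bad = reason != ""
        rejected = None
        if bad.any():
            rejected = df.loc[bad].copy()
            rejected["reason"] = reason[bad]
        clean = pd.DataFrame(
            {
                "time": time[~bad].astype(int),
                "age": age[~bad].astype(int),
                "length": length[~bad].astype(float),
                "weight": weight[~bad].astype(float),
            }
        ).reset_index(drop=True)
        if len(clean) == 0:
            raise ValueError("no valid observations after validation")
        return cls(data=clean, rejected=rejected)

    @classmethod
    def from_arrays(cls, time, age, length, weight=None) -> "ObservationTable":
        n = len(np.asarray(length))
        if weight is None:
            weight = np.ones(n)
        return cls(
            data=pd.DataFrame(
                {
                    "time": np.asarray(time, dtype=int),
                    "age": np.asarray(age, dtype=int),
                    "length": np.asarray(length, dtype=float),
                    "weight": np.asarray(weight, dtype=float),
                }
            )
        )

    # -- basic properties ------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def total_weight(self) -> float:
        return float(self.data["weight"].sum())

    def infer_grid(self) -> GridSpec:
        """Bounding lattice of the observed (time, age) pairs."""
        t = self.data["time"]
        a = self.data["age"]
        return GridSpec(
            t_min=int(t.min()),
            n_t=int(t.max() - t.min() + 1),
            a_min=int(a.min()),
            n_a=int(a.max() - a.min() + 1),
        )

    def unweighted(self) -> "ObservationTable":
        """Copy with every weight reset to 1."""
        df = self.data.copy()
        df["weight"] = 1.0
        return ObservationTable(data=df)

    def without_occasion(self, t: int) -> "ObservationTable":
        """Copy with all rows of occasion ``t`` removed."""
        df = self.data.loc[self.data["time"] != t].reset_index(drop=True)
        return ObservationTable(data=df)

    # -- likelihood plumbing ---------------------------------------------

    def cell_stats(self, grid: GridSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-cell weighted sufficient statistics (sum w, sum w*x, sum w*x^2).

        The Gaussian cell log-likelihood depends on the data only through
        these three (n_t, n_a) arrays, which makes repeated likelihood
        evaluation during optimization cheap.
        """
        t = self.data["time"].to_numpy()
        a = self.data["age"].to_numpy()
        on = grid.contains(t, a)
        if not on.all():
            bad = self.data.loc[~on, ["time", "age"]].drop_duplicates()
            pairs = sorted(map(tuple, bad.to_numpy()))
            raise ValueError(f"observations fall outside the grid at cells {pairs}")
        x = self.data["length"].to_numpy()
        w = self.data["weight"].to_numpy()
        idx = (t - grid.t_min) * grid.n_a + (a - grid.a_min)
        size = grid.n_t * grid.n_a
        w_sum = np.bincount(idx, weights=w, minlength=size)
        wx = np.bincount(idx, weights=w * x, minlength=size)
        wx2 = np.bincount(idx, weights=w * x * x, minlength=size)
        shape = (grid.n_t, grid.n_a)
        return w_sum.reshape(shape), wx.reshape(shape), wx2.reshape(shape)


@dataclass(frozen=True)
class FitStatistics:
    """Negative weighted log-likelihood and model-comparison statistics."""

    nll: float
    k: int
    weighted_n: float
    n_floored_cells: int = 0
    zero_weight_cells: tuple = ()

    @property
    def aic(self) -> float:
        return 2.0 * self.k + 2.0 * self.nll


def _nll_from_stats(
    w_sum: np.ndarray,
    wx_sum: np.ndarray,
    wx2_sum: np.ndarray,
    mean: np.ndarray,
    var: np.ndarray,
    var_floor: float = VAR_FLOOR,
) -> tuple[float, int]:
    """Negative weighted log-likelihood from per-cell sufficient statistics.

    Cells with zero total weight contribute nothing.  Variances below the
    floor are clamped; the number of floored occupied cells is returned so
    callers can flag it.
    """
    occupied = w_sum > 0
    if not occupied.any():
        return 0.0, 0
    if np.any(~np.isfinite(mean[occupied])) or np.any(~np.isfinite(var[occupied])):
        raise ValueError("observations fall in absent (unpredicted) grid cells")
    v = np.maximum(var[occupied], var_floor)
    n_floored = int(np.count_nonzero(var[occupied] < var_floor))
    m = mean[occupied]
    w = w_sum[occupied]
    s1 = wx_sum[occupied]
    s2 = wx2_sum[occupied]
    quad = s2 - 2.0 * m * s1 + m * m * w
    nll = 0.5 * float(np.sum(w * (_LOG_2PI + np.log(v)) + quad / v))
    return nll, n_floored


def cell_loglik(lengths, weights, mean, var, *, var_floor: float = VAR_FLOOR) -> float:
    """Weighted Gaussian log-likelihood of one cell's observations.

    Returns ``sum_i w_i * log N(x_i; mean, var)``.  A variance below the
    floor is clamped (with a warning) so the result is always finite.
    """
    x = np.asarray(lengths, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.shape != w.shape:
        raise ValueError("lengths and weights must have the same shape")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if var < var_floor:
        warnings.warn(
            f"cell variance {var:g} below floor {var_floor:g}; clamped",
            RuntimeWarning,
            stacklevel=2,
        )
        var = var_floor
    z = (x - mean) ** 2 / var
    return float(np.sum(w * (-0.5 * (_LOG_2PI + np.log(var) + z))))


def total_nll(
    obs: ObservationTable, grid_pred: CohortGrid, *, var_floor: float = VAR_FLOOR
) -> float:
    """Negative weighted log-likelihood of a table under a predicted grid.

    Decomposes exactly into per-cell contributions; an observation in an
    absent cell raises with the offending (time, age) pairs listed.
    """
    w_sum, wx, wx2 = obs.cell_stats(grid_pred.grid)
    occupied = w_sum > 0
    absent = occupied & ~grid_pred.present
    if absent.any():
        ti, ai = np.nonzero(absent)
        pairs = [
            (int(t + grid_pred.grid.t_min), int(a + grid_pred.grid.a_min))
            for t, a in zip(ti, ai)
        ]
        raise ValueError(f"observations fall in absent grid cells: {pairs}")
    nll, _ = _nll_from_stats(w_sum, wx, wx2, grid_pred.mean, grid_pred.var, var_floor)
    return nll


def lr_test(nll_restricted: float, nll_full: float, df: int, *, tol: float = 1e-6) -> float:
    """Likelihood-ratio test p-value for a nested model pair.

    The deviance ``2 * (nll_restricted - nll_full)`` is referred to a
    chi-square distribution with ``df`` degrees of freedom.  A deviance
    below ``-tol`` indicates the models are not nested (or the optimizer
    failed) and raises.
    """
    if df < 1:
        raise ValueError("df must be at least 1")
    deviance = 2.0 * (nll_restricted - nll_full)
    if deviance < -tol * max(1.0, abs(nll_full)):
        raise ValueError(
            f"restricted model fits better than full (deviance {deviance:g}); "
            "model nesting violated"
        )
    return float(sps.chi2.sf(max(deviance, 0.0), df))
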