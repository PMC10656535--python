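"""Census calibration: nonlinear least-squares fit of (r, K) and fit diagnostics.

The fit minimizes sum over census years of (observed - N(t; r, K, N0))^2 with
the closed-form logistic N(t), N0 pinned to the first observation, using the
trust-region-reflective algorithm within bounds that keep the sigmoid
identifiable on short series (r in (1e-4, 1) per year, K between the largest
observed count and 20x that).  The starting point comes from the three-point
Verhulst estimate on the first/middle/last observations.

Goodness of fit is reported as the Pearson correlation between observed and
modeled series ("regression coefficient r" in demographic usage) and the
coefficient of determination R^2 = 1 - SS_res/SS_tot, plus per-year absolute
errors and the percent error at a target year.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .model_core import (
    CensusSeries,
    DegenerateTripleError,
    LogisticParams,
    Trajectory,
    logistic_exact,
)

#: bounds keeping (r, K) identifiable on short census series
R_BOUNDS = (1e-4, 1.0)
K_UPPER_FACTOR = 20.0


@dataclass
class FitResult:
    params: LogisticParams
    residuals: np.ndarray
    regression_r: float
    r_squared: float
    converged: bool
    n_iter: int
    message: str = ""
    seed_estimate: tuple | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "r": self.params.r,
                "K": self.params.K,
                "N0": self.params.N0,
                "regression_r": self.regression_r,
                "r_squared": self.r_squared,
                "converged": self.converged,
                "n_iter": self.n_iter,
                "message": self.message,
                "seed_estimate": self.seed_estimate,
                "n_residuals": int(np.asarray(self.residuals).size),
            },
            sort_keys=True,
        )


@dataclass
class ErrorReport:
    """Per-year absolute errors plus the percent error at the target year."""

    years: np.ndarray
    absolute_errors: np.ndarray
    target_year: float
    modeled_at_target: float
    observed_at_target: float
    percent_error_at_target: float
    percent_error_formatted: str


def fit_logistic(
    census: CensusSeries,
    seed_estimate: tuple | None = None,
    *,
    log_scale: bool = False,
) -> FitResult:
    """Fit (r, K) to a census series; N0 is fixed at the first observation.

    ``seed_estimate`` is an optional (K, r) starting point; by default the
    Verhulst three-point estimate on the first/middle/last observations is
    used, clipped into the bounds.  ``log_scale=True`` fits log-counts
    instead of raw counts (the default matches the raw-count objective).
    """
    counts = np.asarray(census.counts)
    times = census.times
    if len(census) < 3:
        raise ValueError("need at least 3 observations to fit (r, K)")
    N0 = counts[0]
    k_bounds = (counts.max() * (1 + 1e-9), counts.max() * K_UPPER_FACTOR)

    if seed_estimate is None:
        mid = len(counts) // 2
        try:
            T = times[mid] - times[0]
            # Verhulst needs equal spacing: use the closed form at 0, T, 2T
            # by interpolating the series where 2T overshoots the data.
            N2 = float(np.interp(times[0] + 2 * T, times, counts))
            from .model_core import verhulst_estimate

            seed_estimate = verhulst_estimate(counts[0], counts[mid], N2, T)
        except (DegenerateTripleError, ValueError):
            seed_estimate = (2.0 * counts.max(), 0.03)
    K0 = float(np.clip(seed_estimate[0], *k_bounds))
    r0 = float(np.clip(seed_estimate[1], *R_BOUNDS))

    obs = np.log(counts) if log_scale else counts

    def resid(theta):
        r, K = theta
        model = logistic_exact(LogisticParams(r=r, K=K, N0=N0), times)
        model = np.log(model) if log_scale else model
        return model - obs

    sol = optimize.least_squares(
        resid,
        x0=[r0, K0],
        bounds=([R_BOUNDS[0], k_bounds[0]], [R_BOUNDS[1], k_bounds[1]]),
        method="trf",
        x_scale=[0.01, counts.max()],
    )
    params = LogisticParams(r=float(sol.x[0]), K=float(sol.x[1]), N0=float(N0))
    modeled = logistic_exact(params, times)
    reg_r, r2 = regression_stats(counts, modeled)
    converged = bool(sol.success)
    message = sol.message
    if np.all(np.diff(counts) < 0):
        # strictly decreasing data cannot come from the growth regime with
        # N0 fixed at the first (largest) observation and K > max(counts)
        converged = False
        message = "observed series strictly decreasing: logistic growth regime mismatch"
    return FitResult(
        params=params,
        residuals=counts - modeled,
        regression_r=reg_r,
        r_squared=r2,
        converged=converged,
        n_iter=int(sol.nfev),
        message=message,
        seed_estimate=(K0, r0),
    )


def regression_stats(observed, modeled) -> tuple[float, float]:
    """(Pearson correlation, R^2 = 1 - SS_res/SS_tot) of modeled vs observed."""
    observed = np.asarray(observed, dtype=float)
    modeled = np.asarray(modeled, dtype=float)
    if observed.shape != modeled.shape or observed.size < 2:
        raise ValueError("observed and modeled must share a length >= 2")
    if np.var(observed) == 0:
        raise ValueError("observed series has zero variance")
    with warnings.catch_warnings():
        # a (near-)constant modeled series is a legitimate null model: the
        # correlation is undefined (nan) there, but R^2 is still meaningful
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        warnings.simplefilter("ignore", stats.NearConstantInputWarning)
        reg_r = float(stats.pearsonr(observed, modeled).statistic)
    ss_res = float(np.sum((observed - modeled) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    return reg_r, 1.0 - ss_res / ss_tot


def regression_r_ci(reg_r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation CI for a correlation via the Fisher z-transform."""
    if n < 4:
        raise ValueError("need n >= 4 for a Fisher-z interval")
    z = math.atanh(reg_r)
    se = 1.0 / math.sqrt(n - 3)
    q = stats.norm.ppf(0.5 + level / 2)
    return math.tanh(z - q * se), math.tanh(z + q * se)


def format_percent(p: float, decimals: int = 2) -> str:
    """Report-style percent: fixed 2 decimals, scientific below 1e-3."""
    if p != 0 and abs(p) < 1e-3:
        return f"{p:.1e}%"
    return f"{p:.{decimals}f}%"


def error_report(
    census: CensusSeries, traj: Trajectory, target_year: float
) -> ErrorReport:
    """Absolute errors on the census/trajectory overlap and percent error at a year."""
    traj_years = np.asarray(traj.times) + census.epoch_year
    years = np.asarray(census.years)
    mask = (years >= traj_years.min() - 1e-9) & (years <= traj_years.max() + 1e-9)
    if not mask.any():
        raise ValueError("census and trajectory share no overlapping years")
    overlap_years = years[mask]
    observed = np.asarray(census.counts)[mask]
    modeled = np.interp(overlap_years, traj_years, traj.values)
    abs_err = np.abs(observed - modeled)

    if not (years.min() <= target_year <= years.max()):
        raise ValueError(f"target year {target_year} outside the census span")
    obs_t = float(np.interp(target_year, years, np.asarray(census.counts)))
    if not (traj_years.min() - 1e-9 <= target_year <= traj_years.max() + 1e-9):
        raise ValueError(f"target year {target_year} outside the trajectory span")
    mod_t = float(np.interp(target_year, traj_years, traj.values))
    pct = abs(mod_t - obs_t) / obs_t * 100.0
    return ErrorReport(
        years=overlap_years,
        absolute_errors=abs_err,
        target_year=float(target_year),
        modeled_at_target=mod_t,
        observed_at_target=obs_t,
        percent_error_at_target=pct,
        percent_error_formatted=format_percent(pct),
    )
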