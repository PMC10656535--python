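"""Constant- and time-varying-parameter logistic growth machinery.

The Verhulst logistic model

    dN/dt = r N (1 - N/K),   N(0) = N0,

with intrinsic growth rate ``r`` (1/year), carrying capacity ``K``
(individuals) and initial population ``N0``, has the closed-form solution

    N(t) = K / (1 + (K/N0 - 1) exp(-r t)).

This module provides that closed form, the right-hand side, the classical
three-point Verhulst parameter estimator, the closed-form solution for
time-varying coefficients r(t), K(t), and two integer-order numerical
integrators: a 4th-order Adams–Bashforth–Moulton predictor–corrector (PECE)
and an adaptive embedded Runge–Kutta oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import cumulative_simpson, simpson, solve_ivp


class DegenerateTripleError(ValueError):
    """Raised when a Verhulst triple carries no carrying-capacity information."""


class QuadratureError(RuntimeError):
    """Raised when adaptive quadrature fails to reach the requested tolerance."""

    def __init__(self, message: str, achieved_tol: float):
        super().__init__(f"{message} (achieved relative tolerance {achieved_tol:.3e})")
        self.achieved_tol = achieved_tol


@dataclass(frozen=True)
class LogisticParams:
    """The triple (r, K, N0) determining a constant-parameter logistic trajectory.

    r : intrinsic growth rate, 1/year
    K : carrying capacity, individuals
    N0 : initial population at t = 0, individuals
    """

    r: float
    K: float
    N0: float

    def __post_init__(self):
        if not (self.r >= 0 and self.K > 0 and self.N0 > 0):
            raise ValueError(
                f"LogisticParams requires r >= 0, K > 0, N0 > 0; got {self}"
            )

    @property
    def growth_regime(self) -> str:
        """'growth' when N0 < K (standard sigmoid), else 'decay' (N0 >= K)."""
        return "growth" if self.N0 < self.K else "decay"


@dataclass(frozen=True)
class TimeGrid:
    """Uniform time grid t_start + k*h, k = 0..n_steps (years from the epoch)."""

    t_start: float
    h: float
    n_steps: int

    def __post_init__(self):
        if self.h <= 0:
            raise ValueError("step h must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    @property
    def times(self) -> np.ndarray:
        return self.t_start + self.h * np.arange(self.n_steps + 1)

    @property
    def t_end(self) -> float:
        return self.t_start + self.h * self.n_steps


@dataclass
class Trajectory:
    """A solver output: population values on strictly increasing times."""

    times: np.ndarray
    values: np.ndarray
    scheme_label: str

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("population values must be non-negative")

    def at(self, t: float | np.ndarray) -> np.ndarray:
        """Interpolate the trajectory at arbitrary times (linear)."""
        return np.interp(t, self.times, self.values)

    def final(self) -> float:
        return float(self.values[-1])


@dataclass(frozen=True)
class CensusSeries:
    """Observed (year, count) pairs; epoch_year maps to model time t = 0."""

    years: tuple
    counts: tuple
    epoch_year: int

    def __post_init__(self):
        years = np.asarray(self.years, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        if years.size != counts.size:
            raise ValueError("years and counts must have equal length")
        if years.size > 1 and not np.all(np.diff(years) > 0):
            raise ValueError("years must be strictly increasing")
        if np.any(counts <= 0):
            raise ValueError("counts must be positive")
        object.__setattr__(self, "years", tuple(float(y) for y in years))
        object.__setattr__(self, "counts", tuple(float(c) for c in counts))

    @property
    def times(self) -> np.ndarray:
        """Model times in years since the epoch year."""
        return np.asarray(self.years) - self.epoch_year

    def __len__(self) -> int:
        return len(self.years)


def year_to_t(year, epoch_year: int):
    """Calendar year -> model time (years since the epoch). 2022 -> 48 for epoch 1974.

    Centralized so calendar/model-time conversion cannot drift by a year
    between modules.
    """
    return np.asarray(year, dtype=float) - epoch_year


def t_to_year(t, epoch_year: int):
    return np.asarray(t, dtype=float) + epoch_year


def logistic_rhs(params: LogisticParams, N) -> np.ndarray | float:
    """Right-hand side r N (1 - N/K) in individuals/year."""
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("population N must be non-negative")
    out = params.r * N * (1.0 - N / params.K)
    return float(out) if out.ndim == 0 else out


def logistic_exact(params: LogisticParams, t) -> np.ndarray | float:
    """Closed-form logistic solution K / (1 + (K/N0 - 1) e^{-r t}).

    Negative t is permitted (backward extrapolation along the same solution
    curve).
    """
    t = np.asarray(t, dtype=float)
    A = params.K / params.N0 - 1.0
    out = params.K / (1.0 + A * np.exp(-params.r * t))
    return float(out) if out.ndim == 0 else out


def verhulst_estimate(
    N0: float, N1: float, N2: float, T: float, *, degenerate_rtol: float = 1e-12
) -> tuple[float, float]:
    """Three-point (K, r) estimate from populations at equally spaced times 0, T, 2T.

        K = (N0 N1^2 + N1^2 N2 - 2 N0 N1 N2) / (N1^2 - N0 N2)
        r = (1/T) log[ (1/N0 - 1/K) / (1/N1 - 1/K) ]

    Exact on noiseless logistic triples.  A geometric triple (N1^2 = N0 N2,
    pure exponential growth) carries no information about K and is rejected,
    as is an equilibrium triple or any K that makes the log argument
    non-positive.
    """
    if min(N0, N1, N2) <= 0:
        raise ValueError("populations must be positive")
    if T <= 0:
        raise ValueError("spacing T must be positive")
    denom = N1 * N1 - N0 * N2
    if abs(denom) <= degenerate_rtol * N1 * N1:
        raise DegenerateTripleError(
            "N1^2 = N0*N2: geometric (exponential) triple, K undefined"
        )
    if N0 == N1 == N2:
        raise DegenerateTripleError("constant triple: equilibrium, r indeterminate")
    K = (N0 * N1 * N1 + N1 * N1 * N2 - 2.0 * N0 * N1 * N2) / denom
    if K <= 0:
        raise DegenerateTripleError(f"estimated K = {K} is non-positive")
    a0 = 1.0 / N0 - 1.0 / K
    a1 = 1.0 / N1 - 1.0 / K
    if a0 * a1 <= 0:
        raise DegenerateTripleError(
            "non-positive log argument: K does not bracket the triple "
            f"(K = {K}, max observation = {max(N0, N1, N2)})"
        )
    r = np.log(a0 / a1) / T
    return K, float(r)


def _vector_eval(fn: Callable, s: np.ndarray) -> np.ndarray:
    """Evaluate a scalar-or-vector callable on an array."""
    try:
        out = np.asarray(fn(s), dtype=float)
        if out.shape == s.shape:
            return out
    except (TypeError, ValueError):
        pass
    return np.asarray([fn(x) for x in s], dtype=float)


def timevarying_exact(
    r_fn: Callable,
    K_fn: Callable,
    N0: float,
    t: float,
    *,
    rtol: float = 1e-10,
    n_start: int = 64,
    max_doublings: int = 14,
) -> float:
    """Closed-form solution of the logistic equation with time-varying r(t), K(t):

        N(t) = N0 e^{R(t)} / (1 + N0 \\int_0^t [r(q)/K(q)] e^{R(q)} dq),
        R(t) = \\int_0^t r(q) dq.

    Both integrals are evaluated on one shared refinement grid with
    cumulative Simpson quadrature (the inner exponential is a cached
    cumulative antiderivative, so there is no nested-quadrature blow-up); the
    grid is doubled until two successive evaluations agree to ``rtol``.  The
    exponentials are rescaled by e^{-R(t)} so large r*t cannot overflow.
    """
    if N0 <= 0:
        raise ValueError("N0 must be positive")
    if t == 0:
        return float(N0)
    prev = None
    n = n_start
    achieved = np.inf
    for _ in range(max_doublings + 1):
        s = np.linspace(0.0, t, n + 1)
        r = _vector_eval(r_fn, s)
        Kv = _vector_eval(K_fn, s)
        R = cumulative_simpson(r, x=s, initial=0.0)
        # integrand scaled by e^{-R(t)}:  N = N0 / (e^{-R(t)} + N0 * I_scaled)
        integrand = (r / Kv) * np.exp(R - R[-1])
        I = simpson(integrand, x=s)
        val = N0 / (np.exp(-R[-1]) + N0 * I)
        if prev is not None:
            achieved = abs(val - prev) / max(abs(val), 1e-300)
            if achieved <= rtol:
                return float(val)
        prev = val
        n *= 2
    raise QuadratureError(
        f"timevarying_exact did not converge to rtol={rtol:g} at t={t}", achieved
    )


def pece_solve(params: LogisticParams, grid: TimeGrid) -> Trajectory:
    """Adams–Bashforth(4) predictor / Adams–Moulton(4) corrector on the logistic ODE.

    The first three steps are bootstrapped with classical 4th-order
    Runge–Kutta so the multistep history is available at full order.
    Converges to the closed form with order 4 as h -> 0.
    """
    h = grid.h
    times = grid.times
    N = np.empty(grid.n_steps + 1)
    N[0] = params.N0

    def f(y):
        return params.r * y * (1.0 - y / params.K)

    # RK4 bootstrap for the first min(3, n_steps) steps
    for i in range(min(3, grid.n_steps)):
        y = N[i]
        k1 = f(y)
        k2 = f(y + 0.5 * h * k1)
        k3 = f(y + 0.5 * h * k2)
        k4 = f(y + h * k3)
        N[i + 1] = y + h * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0

    fs = [f(N[i]) for i in range(min(4, grid.n_steps + 1))]
    for i in range(3, grid.n_steps):
        # predict (AB4), evaluate, correct (AM4), evaluate
        yp = N[i] + h * (55 * fs[i] - 59 * fs[i - 1] + 37 * fs[i - 2] - 9 * fs[i - 3]) / 24.0
        fp = f(yp)
        yc = N[i] + h * (9 * fp + 19 * fs[i] - 5 * fs[i - 1] + fs[i - 2]) / 24.0
        N[i + 1] = yc
        fs.append(f(yc))
    return Trajectory(times, N, scheme_label="pece")


def rkf_solve(
    params: LogisticParams, t_end: float, tol: float = 1e-10
) -> Trajectory:
    """Adaptive embedded Runge–Kutta integration of the logistic ODE.

    The in-repo oracle for the integer-order solvers; uses an embedded
    4(5) pair with step-size control at relative tolerance ``tol``.
    """
    if not (0 < tol <= 1e-3):
        raise ValueError("tol must lie in (0, 1e-3]")
    sol = solve_ivp(
        lambda t, y: params.r * y * (1.0 - y / params.K),
        (0.0, t_end),
        [params.N0],
        method="RK45",
        rtol=tol,
        atol=tol * params.K,
        dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(f"adaptive Runge-Kutta failed: {sol.message}")
    return Trajectory(sol.t, sol.y[0], scheme_label="rkf")
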