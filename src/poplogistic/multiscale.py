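"""Two-term multiple-scales approximation of the slowly varying logistic model.

When the growth rate and carrying capacity drift slowly,

    K(eps t) = K0 + delta * sin(eps t),   r(eps t) = r0 + Delta * sin(eps t),

the logistic equation dN/dt = r(eps t) N (1 - N/K(eps t)) admits a two-term
multiple-scales expansion built on the fast time

    t0(t) = int_0^t r(eps s) ds = r0 t + (Delta/eps)(1 - cos(eps t)),

the accumulated growth, and the slow time eps*t.  The approximation is

    N(t) =  K(eps t) N0 K0 / D
          - eps N0^2 [K' K0^2 r0 - K(eps t)^2 K' r(eps t) e^{-t0}]
            / ( r(eps t) r0 D^2 )  + O(eps^2),

    D = N0 K0 + K(eps t) (K0 - N0) e^{-t0},

where K' denotes the *slow-time* derivative dK/dT evaluated at T = eps t,
i.e. K' = delta * cos(eps t) for the sinusoidal family.  This convention is
forced by the large-time behaviour: as t0 -> infinity the two terms give
N -> K(T) - eps K'(T)/r(T), exactly the known O(eps) tracking of the slowly
moving attractor, whereas reading K' as d/dt would shrink the correction to
O(eps^2 delta) and leave an O(eps delta) error uncorrected.  At
delta = Delta = 0 the expansion reduces exactly to the constant-parameter
closed form, and at t = 0 the correction numerator vanishes
(K(0) = K0, r(0) = r0), so N(0) = N0 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import LogisticParams, Trajectory


class ExpansionBreakdownError(ArithmeticError):
    """The expansion denominator vanished (approximation invalid there)."""


@dataclass(frozen=True)
class MultiscaleParams:
    """Slowly varying coefficient family K(eps t) = K0 + delta sin(eps t), r likewise.

    r0 : base growth rate, 1/year
    K0 : base carrying capacity, individuals
    delta : carrying-capacity oscillation amplitude; individuals when
        delta_units == "absolute", fraction of K0 when "fraction"
    Delta : growth-rate oscillation amplitude, 1/year
    epsilon : slow-time scale, 1/year; epsilon = 0 freezes the coefficients
    """

    r0: float
    K0: float
    delta: float = 0.0
    Delta: float = 0.0
    epsilon: float = 0.0
    delta_units: str = "absolute"

    def __post_init__(self):
        if self.r0 <= 0 or self.K0 <= 0 or self.epsilon < 0:
            raise ValueError("require r0 > 0, K0 > 0, epsilon >= 0")
        if self.delta_units not in ("absolute", "fraction"):
            raise ValueError("delta_units must be 'absolute' or 'fraction'")
        if abs(self.delta_abs) >= self.K0:
            raise ValueError("|delta| must keep K(t) positive (|delta| < K0)")
        if abs(self.Delta) >= self.r0:
            raise ValueError("|Delta| must keep r(t) positive (|Delta| < r0)")

    @property
    def delta_abs(self) -> float:
        """The oscillation amplitude in individuals, whichever units were given."""
        return self.delta * self.K0 if self.delta_units == "fraction" else self.delta


def periodic_coefficients(ms: MultiscaleParams, t) -> tuple:
    """(K(eps t), r(eps t)) at time t (vectorized)."""
    t = np.asarray(t, dtype=float)
    phase = np.sin(ms.epsilon * t)
    K_t = ms.K0 + ms.delta_abs * phase
    r_t = ms.r0 + ms.Delta * phase
    if t.ndim == 0:
        return float(K_t), float(r_t)
    return K_t, r_t


def fast_time(ms: MultiscaleParams, t):
    """Accumulated growth t0(t) = int_0^t r(eps s) ds, in closed form.

    For the sinusoidal family: t0 = r0 t + (Delta/eps)(1 - cos(eps t)); the
    eps -> 0 limit is r0 t (the oscillatory part integrates to
    Delta*eps*t^2/2 -> 0 with the coefficients frozen at r0).
    """
    t = np.asarray(t, dtype=float)
    if ms.epsilon == 0.0:
        out = ms.r0 * t
    else:
        out = ms.r0 * t + (ms.Delta / ms.epsilon) * (1.0 - np.cos(ms.epsilon * t))
    return float(out) if out.ndim == 0 else out


def multiscale_approx(ms: MultiscaleParams, N0: float, t, *, denom_rtol: float = 1e-12):
    """Two-term multiple-scales population at time t (vectorized).

    Raises :class:`ExpansionBreakdownError` if the expansion denominator
    comes within ``denom_rtol * N0 * K0`` of zero.
    """
    if N0 <= 0:
        raise ValueError("N0 must be positive")
    t = np.asarray(t, dtype=float)
    K0, r0, eps = ms.K0, ms.r0, ms.epsilon
    K_t, r_t = periodic_coefficients(ms, t)
    K_t = np.asarray(K_t, dtype=float)
    r_t = np.asarray(r_t, dtype=float)
    t0 = np.asarray(fast_time(ms, t), dtype=float)
    E = np.exp(-t0)
    D = N0 * K0 + K_t * (K0 - N0) * E
    if np.any(np.abs(D) <= denom_rtol * N0 * K0):
        raise ExpansionBreakdownError(
            "multiple-scales denominator vanished; expansion invalid at this t"
        )
    leading = K_t * N0 * K0 / D
    Kprime = ms.delta_abs * np.cos(eps * t)  # dK/dT, slow-time derivative
    correction = (
        eps
        * N0**2
        * (Kprime * K0**2 * r0 - K_t**2 * Kprime * r_t * E)
        / (r_t * r0 * D**2)
    )
    out = leading - correction
    return float(out) if out.ndim == 0 else out


def multiscale_forecast(
    ms: MultiscaleParams, N0: float, times, *, scheme_label: str | None = None
) -> Trajectory:
    """Evaluate the two-term approximation on the requested model times.

    Deterministic (closed form, no randomness); supports sweeps over r0 by
    calling once per parameter set.
    """
    times = np.sort(np.asarray(times, dtype=float))
    values = np.asarray(multiscale_approx(ms, N0, times), dtype=float)
    label = scheme_label or (
        f"multiscale(eps={ms.epsilon},delta={ms.delta_abs},Delta={ms.Delta})"
    )
    return Trajectory(times, values, scheme_label=label)


def equivalent_logistic(ms: MultiscaleParams, N0: float) -> LogisticParams:
    """The constant-parameter model (r0, K0, N0) underlying the expansion."""
    return LogisticParams(r=ms.r0, K=ms.K0, N0=N0)


__all__ = [
    "MultiscaleParams",
    "ExpansionBreakdownError",
    "periodic_coefficients",
    "fast_time",
    "multiscale_approx",
    "multiscale_forecast",
    "equivalent_logistic",
]
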