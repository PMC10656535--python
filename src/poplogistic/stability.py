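"""Existence-uniqueness and Hyers-Ulam stability constants of the ABC model.

For the fractional logistic right-hand side f(N) = r N (1 - N/K) restricted
to |N| <= N0, a Lipschitz constant is

    Psi = r + 2 r N0 / K.

Uniqueness of the ABC solution on [0, b] holds when

    Omega = (1-alpha)/ABC(alpha) * Psi
          + alpha b^alpha / (Gamma(alpha) ABC(alpha)) * Psi  < 1,

and the worked Hyers-Ulam check uses

    eta = (Gamma(alpha) + b^alpha) / (Gamma(alpha) ABC(alpha)) * Psi  < 1.

Both criteria are homogeneous of degree 1 in Psi and increase monotonically
with the horizon b.  The horizon is always an explicit input; no default is
inferred from the analysis span.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from math import gamma

from .abc_fractional import FracConfig
from .model_core import LogisticParams


@dataclass(frozen=True)
class StabilityReport:
    """Computable constants with pass/fail flags.

    psi : Lipschitz constant, 1/year
    omega : uniqueness criterion value (dimensionless); uniqueness_ok = (omega < 1)
    eta : Hyers-Ulam criterion value (dimensionless); hyers_ulam_ok = (eta < 1)
    """

    psi: float
    omega: float
    eta: float
    uniqueness_ok: bool
    hyers_ulam_ok: bool
    alpha: float
    b: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "psi": self.psi,
                "omega": self.omega,
                "eta": self.eta,
                "uniqueness_ok": self.uniqueness_ok,
                "hyers_ulam_ok": self.hyers_ulam_ok,
                "alpha": self.alpha,
                "b": self.b,
            },
            sort_keys=True,
        )


def lipschitz_psi(params: LogisticParams) -> float:
    """Lipschitz constant Psi = r + 2 r N0 / K of the logistic nonlinearity."""
    return params.r + 2.0 * params.r * params.N0 / params.K


def uniqueness_criterion(psi: float, cfg: FracConfig) -> tuple[float, bool]:
    """(Omega, Omega < 1): contraction criterion for a unique solution on [0, b]."""
    if psi <= 0:
        raise ValueError("psi must be positive")
    a, b, B = cfg.alpha, cfg.b, cfg.normalization
    omega = (1.0 - a) / B * psi + a * b**a / (gamma(a) * B) * psi
    return omega, omega < 1.0


def hyers_ulam_criterion(
    psi: float, cfg: FracConfig, *, formula: str = "worked"
) -> tuple[float, bool]:
    """(eta, eta < 1): Hyers-Ulam stability criterion on [0, b].

    ``formula="worked"`` (default) uses
    eta = (Gamma(alpha) + b^alpha)/(Gamma(alpha) ABC(alpha)) * Psi — the form
    behind the model's verifiable worked numbers.  ``formula="theorem"``
    evaluates the alternative statement
    (1-alpha)/ABC(alpha)*Psi + alpha b^alpha/(Gamma(alpha) ABC(alpha))*Psi,
    which coincides with the uniqueness criterion.
    """
    if psi <= 0:
        raise ValueError("psi must be positive")
    a, b, B = cfg.alpha, cfg.b, cfg.normalization
    if formula == "worked":
        eta = (gamma(a) + b**a) / (gamma(a) * B) * psi
    elif formula == "theorem":
        eta = (1.0 - a) / B * psi + a * b**a / (gamma(a) * B) * psi
    else:
        raise ValueError("formula must be 'worked' or 'theorem'")
    return eta, eta < 1.0


def stability_report(params: LogisticParams, cfg: FracConfig) -> StabilityReport:
    """Bundle Psi, Omega and eta for a model/configuration pair."""
    psi = lipschitz_psi(params)
    omega, uniq = uniqueness_criterion(psi, cfg)
    eta, hu = hyers_ulam_criterion(psi, cfg)
    return StabilityReport(
        psi=psi,
        omega=omega,
        eta=eta,
        uniqueness_ok=uniq,
        hyers_ulam_ok=hu,
        alpha=cfg.alpha,
        b=cfg.b,
    )
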