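"""Census-like synthetic series and the study's printed constants as fixtures.

Real decennial censuses report counts at irregular multi-year intervals and
are annualized by interpolation before model fitting.  ``generate_census``
emulates exactly that pathway: a forward model (constant-parameter logistic
or slowly varying multiple-scales family) is evaluated at the census years,
optionally interpolated to annual points with the same interpolant the
calibration pathway uses, and perturbed with multiplicative lognormal noise
(census counts are positive and errors roughly proportional to size; the
multiplier is exp(X), X ~ Normal(-sigma^2/2, sigma^2), so its mean is 1).

``paper_fixture`` exposes the source study's printed constants (fitted
parameters, table cells, stability constants) verbatim from a versioned JSON
file — these are fixtures for tests and reports, never computed quantities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.interpolate import PchipInterpolator

from .model_core import CensusSeries, LogisticParams, logistic_exact
from .multiscale import MultiscaleParams, multiscale_approx


@dataclass(frozen=True)
class NoiseModel:
    """Observation-noise specification for synthetic census counts.

    kind : "none" or "multiplicative_lognormal"
    sigma : relative noise scale (ignored when kind == "none")
    seed : integer seed; all randomness flows through one seeded generator
    """

    kind: str = "none"
    sigma: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("none", "multiplicative_lognormal"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def _forward_model(params, N0: float | None):
    if isinstance(params, LogisticParams):
        return lambda t: np.asarray(logistic_exact(params, t), dtype=float)
    if isinstance(params, MultiscaleParams):
        if N0 is None:
            raise ValueError("N0 is required with MultiscaleParams")
        return lambda t: np.asarray(multiscale_approx(params, N0, t), dtype=float)
    raise TypeError(f"unsupported model parameters {type(params).__name__}")


def generate_census(
    params: LogisticParams | MultiscaleParams,
    epoch_year: int,
    census_years,
    *,
    annualize: bool = False,
    noise: NoiseModel = NoiseModel(),
    interpolation: str = "pchip",
    N0: float | None = None,
) -> CensusSeries:
    """Generate a census series from a forward model.

    ``census_years`` are calendar years, strictly increasing, starting at
    ``epoch_year``.  With ``annualize`` the intermediate years are filled by
    monotone piecewise-cubic (default) or linear interpolation of the census
    points — mirroring the calibration pathway so synthetic and real data
    flow through identical plumbing.  Noise is applied after interpolation.
    Deterministic given (inputs, seed).
    """
    years = np.asarray(census_years, dtype=float)
    if years.size < 2 or not np.all(np.diff(years) > 0):
        raise ValueError("census_years must be >= 2 strictly increasing years")
    if years[0] != epoch_year:
        raise ValueError("first census year must equal epoch_year")
    if interpolation not in ("pchip", "linear"):
        raise ValueError("interpolation must be 'pchip' or 'linear'")

    model = _forward_model(params, N0)
    counts = model(years - epoch_year)

    if annualize:
        all_years = np.arange(years[0], years[-1] + 1.0)
        if interpolation == "pchip":
            counts = PchipInterpolator(years, counts)(all_years)
        else:
            counts = np.interp(all_years, years, counts)
        years = all_years

    if noise.kind == "multiplicative_lognormal" and noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        factors = np.exp(
            rng.normal(-0.5 * noise.sigma**2, noise.sigma, size=years.size)
        )
        counts = counts * factors

    return CensusSeries(
        years=tuple(years), counts=tuple(counts), epoch_year=epoch_year
    )


def _load_fixtures() -> dict:
    with resources.files("poplogistic").joinpath("_fixtures.json").open() as fh:
        return json.load(fh)


_FIXTURES: dict | None = None


def paper_fixture(name: str):
    """Look up a printed constant by dotted path, e.g. ``"census_2022.adjusted"``.

    ``"adjusted_params"`` returns a :class:`LogisticParams`; everything else
    is returned verbatim (dict or scalar).  Unknown names raise ``KeyError``.
    """
    global _FIXTURES
    if _FIXTURES is None:
        _FIXTURES = _load_fixtures()
    node = _FIXTURES
    remaining = name
    while remaining:
        if isinstance(node, dict) and remaining in node:
            # whole remainder is a key (keys may themselves contain dots,
            # e.g. "fps_table.r0=0.01")
            node = node[remaining]
            remaining = ""
        elif isinstance(node, dict) and "." in remaining:
            head, remaining = remaining.split(".", 1)
            if head not in node:
                raise KeyError(f"unknown fixture {name!r}")
            node = node[head]
        else:
            raise KeyError(f"unknown fixture {name!r}")
    if name == "adjusted_params":
        return LogisticParams(r=node["r"], K=node["K"], N0=node["N0"])
    return node
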