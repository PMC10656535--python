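"""End-to-end analysis pipeline: calibrate, compare schemes, check stability, forecast.

A single :class:`AnalysisConfig` (JSON-serializable) drives everything:

- ``run_analysis`` fits (or accepts fixed) logistic parameters, evaluates the
  four schemes — closed-form logistic, predictor-corrector, ABC fractional,
  multiple-scales — at a target year, computes percent errors against the
  census value, regression diagnostics over the full overlap, and the
  stability constants.
- ``run_forecast`` propagates each scheme to a horizon year, sweeping the
  fractional order alpha and the multiscale base growth rate r0, and tabulates
  final population sizes in millions.

Reports are deterministic given (config, seed): identical inputs produce
byte-identical JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abc_fractional import FracConfig, abc_solve
from .calibration import (
    error_report,
    fit_logistic,
    format_percent,
    regression_stats,
)
from .model_core import (
    CensusSeries,
    LogisticParams,
    TimeGrid,
    Trajectory,
    logistic_exact,
    pece_solve,
    t_to_year,
    year_to_t,
)
from .multiscale import MultiscaleParams, multiscale_forecast
from .stability import stability_report
from .synthetic_data import NoiseModel, generate_census

SCHEMES = ("logistic_exact", "pece", "abc", "multiscale")


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings behind one analysis/forecast run.

    Exactly one of ``census_path`` / ``synthetic`` supplies the data.  When
    ``fixed_params`` is given no fitting is performed.  ``comparison_alpha``
    is the fractional order used for the scheme-comparison table (the
    forecast sweeps the full ``alphas`` grid); ``multiscale`` overrides the
    slowly varying coefficient amplitudes (defaults: delta = Delta = 0, i.e.
    the constant-coefficient limit).
    """

    epoch_year: int
    target_year: int
    horizon_year: int = 2080
    census_path: str | None = None
    synthetic: dict | None = None
    fixed_params: dict | None = None
    alphas: tuple = (1.0, 0.95, 0.9, 0.85, 0.8)
    comparison_alpha: float = 0.95
    r0_sweep: tuple = (0.0374286, 0.03, 0.02, 0.01)
    frac_h: float = 0.01
    forecast_frac_h: float = 0.05
    stability_alpha: float = 0.5
    stability_b: float = 10.0
    normalization: float = 1.0
    multiscale: dict | None = None
    interpolation: str = "pchip"
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self):
        if self.horizon_year <= self.target_year:
            raise ValueError("horizon_year must exceed target_year")
        if self.interpolation not in ("pchip", "linear"):
            raise ValueError("interpolation must be 'pchip' or 'linear'")

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = json.load(fh)
        for key in ("alphas", "r0_sweep"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["alphas"] = list(self.alphas)
        d["r0_sweep"] = list(self.r0_sweep)
        return d

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ComparisonReport:
    """Per-scheme predictions and errors at the target year, plus diagnostics."""

    target_year: int
    census_value: float
    predictions: dict
    percent_errors: dict
    percent_errors_formatted: dict
    regression: dict
    fit: dict | None
    stability: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "target_year": self.target_year,
            "census_value": self.census_value,
            "predictions": self.predictions,
            "percent_errors": self.percent_errors,
            "percent_errors_formatted": self.percent_errors_formatted,
            "regression": self.regression,
            "fit": self.fit,
            "stability": self.stability,
            "provenance": self.provenance,
        }


def read_census_csv(path) -> CensusSeries:
    """Read a two-column ``year,population`` CSV (header required, UTF-8).

    Populations are parsed permissively: thousands separators (commas,
    underscores, spaces) are stripped.  Malformed rows are reported with
    their line number.
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    cols = [c.strip().lower() for c in df.columns]
    if cols[:2] != ["year", "population"]:
        raise ValueError(
            f"{path}: expected header 'year,population', found {list(df.columns)}"
        )
    years, counts = [], []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        y_raw, p_raw = str(row[0]).strip(), str(row[1]).strip()
        try:
            years.append(float(y_raw))
        except ValueError:
            raise ValueError(f"{path}: line {i}: non-numeric year {y_raw!r}") from None
        cleaned = p_raw.replace(",", "").replace("_", "").replace(" ", "")
        try:
            counts.append(float(cleaned))
        except ValueError:
            raise ValueError(
                f"{path}: line {i}: non-numeric population {p_raw!r}"
            ) from None
    epoch = int(years[0])
    return CensusSeries(years=tuple(years), counts=tuple(counts), epoch_year=epoch)


def write_census_csv(census: CensusSeries, path) -> None:
    pd.DataFrame({"year": census.years, "population": census.counts}).to_csv(
        path, index=False
    )


def trajectory_frame(traj: Trajectory, epoch_year: int) -> pd.DataFrame:
    """Standard trajectory table: t, year, population, scheme."""
    return pd.DataFrame(
        {
            "t": traj.times,
            "year": t_to_year(traj.times, epoch_year),
            "population": traj.values,
            "scheme": traj.scheme_label,
        }
    )


def _load_census(config: AnalysisConfig) -> CensusSeries:
    if (config.census_path is None) == (config.synthetic is None):
        raise ValueError("exactly one of census_path / synthetic must be given")
    if config.census_path is not None:
        return read_census_csv(config.census_path)
    spec = dict(config.synthetic)
    kind = spec.pop("kind", "logistic")
    noise = NoiseModel(**spec.pop("noise", {"kind": "none"}))
    census_years = spec.pop("census_years")
    annualize = spec.pop("annualize", True)
    N0 = spec.pop("N0", None)
    if kind == "logistic":
        params = LogisticParams(**spec.pop("params"))
    elif kind == "multiscale":
        params = MultiscaleParams(**spec.pop("params"))
    else:
        raise ValueError(f"unknown synthetic kind {kind!r}")
    if spec:
        raise ValueError(f"unknown synthetic keys {sorted(spec)}")
    return generate_census(
        params,
        config.epoch_year,
        census_years,
        annualize=annualize,
        noise=noise,
        interpolation=config.interpolation,
        N0=N0,
    )


def _resolve_params(config: AnalysisConfig, census: CensusSeries):
    """(LogisticParams, fit-summary dict or None)."""
    if config.fixed_params is not None:
        return LogisticParams(**config.fixed_params), None
    fit = fit_logistic(census)
    return fit.params, json.loads(fit.to_json())


def _multiscale_params(config: AnalysisConfig, params: LogisticParams) -> MultiscaleParams:
    base = {"r0": params.r, "K0": params.K, "delta": 0.0, "Delta": 0.0, "epsilon": 0.0}
    if config.multiscale:
        base.update(config.multiscale)
    return MultiscaleParams(**base)


def run_analysis(config: AnalysisConfig) -> ComparisonReport:
    """Calibrate, evaluate the four schemes at the target year, attach diagnostics."""
    census = _load_census(config)
    years = np.asarray(census.years)
    if not (years.min() <= config.target_year <= years.max()):
        raise ValueError(
            f"target_year {config.target_year} outside the census span "
            f"[{years.min():.0f}, {years.max():.0f}]"
        )
    params, fit_summary = _resolve_params(config, census)
    t_target = float(year_to_t(config.target_year, census.epoch_year))
    census_value = float(np.interp(config.target_year, years, np.asarray(census.counts)))

    h = config.frac_h
    n_steps = max(1, int(round(t_target / h)))
    grid = TimeGrid(t_start=0.0, h=t_target / n_steps, n_steps=n_steps)

    frac_cfg = FracConfig(
        alpha=config.comparison_alpha,
        b=config.stability_b,
        normalization=config.normalization,
        h=grid.h,
    )
    ms = _multiscale_params(config, params)

    predictions = {
        "logistic_exact": float(logistic_exact(params, t_target)),
        "pece": pece_solve(params, grid).final(),
        "abc": abc_solve(params, frac_cfg, grid).final(),
        "multiscale": multiscale_forecast(ms, params.N0, [t_target]).final(),
    }
    percent_errors = {
        s: abs(v - census_value) / census_value * 100.0 for s, v in predictions.items()
    }

    modeled_at_census = np.asarray(logistic_exact(params, census.times))
    reg_r, r2 = regression_stats(np.asarray(census.counts), modeled_at_census)
    # absolute-error curve of the closed form against the census overlap
    traj = Trajectory(census.times, modeled_at_census, scheme_label="logistic_exact")
    errs = error_report(census, traj, config.target_year)

    stab = stability_report(
        params,
        FracConfig(
            alpha=config.stability_alpha,
            b=config.stability_b,
            normalization=config.normalization,
        ),
    )
    report = ComparisonReport(
        target_year=config.target_year,
        census_value=census_value,
        predictions={k: round(v, 4) for k, v in predictions.items()},
        percent_errors=percent_errors,
        percent_errors_formatted={
            s: format_percent(p) for s, p in percent_errors.items()
        },
        regression={
            "regression_r": reg_r,
            "r_squared": r2,
            "max_absolute_error": float(errs.absolute_errors.max()),
        },
        fit=fit_summary,
        stability=json.loads(stab.to_json()),
        provenance=_provenance(config),
    )
    return report


def run_forecast(config: AnalysisConfig) -> dict:
    """Trajectories to the horizon for each scheme, alpha, and r0; FPS table.

    Returns a bundle with annual logistic/multiscale trajectories, ABC
    trajectories per fractional order, and the final-population-size table
    (millions, 3 decimals) of the multiscale r0 sweep.
    """
    census = _load_census(config)
    params, fit_summary = _resolve_params(config, census)
    epoch = census.epoch_year
    t_end = float(year_to_t(config.horizon_year, epoch))
    annual_t = np.arange(0.0, t_end + 0.5)

    logistic_traj = Trajectory(
        annual_t, np.asarray(logistic_exact(params, annual_t)), "logistic_exact"
    )

    frac_cfg = FracConfig(
        alpha=1.0,
        b=config.stability_b,
        normalization=config.normalization,
        h=config.forecast_frac_h,
    )
    n_steps = max(1, int(round(t_end / frac_cfg.h)))
    grid = TimeGrid(t_start=0.0, h=t_end / n_steps, n_steps=n_steps)
    abc_trajs = {}
    for a in config.alphas:
        cfg_a = FracConfig(
            alpha=a, b=frac_cfg.b, normalization=frac_cfg.normalization, h=grid.h
        )
        abc_trajs[a] = abc_solve(params, cfg_a, grid)

    ms_base = _multiscale_params(config, params)
    ms_trajs = {}
    fps_rows = []
    for r0 in config.r0_sweep:
        ms = dataclasses.replace(ms_base, r0=r0)
        traj = multiscale_forecast(ms, params.N0, annual_t)
        ms_trajs[r0] = traj
        fps_rows.append(
            {"r0": r0, "fps_millions": round(traj.final() / 1e6, 3)}
        )

    return {
        "epoch_year": epoch,
        "horizon_year": config.horizon_year,
        "params": {"r": params.r, "K": params.K, "N0": params.N0},
        "fit": fit_summary,
        "logistic": logistic_traj,
        "abc": abc_trajs,
        "multiscale": ms_trajs,
        "fps_table": fps_rows,
        "provenance": _provenance(config),
    }


def _provenance(config: AnalysisConfig) -> dict:
    return {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "version": __version__,
        "interpolation": config.interpolation,
        "comparison_alpha": config.comparison_alpha,
        "frac_h": config.frac_h,
    }


def write_report(report: ComparisonReport | dict, out_dir) -> list[Path]:
    """Serialize a report (analysis or forecast bundle) under ``out_dir``.

    Writes a deterministic JSON report, CSV tables/trajectories and a short
    human-readable summary; returns the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    if isinstance(report, ComparisonReport):
        payload = report.to_dict()
        p = out / "analysis_report.json"
        p.write_text(json.dumps(payload, indent=2, sort_keys=True))
        written.append(p)
        table = pd.DataFrame(
            {
                "scheme": list(report.predictions),
                "population_size": [report.predictions[s] for s in report.predictions],
                "percent_error": [
                    report.percent_errors_formatted[s] for s in report.predictions
                ],
            }
        )
        p = out / "scheme_comparison.csv"
        table.to_csv(p, index=False)
        written.append(p)
        summary = [
            f"Scheme comparison at {report.target_year} "
            f"(census value {report.census_value:,.4f})",
            table.to_string(index=False),
            f"regression_r = {report.regression['regression_r']:.6f}, "
            f"R^2 = {report.regression['r_squared']:.6f}",
            f"stability: psi = {report.stability['psi']:.11g}, "
            f"omega = {report.stability['omega']:.11g} "
            f"(unique: {report.stability['uniqueness_ok']}), "
            f"eta = {report.stability['eta']:.11g} "
            f"(Hyers-Ulam: {report.stability['hyers_ulam_ok']})",
            f"provenance: {json.dumps(report.provenance, sort_keys=True)}",
        ]
        p = out / "summary.txt"
        p.write_text("\n".join(summary) + "\n")
        written.append(p)
    else:
        epoch = report["epoch_year"]
        frames = [trajectory_frame(report["logistic"], epoch)]
        frames += [trajectory_frame(t, epoch) for t in report["abc"].values()]
        frames += [trajectory_frame(t, epoch) for t in report["multiscale"].values()]
        p = out / "forecast_trajectories.csv"
        pd.concat(frames, ignore_index=True).to_csv(p, index=False)
        written.append(p)
        p = out / "fps_table.csv"
        pd.DataFrame(report["fps_table"]).to_csv(p, index=False)
        written.append(p)
        payload = {
            "epoch_year": epoch,
            "horizon_year": report["horizon_year"],
            "params": report["params"],
            "fit": report["fit"],
            "fps_table": report["fps_table"],
            "final_populations": {
                "logistic": report["logistic"].final(),
                "abc": {str(a): t.final() for a, t in report["abc"].items()},
                "multiscale": {str(r): t.final() for r, t in report["multiscale"].items()},
            },
            "provenance": report["provenance"],
        }
        p = out / "forecast_report.json"
        p.write_text(json.dumps(payload, indent=2, sort_keys=True))
        written.append(p)
    return written
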