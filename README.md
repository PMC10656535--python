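# poplogistic

Logistic population-growth analysis and forecasting for census time series,
built around four propagation schemes for the Verhulst model

```
dN/dt = r N (1 − N/K),    N(0) = N0,
```

where `r` is the intrinsic growth rate (1/year), `K` the carrying capacity
and `N0` the initial population:

1. **Closed form** — `N(t) = K / (1 + (K/N0 − 1) e^{−rt})`.
2. **Predictor–corrector (PECE)** — 4th-order Adams–Bashforth/Adams–Moulton
   integration, with an adaptive embedded Runge–Kutta solver as oracle.
3. **ABC fractional order** — the logistic equation under the
   Atangana–Baleanu–Caputo derivative (non-singular Mittag–Leffler kernel),
   stepped with a two-step Lagrange Adams-type scheme whose weights are
   closed forms of the kernel integrals.  Order `α ∈ (0, 1]` controls the
   memory effect; `α = 1` recovers the classical model.
4. **Multiple scales** — a two-term perturbation approximation for slowly
   varying coefficients `K(εt) = K0 + δ sin εt`, `r(εt) = r0 + Δ sin εt`,
   built on the accumulated-growth fast time `t0 = ∫0^t r(εs) ds`.

Around the solvers the package provides Verhulst three-point parameter
estimation, trust-region-reflective least-squares calibration of `(r, K)` to
census counts, regression/error diagnostics, the model's computable
uniqueness (`Ω < 1`) and Hyers–Ulam stability (`η < 1`) constants, a
synthetic-census generator with multiplicative lognormal observation noise,
and a pipeline/CLI that produces deterministic scheme-comparison and
forecast reports.

Intended users: demographers and applied mathematicians comparing classical,
fractional-order and perturbation forecasts on national census series.

## Worked example

Fitted adjusted-census parameters for Bangladesh (epoch 1974, so calendar
2022 is model time t = 48):

```python
>>> import poplogistic as pl
>>> p = pl.LogisticParams(r=0.0374286, K=225062093.9465337, N0=76398000)
>>> pl.logistic_exact(p, 48.0)
170145565.0601202
```

Against the adjusted 2022 census count of 170,000,000 that closed-form value
is 0.09% off:

```python
>>> abs(170145565.0601202 - 170e6) / 170e6 * 100
0.08562650595305597
```

The stability constants for the fractional model on the horizon b = 10 years
at order α = ½ (normalization ABC(α) = 1):

```bash
$ poplogistic stability --r 0.0374286 --k 225062093.9465337 --n0 76398000
{"alpha": 0.5, "b": 10.0, "eta": 0.17495185408593525, "hyers_ulam_ok": true,
 "omega": 0.08747592704296764, "psi": 0.06283910012161802, "uniqueness_ok": true}
```

`psi` is the Lipschitz constant `Ψ = r + 2rN0/K` of the logistic
nonlinearity; `omega < 1` certifies a unique solution on `[0, b]` and
`eta < 1` certifies Hyers–Ulam stability (every approximate solution stays
within a bounded multiple of its defect from the exact one).

A full scheme comparison from a census CSV (`year,population`):

```bash
$ poplogistic analyze --config config.json --out report/
$ cat report/scheme_comparison.csv
scheme,population_size,percent_error
logistic_exact,170145565.0601,0.09%
pece,170145565.0601,0.09%
abc,153812145.9889,9.52%
multiscale,170145565.0601,0.09%
```

(the `abc` row uses the default comparison order α = 0.95 — the lower the
order, the stronger the memory-induced delay; `multiscale` with the default
δ = Δ = 0 coincides with the closed form).  `poplogistic forecast` sweeps the
fractional order over {1.0, …, 0.8} and the multiscale base growth rate over
an `r0` grid to the horizon year and tabulates final population sizes in
millions.

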