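# Methods

## Model and time convention

All schemes propagate the Verhulst logistic model `dN/dt = rN(1 − N/K)` for
a single closed population: no age structure, migration or fertility
components, and density dependence enters only through the quadratic term.
Model time is `t = calendar year − epoch_year`, centralized in one
conversion function (`year_to_t`); the epoch is the first census year, so
for a 1974 epoch calendar 2022 is `t = 48`.  `N0` is always the first
observation of the series being analyzed, never a fitted quantity.

## Closed forms

`logistic_exact` evaluates `K/(1 + (K/N0 − 1)e^{−rt})`; negative `t` is
permitted and documented as backward extrapolation.  For time-varying
coefficients `timevarying_exact` evaluates

```
N(t) = N0 e^{R(t)} / (1 + N0 ∫0^t [r(q)/K(q)] e^{R(q)} dq),   R(t) = ∫0^t r(q) dq,
```

with both integrals on one shared refinement grid via cumulative Simpson
quadrature: the inner exponential is a cached cumulative antiderivative, so
there is no nested-quadrature blow-up, and all exponentials are rescaled by
`e^{−R(t)}` so large `rt` cannot overflow.  The grid doubles (from 64
intervals, at most 14 doublings) until two successive evaluations agree to a
relative 1e-10; non-convergence raises an error carrying the achieved
tolerance.

`verhulst_estimate` inverts a noiseless logistic triple at times 0, T, 2T.
A geometric triple (`N1² = N0·N2`, detected at relative tolerance 1e-12) is
pure exponential growth and carries no information about `K`; constant
triples (equilibrium) and any `K` producing a non-positive log argument are
likewise rejected rather than silently extrapolated.

## Integer-order solvers

The PECE solver is the classical 4th-order Adams–Bashforth predictor with an
Adams–Moulton corrector in PECE mode, bootstrapped by three classical
Runge–Kutta steps; its default step is h = 0.01 year.  Measured convergence
on the calibrated problem is order 4, and at h = 0.01 it agrees with the
closed form to ~1e-12 relative.  The adaptive oracle (`rkf_solve`) is an
embedded 4(5) Runge–Kutta pair (scipy's `RK45`) with relative tolerance
capped at 1e-3 from above; it exists to cross-check the fixed-step solvers,
not as a general-purpose integrator.

## ABC fractional-order scheme

The fractional model replaces `d/dt` by the Atangana–Baleanu–Caputo
derivative of order `α ∈ (0, 1]`, whose kernel is the Mittag–Leffler
function `E_α`.  Applying the ABC integral converts the model to a Volterra
equation; interpolating the right-hand side linearly on each past interval
(two-step Lagrange) gives an Adams-type recursion with closed-form weights

```
w1(m) = (m+1)^α (m+2+α) − m^α (m+2+2α),
w2(m) = (m+1)^(α+1)     − m^α (m+1+α),        m = n − k,
```

equal (up to the common factor `h^{α+1}/(α(α+1))`) to the defining kernel
integrals — verified against adaptive quadrature to 1e-9 relative.

Numerical choices:

- **k = 0 history term.**  The first step of the recursion references the
  off-grid value `N_{−1}`.  The default convention is constant extension
  (`N_{−1} := N0`), isolated in one place with a "drop the term" alternative
  toggleable; the α = 1 closed-form convergence test pins the default.
- **Normalization.**  `ABC(α) ≡ 1` for all α, consistent with the endpoint
  constraint ABC(0) = ABC(1) = 1; exposed in `FracConfig` for other
  conventions.
- **History sum.**  Full history each step, O(n²) total but vectorized over
  the lag; at the desk scales used here (n ≤ ~1e4) this runs in seconds.  A
  short-memory truncation length is available but off by default.
- **Stability guard.**  The explicit recursion destabilizes for large `h` at
  strong growth; any iterate escaping `[0, 2K]` aborts with a diagnostic
  naming the step, order and h.
- **Mittag–Leffler evaluation.**  Direct series to absolute tolerance 1e-14;
  beyond |z| = 10 the summation runs in mpmath with working precision scaled
  to the term peak `e^{|z|^{1/α}}`, and the Gamma argument is built in
  arbitrary precision (float rounding of `αj` would otherwise contaminate
  the cancellation for large negative arguments).

Measured behavior on the calibrated problem: at α = 1 the scheme converges
to the closed form at order ~2; for α ∈ [0.8, 1] and h ≤ 0.05 trajectories
stay inside `(0, K(1+1e-6))`; at fixed forecast time the population is
monotone increasing in α (smaller order = heavier memory = slower approach
to K).  That ordering is asserted for the calibrated configuration, not
claimed universally.

## Multiple-scales approximation

For slowly varying coefficients `K(εt) = K0 + δ sin εt`,
`r(εt) = r0 + Δ sin εt` (amplitudes `|δ| < K0`, `|Δ| < r0` keep both
positive; δ may be given in individuals or as a fraction of K0 via a units
flag), the two-term expansion is built on the accumulated-growth fast time

```
t0(t) = ∫0^t r(εs) ds = r0 t + (Δ/ε)(1 − cos εt),
```

(ε = 0 freezes the coefficients, t0 = r0 t) and reads

```
N ≈ K(εt) N0 K0 / D  −  ε N0² [K′ K0² r0 − K(εt)² K′ r(εt) e^{−t0}] / (r(εt) r0 D²),
D = N0 K0 + K(εt)(K0 − N0) e^{−t0}.
```

**Convention for K′.**  K′ is the slow-time derivative `dK/dT = δ cos(εt)`.
This is the package's own resolution of an ambiguity in the printed source
form: with the slow-time reading the large-t limit of the two terms is
`K(T) − ε K′(T)/r(T)`, exactly the standard O(ε) tracking of the slowly
moving logistic attractor, and the measured error against a high-accuracy
ODE solution of the nonautonomous equation falls with log–log slope ≈ 1.5
over ε ∈ {0.2, …, 0.025}.  Reading K′ as d/dt instead makes the correction
O(ε²δ) and leaves an uncorrected O(εδ) error (measured slope ≈ 0.5), failing
the expansion's own accuracy contract.  Two exact limits pin the remaining
sign/brace choices: at δ = Δ = 0 the expression reduces to the
constant-parameter closed form to machine precision, and at t = 0 the
correction numerator vanishes so N(0) = N0 exactly.  A denominator within
1e-12·N0·K0 of zero raises an expansion-breakdown error; for positive
parameters and t ≥ 0 this cannot occur, the guard protects extrapolated use.

## Calibration

`fit_logistic` minimizes raw-count residuals (a log-count option exists; raw
counts match the magnitude of the reported carrying capacities) over
`(r, K)` with `N0` pinned to the first observation, using scipy's
trust-region-reflective `least_squares` within bounds r ∈ (1e-4, 1) per year
and K ∈ (max observed count, 20× that) — on a short, pre-inflection series
the sigmoid is otherwise unidentifiable.  The starting point is the
three-point Verhulst estimate on the first/middle/last observations
(interpolating where 2T overshoots the span), clipped into bounds, with a
fixed fallback if the triple is degenerate.  A strictly decreasing series is
reported as `converged = False` with an explicit regime-mismatch message:
with `N0` fixed at the largest observation and `K` above it, the growth
model cannot represent such data.

Goodness of fit: Pearson correlation between observed and modeled counts
("regression coefficient r" in demographic usage) and `R² = 1 − SS_res/SS_tot`.
The 95% interval on the correlation uses the Fisher z normal approximation —
an explicit interpretation, since the interval construction behind reported
demographic tables is rarely stated.  Percent errors print at two decimals,
switching to scientific notation below 1e-3.

## Stability constants

For `f(N) = rN(1 − N/K)` restricted to `|N| ≤ N0` the Lipschitz constant is
`Ψ = r + 2rN0/K`.  The uniqueness criterion on `[0, b]` is
`Ω = (1−α)/ABC(α)·Ψ + α b^α/(Γ(α) ABC(α))·Ψ < 1` and the Hyers–Ulam
criterion is `η = (Γ(α) + b^α)/(Γ(α) ABC(α))·Ψ < 1`; an alternative
statement of the latter that coincides with Ω is exposed behind a formula
flag.  Both are homogeneous of degree 1 in Ψ and monotone in b.  The horizon
`b` is always an explicit input — no default is inferred from the analysis
span, because the criteria certify a property of a chosen interval, not of
the data.

## Synthetic data

`generate_census` emulates the real census pathway: evaluate a forward model
(constant-parameter logistic, or the multiple-scales family) at the census
years, optionally annualize by monotone piecewise-cubic (PCHIP) or linear
interpolation — the same interpolant the calibration pathway uses, so
synthetic and real data flow through identical plumbing — then apply
multiplicative lognormal noise, `count × exp(X)` with
`X ~ Normal(−σ²/2, σ²)` so the multiplier has unit mean.  Census counts are
positive with roughly size-proportional errors, which this noise family
matches; the default scale σ = 0.005 (0.5%) reflects the order of
post-enumeration adjustments to modern censuses.  All randomness flows
through one seeded `numpy` generator; identical inputs and seed reproduce
the series bit-for-bit.

What the generator does *not* emulate: undercount bias that varies
systematically over time, boundary/definition changes between censuses, and
any demographic microstructure.  Passing the recovery tests therefore shows
the estimation pipeline is correct and noise-robust under proportional
observation error, not that real census series satisfy the logistic model.

The package also ships the source study's printed constants (fitted
parameters, table cells, stability constants) in a versioned JSON fixtures
file behind `paper_fixture`.  These are inputs and test anchors, never
computed quantities; one multiscale parameter row is typographically garbled
in the source and is stored verbatim with an `ambiguous` flag, with nothing
downstream depending on it.

## Pipeline

`run_analysis` evaluates all four schemes at the target year on a shared
grid (default h = 0.01 year), computes percent errors against the census
value, regression statistics over the full census overlap, and the stability
report.  The comparison table's fractional order defaults to α = 0.95 — a
deliberate, visible memory effect; the source tables' fractional order is
unstated, so those cells are treated as fixtures, not targets.  The
multiscale row defaults to δ = Δ = 0 (constant-coefficient limit) unless
amplitudes are configured.  `run_forecast` propagates to the horizon over
the α grid {1.0, 0.95, 0.9, 0.85, 0.8} (default forecast step h = 0.05 to
keep the O(n²) history sums at desk scale) and over an `r0` sweep for the
multiscale scheme, tabulating final population sizes in millions at three
decimals.  Reports round populations to 4 decimals and percent errors to 2
(scientific below 1e-3), mirroring standard demographic tables, and embed
provenance (config hash, seed, package version, interpolation choice) so
identical configs yield byte-identical JSON.

## Known limitations

- The ABC stepping scheme is explicit; very small α combined with large
  steps destabilizes it (the guard aborts rather than truncating memory).
- The multiple-scales form assumes sinusoidal coefficient families; other
  slowly varying shapes go through `timevarying_exact` with user callables.
- Calibration fixes `N0` at the first observation; measurement error in that
  single count propagates into both fitted parameters.
- On series that end well before the inflection point, `K` is weakly
  identified and its confidence statements should not be over-read.
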