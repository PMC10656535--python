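"""Mittag-Leffler kernel, ABC integral, Lagrange weights and the fractional solver."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from poplogistic import (
    FracConfig,
    LogisticParams,
    TimeGrid,
    abc_forecast,
    abc_integral_constant,
    abc_solve,
    abc_weights,
    logistic_exact,
    mittag_leffler,
)
from poplogistic.abc_fractional import SchemeInstabilityError


def weight_quadrature(alpha: float, h: float, n: int, k: int, lag: int) -> float:
    """Defining integral int_{t_k}^{t_{k+1}} (v - t_{k-lag}) (t_{n+1} - v)^(alpha-1) dv.

    For k == n the kernel is singular at the upper limit, so the algebraic
    endpoint weight of QUADPACK is used there.
    """
    tk, tk1 = k * h, (k + 1) * h
    tkl, tn1 = (k - lag) * h, (n + 1) * h
    if k == n and alpha < 1:
        val, _ = quad(
            lambda v: v - tkl, tk, tk1,
            weight="alg", wvar=(0.0, alpha - 1.0),
            epsabs=1e-13, epsrel=1e-13,
        )
    else:
        val, _ = quad(
            lambda v: (v - tkl) * (tn1 - v) ** (alpha - 1),
            tk, tk1, epsabs=1e-13, epsrel=1e-13,
        )
    return val


class TestMittagLeffler:
    def test_alpha_one_is_exponential(self):
        for z in np.linspace(-5.0, 5.0, 21):
            assert mittag_leffler(1.0, z) == pytest.approx(math.exp(z), rel=1e-10)

    def test_normalization_at_zero(self):
        assert mittag_leffler(0.7, 0.0) == 1.0

    def test_alpha_two_is_cosh(self):
        assert mittag_leffler(2.0, 1.0) == pytest.approx(math.cosh(1.0), rel=1e-12)

    def test_high_precision_fallback_large_argument(self):
        # E_1(-20) = e^-20 exercises the cancellation-heavy branch
        assert mittag_leffler(1.0, -20.0) == pytest.approx(
            math.exp(-20.0), abs=1e-12
        )
        assert mittag_leffler(1.0, 15.0) == pytest.approx(math.exp(15.0), rel=1e-12)


class TestAbcIntegralConstant:
    def test_zero_input(self):
        assert abc_integral_constant(0.0, FracConfig(alpha=0.5), 3.0) == 0.0

    def test_classical_limit_alpha_one(self):
        # alpha = 1 is the ordinary integral of a constant
        assert abc_integral_constant(1.0, FracConfig(alpha=1.0), 2.0) == pytest.approx(
            2.0, rel=1e-14
        )

    def test_half_order_against_quadrature(self):
        # direct numerical quadrature of the defining operator for F = 1
        a, t = 0.5, 1.0
        kernel, _ = quad(lambda v: (t - v) ** (a - 1), 0.0, t, points=[t])
        expected = (1 - a) + a / math.gamma(a) * kernel
        got = abc_integral_constant(1.0, FracConfig(alpha=a), t)
        assert got == pytest.approx(expected, rel=1e-9)
        assert got == pytest.approx(0.5 + 1.0 / math.gamma(0.5), rel=1e-12)


class TestAbcWeights:
    def test_classical_limit_closed_form(self):
        for h in (0.1, 0.5, 2.0):
            w = abc_weights(1.0, h, n=7, k=7)
            assert w.A1 == pytest.approx(1.5 * h * h, rel=1e-12)
            assert w.A2 == pytest.approx(0.5 * h * h, rel=1e-12)

    @pytest.mark.parametrize("alpha", [0.3, 0.5, 0.8, 0.95, 1.0])
    @pytest.mark.parametrize("h", [0.1, 0.5, 1.0])
    @pytest.mark.parametrize("n,k", [(0, 0), (4, 2), (4, 4), (9, 0), (9, 7)])
    def test_weights_equal_defining_integrals(self, alpha, h, n, k):
        w = abc_weights(alpha, h, n, k)
        q1 = weight_quadrature(alpha, h, n, k, lag=1)
        q2 = weight_quadrature(alpha, h, n, k, lag=0)
        assert w.A1 == pytest.approx(q1, rel=1e-9)
        assert w.A2 == pytest.approx(q2, rel=1e-9, abs=1e-300)

    def test_positivity(self):
        for alpha in (0.2, 0.6, 1.0):
            for n in (0, 3, 10):
                for k in range(n + 1):
                    w = abc_weights(alpha, 0.25, n, k)
                    assert w.A1 > 0 and w.A2 >= 0

    def test_out_of_range_history_index(self):
        with pytest.raises(ValueError):
            abc_weights(0.8, 0.5, n=4, k=5)


class TestAbcSolve:
    def test_zero_vector_field_constant(self):
        p = LogisticParams(r=0.0, K=1e8, N0=5e7)
        traj = abc_solve(p, FracConfig(alpha=0.6, h=0.5), TimeGrid(0.0, 0.5, 30))
        assert np.all(traj.values == p.N0)

    def test_classical_limit_converges_to_closed_form(self, adjusted_params):
        exact = float(logistic_exact(adjusted_params, 48.0))
        errs = []
        for h in (0.2, 0.1, 0.05, 0.025):
            grid = TimeGrid(0.0, h, int(round(48.0 / h)))
            v = abc_solve(adjusted_params, FracConfig(alpha=1.0, h=h), grid).final()
            errs.append(abs(v - exact) / exact)
        assert errs[0] <= 1e-3
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert np.all(orders >= 1.0)

    def test_single_step_matches_hand_expansion(self):
        # one step of the recursion at alpha = 1/2, h = 1, expanded by hand:
        # with the constant-extension convention f(N_-1) = f(N_0),
        #   N_1 = N_0 + (1-a) f_0 + a h^a / Gamma(a+2) * f_0 * (w1(0) - w2(0)),
        #   w1(0) = 2 + a,  w2(0) = 1.
        a, h = 0.5, 1.0
        p = LogisticParams(r=0.05, K=1000.0, N0=100.0)
        f0 = p.r * p.N0 * (1 - p.N0 / p.K)
        expected = p.N0 + (1 - a) * f0 + a * h**a / math.gamma(a + 2) * f0 * (
            (2 + a) - 1.0
        )
        traj = abc_solve(p, FracConfig(alpha=a, h=h), TimeGrid(0.0, h, 1))
        assert traj.values[-1] == pytest.approx(expected, rel=1e-14)

    def test_drop_convention_single_step(self):
        # dropping the k = 0 second Lagrange term removes the w2 contribution
        a, h = 0.5, 1.0
        p = LogisticParams(r=0.05, K=1000.0, N0=100.0)
        f0 = p.r * p.N0 * (1 - p.N0 / p.K)
        expected = p.N0 + (1 - a) * f0 + a * h**a / math.gamma(a + 2) * f0 * (2 + a)
        traj = abc_solve(
            p, FracConfig(alpha=a, h=h), TimeGrid(0.0, h, 1),
            history_convention="drop",
        )
        assert traj.values[-1] == pytest.approx(expected, rel=1e-14)

    @pytest.mark.parametrize("alpha", [0.8, 0.9, 1.0])
    def test_positivity_and_boundedness(self, adjusted_params, alpha):
        grid = TimeGrid(0.0, 0.05, 960)
        traj = abc_solve(adjusted_params, FracConfig(alpha=alpha, h=0.05), grid)
        assert np.all(traj.values > 0)
        assert np.all(traj.values <= adjusted_params.K * (1 + 1e-6))

    def test_instability_aborts_with_diagnostic(self):
        # an aggressively large step at strong growth destabilizes the
        # explicit recursion; the solver must abort, not return garbage
        p = LogisticParams(r=2.5, K=1e6, N0=1e5)
        with pytest.raises(SchemeInstabilityError):
            abc_solve(p, FracConfig(alpha=0.9, h=5.0), TimeGrid(0.0, 5.0, 60))


class TestAbcForecast:
    def test_single_alpha_identical_to_solve(self, adjusted_params):
        cfg = FracConfig(alpha=1.0, h=0.1)
        (traj,) = abc_forecast(adjusted_params, [1.0], cfg, horizon=20.0)
        direct = abc_solve(adjusted_params, cfg, TimeGrid(0.0, 0.1, 200))
        assert np.array_equal(traj.values, direct.values)

    def test_boundedness_across_orders(self, adjusted_params):
        cfg = FracConfig(alpha=1.0, h=0.1)
        for traj in abc_forecast(adjusted_params, [1.0, 0.8], cfg, horizon=100.0):
            final = traj.final()
            assert adjusted_params.N0 < final < adjusted_params.K

    def test_growth_phase_ordering_in_alpha(self, adjusted_params):
        # smaller fractional order = heavier memory = slower approach to K
        cfg = FracConfig(alpha=1.0, h=0.1)
        alphas = [1.0, 0.95, 0.9, 0.85, 0.8]
        finals = [
            t.final()
            for t in abc_forecast(adjusted_params, alphas, cfg, horizon=106.0)
        ]
        assert all(a > b for a, b in zip(finals, finals[1:]))
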