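"""Closed-form logistic machinery, Verhulst estimation, integer-order solvers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from poplogistic import (
    LogisticParams,
    TimeGrid,
    logistic_exact,
    logistic_rhs,
    pece_solve,
    rkf_solve,
    timevarying_exact,
    verhulst_estimate,
)
from poplogistic.model_core import DegenerateTripleError


class TestLogisticRhs:
    @pytest.mark.parametrize(
        "N_over_K, expected_over_rK",
        [(1.0, 0.0), (0.0, 0.0), (0.5, 0.25)],
        ids=["equilibrium", "extinction", "inflection-maximum"],
    )
    def test_fixed_points_and_maximum(self, N_over_K, expected_over_rK):
        p = LogisticParams(r=0.04, K=1e8, N0=1e7)
        assert logistic_rhs(p, N_over_K * p.K) == pytest.approx(
            expected_over_rK * p.r * p.K, abs=1e-9
        )

    def test_negative_population_rejected(self):
        with pytest.raises(ValueError):
            logistic_rhs(LogisticParams(r=0.04, K=1e8, N0=1e7), -1.0)


class TestLogisticExact:
    def test_initial_condition(self, adjusted_params):
        assert logistic_exact(adjusted_params, 0.0) == pytest.approx(
            adjusted_params.N0, rel=1e-15
        )

    def test_2022_value_matches_printed_table(self, adjusted_params):
        # closed-form value at t = 48 (calendar 2022 for epoch 1974)
        assert logistic_exact(adjusted_params, 48.0) == pytest.approx(
            170145565.0601, abs=1e-4
        )

    def test_carrying_capacity_limit(self, adjusted_params):
        t = 50.0 / adjusted_params.r  # r*t = 50
        assert logistic_exact(adjusted_params, t) == pytest.approx(
            adjusted_params.K, rel=1e-9
        )

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        r=st.floats(0.005, 0.5),
        ratio=st.floats(0.01, 0.99),
        K=st.floats(1e3, 1e9),
    )
    def test_growth_regime_monotone_and_bounded(self, r, ratio, K):
        p = LogisticParams(r=r, K=K, N0=ratio * K)
        # below float saturation (r*t <= 30) growth is strictly monotone
        t = np.linspace(0.0, 30.0 / r, 101)
        N = logistic_exact(p, t)
        assert np.all(np.diff(N) > 0)
        assert np.all(N < K)

    def test_decay_regime_monotone_decreasing(self):
        p = LogisticParams(r=0.05, K=1e8, N0=3e8)
        assert p.growth_regime == "decay"
        N = logistic_exact(p, np.linspace(0, 100, 51))
        assert np.all(np.diff(N) < 0) and np.all(N > p.K)


class TestVerhulstEstimate:
    def test_round_trip_on_noiseless_triple(self):
        true = LogisticParams(r=0.03, K=2e8, N0=76398000.0)
        N0, N1, N2 = (float(logistic_exact(true, t)) for t in (0.0, 24.0, 48.0))
        K, r = verhulst_estimate(N0, N1, N2, T=24.0)
        assert K == pytest.approx(true.K, rel=1e-9)
        assert r == pytest.approx(true.r, rel=1e-9)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        r=st.floats(0.01, 0.2),
        ratio=st.floats(0.05, 0.8),
        T=st.floats(1.0, 30.0),
    )
    def test_round_trip_property(self, r, ratio, T):
        true = LogisticParams(r=r, K=5e8, N0=ratio * 5e8)
        N0, N1, N2 = (float(logistic_exact(true, k * T)) for k in range(3))
        K, r_hat = verhulst_estimate(N0, N1, N2, T=T)
        assert K == pytest.approx(true.K, rel=1e-7)
        assert r_hat == pytest.approx(true.r, rel=1e-7)

    def test_geometric_triple_rejected(self):
        with pytest.raises(DegenerateTripleError):
            verhulst_estimate(100.0, 200.0, 400.0, T=10.0)

    def test_equilibrium_triple_rejected(self):
        with pytest.raises(DegenerateTripleError):
            verhulst_estimate(500.0, 500.0, 500.0, T=10.0)


class TestTimevaryingExact:
    def test_constant_coefficients_reduce_to_closed_form(self, rng):
        for _ in range(20):
            r = rng.uniform(0.01, 0.2)
            K = rng.uniform(1e6, 1e9)
            N0 = rng.uniform(0.05, 0.9) * K
            t = rng.uniform(1.0, 80.0)
            p = LogisticParams(r=r, K=K, N0=N0)
            val = timevarying_exact(lambda s: r + 0 * s, lambda s: K + 0 * s, N0, t)
            assert val == pytest.approx(float(logistic_exact(p, t)), rel=1e-10)

    def test_malthusian_limit(self):
        N0, r, t = 76398000.0, 0.03, 10.0
        val = timevarying_exact(
            lambda s: r + 0 * s, lambda s: 1e15 * N0 + 0 * s, N0, t
        )
        assert val == pytest.approx(N0 * np.exp(r * t), rel=1e-6)

    def test_periodic_coefficients_match_ode_oracle(self):
        r0, K0 = 0.0374286, 225062093.9465337
        delta, Delta, eps = 1e6, 1e-3, 0.1
        N0 = 76398000.0

        def r_fn(s):
            return r0 + Delta * np.sin(eps * s)

        def K_fn(s):
            return K0 + delta * np.sin(eps * s)

        sol = solve_ivp(
            lambda t, y: r_fn(t) * y * (1 - y / K_fn(t)),
            (0.0, 48.0),
            [N0],
            rtol=1e-12,
            atol=1e-3,
        )
        val = timevarying_exact(r_fn, K_fn, N0, 48.0)
        assert val == pytest.approx(sol.y[0, -1], rel=1e-6)


class TestIntegerOrderSolvers:
    def test_pece_matches_printed_2022_cell(self, adjusted_params):
        grid = TimeGrid(t_start=0.0, h=0.01, n_steps=4800)
        final = pece_solve(adjusted_params, grid).final()
        assert final == pytest.approx(170145565.0603, rel=1e-6)

    def test_pece_zero_growth_is_constant(self):
        p = LogisticParams(r=0.0, K=1e8, N0=5e7)
        traj = pece_solve(p, TimeGrid(0.0, 0.5, 40))
        assert np.all(traj.values == p.N0)

    def test_pece_agrees_with_adaptive_rk(self, adjusted_params):
        grid = TimeGrid(0.0, 0.01, 4800)
        pece = pece_solve(adjusted_params, grid).final()
        rkf = rkf_solve(adjusted_params, 48.0, tol=1e-10).final()
        assert pece == pytest.approx(rkf, rel=1e-8)

    def test_pece_convergence_order_at_least_two(self, adjusted_params):
        exact = float(logistic_exact(adjusted_params, 48.0))
        errs = []
        for h in (0.2, 0.1, 0.05, 0.025):
            grid = TimeGrid(0.0, h, int(round(48.0 / h)))
            errs.append(abs(pece_solve(adjusted_params, grid).final() - exact) / exact)
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert np.all(orders >= 2.0)

    def test_rkf_tracks_closed_form(self, adjusted_params):
        tol = 1e-10
        traj = rkf_solve(adjusted_params, 48.0, tol=tol)
        exact = np.asarray(logistic_exact(adjusted_params, traj.times))
        assert np.max(np.abs(traj.values - exact) / exact) <= 10 * tol

    def test_rkf_equilibrium_start_stays_constant(self):
        p = LogisticParams(r=0.05, K=1e8, N0=1e8)
        traj = rkf_solve(p, 50.0, tol=1e-8)
        assert np.allclose(traj.values, p.K, rtol=1e-7)

    def test_rkf_rejects_loose_tolerance(self, adjusted_params):
        with pytest.raises(ValueError):
            rkf_solve(adjusted_params, 48.0, tol=0.01)
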