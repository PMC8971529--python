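"""Cycle transfer curve, closed-loop fixed point, and sensitivity theory."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from phosphocycle.cmc_model import (
    CMCParams,
    DegenerateCycleWarning,
    PromoterHill,
    closedloop_output,
    closedloop_rates,
    closedloop_steady_state,
    cmc_rate,
    gk_transfer,
    quasi_integral_setpoint,
    sensitivity_cl,
    sensitivity_cl_fd,
    sensitivity_ol,
    simulate,
)

from conftest import random_params


def ode_steady_state(params: CMCParams, P_t: float, x0: float | None = None) -> float:
    """Independent oracle: integrate the bare cycle until X* stops moving."""
    x = params.X_t / 2 if x0 is None else x0
    scale = params.theta_k * params.K_t + params.theta_p * P_t
    t_chunk = 1.0 / max(scale / params.X_t, 1e-6)
    for _ in range(80):
        sol = solve_ivp(
            lambda _t, y: [cmc_rate(min(max(y[0], 0.0), params.X_t), params, P_t)],
            (0.0, t_chunk), [x], method="LSODA",
            rtol=1e-12, atol=1e-13 * params.X_t,
        )
        x_new = float(sol.y[0, -1])
        if abs(x_new - x) < 1e-10 * params.X_t:
            return x_new
        x, t_chunk = x_new, t_chunk * 2
    return x


class TestGKTransfer:
    def test_no_kinase_drains_cycle(self, simple_params):
        assert gk_transfer(simple_params, 0.0, 1.0) == 0.0

    def test_no_phosphatase_full_phosphorylation(self, simple_params):
        assert gk_transfer(simple_params, 1.0, 0.0) == simple_params.X_t

    def test_hand_solved_symmetric_balance(self, simple_params):
        # (10 - X)(X + 1) = X(11 - X) has the root X = 5
        assert gk_transfer(simple_params, 1.0, 1.0) == pytest.approx(5.0, rel=1e-12)

    def test_degenerate_both_enzymes_absent(self, simple_params):
        with pytest.warns(DegenerateCycleWarning):
            assert gk_transfer(simple_params, 0.0, 0.0) == 0.0

    def test_rejects_non_finite(self, simple_params):
        with pytest.raises(ValueError):
            gk_transfer(simple_params, np.nan, 1.0)
        with pytest.raises(ValueError):
            gk_transfer(simple_params, 1.0, -0.5)

    def test_closed_form_vs_bracketed_root_vs_ode(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            p = random_params(rng)
            P = 10 ** rng.uniform(-1, 2)
            x_cf = gk_transfer(p, p.K_t, P)
            x_br = brentq(lambda x: cmc_rate(x, p, P), 0.0, p.X_t,
                          xtol=1e-15 * p.X_t, rtol=8.9e-16)
            x_ode = ode_steady_state(p, P)
            assert x_cf == pytest.approx(x_br, abs=1e-9 * p.X_t)
            assert x_cf == pytest.approx(x_ode, abs=1e-6 * p.X_t)

    def test_vectorised_matches_scalar(self, simple_params):
        K = np.array([0.0, 1.0, 2.0, 5.0])
        P = np.array([1.0, 1.0, 0.5, 2.0])
        vec = gk_transfer(simple_params, K, P)
        scalar = [gk_transfer(simple_params, k, q) for k, q in zip(K, P)]
        np.testing.assert_allclose(vec, scalar, rtol=1e-12)

    def test_monotone_in_enzymes(self, simple_params):
        # more kinase -> more X*; more phosphatase -> less
        ks = np.linspace(0.1, 10, 25)
        xs = gk_transfer(simple_params, ks, 1.0)
        assert np.all(np.diff(xs) > 0)
        ps = np.linspace(0.1, 10, 25)
        xs = gk_transfer(simple_params, 1.0, ps)
        assert np.all(np.diff(xs) < 0)


class TestCMCRate:
    def test_zero_at_empty_cycle(self, simple_params):
        assert cmc_rate(0.0, simple_params, 3.0, K_t=0.0) == 0.0

    def test_direct_evaluation(self, simple_params):
        # 10/6 - 5/6 at X* = 5, K_t = 2
        assert cmc_rate(5.0, simple_params, 1.0, K_t=2.0) == pytest.approx(5 / 6, rel=1e-12)

    def test_zero_at_transfer_root(self, simple_params):
        x = gk_transfer(simple_params, 2.0, 1.5)
        assert cmc_rate(x, simple_params, 1.5, K_t=2.0) == pytest.approx(0.0, abs=1e-10)

    def test_rejects_state_outside_bounds(self, simple_params):
        with pytest.raises(ValueError):
            cmc_rate(11.0, simple_params, 1.0)
        with pytest.raises(ValueError):
            cmc_rate(-0.5, simple_params, 1.0)


def closedloop_rates_reference(state, p: CMCParams):
    """Second, independently coded evaluator of the model equations."""
    x, P = state
    kinase_flux = p.theta_k * p.K_t * (p.X_t - x) / (p.X_t - x + p.K_Mk)
    phos_flux = p.theta_p * P * x / (x + p.K_Mp)
    hill = p.phi.basal + (1 - p.phi.basal) * (x / p.phi.K_D) ** 2 / (1 + (x / p.phi.K_D) ** 2)
    return kinase_flux - phos_flux, p.alpha * (1 - p.w) * hill - p.gamma * P


class TestClosedLoop:
    def test_rates_vanish_at_fixed_point(self, simple_params):
        ss = closedloop_steady_state(simple_params)
        dx, dp = closedloop_rates((ss.X_star, ss.P_t), simple_params)
        assert abs(dx) < 1e-8 and abs(dp) < 1e-8

    def test_pure_decay_without_activation(self, simple_params):
        _, dp = closedloop_rates((0.0, 2.0), simple_params)
        assert dp == pytest.approx(-simple_params.gamma * 2.0, rel=1e-12)

    def test_rates_match_independent_evaluator(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            p = random_params(rng)
            state = (rng.uniform(0, p.X_t), rng.uniform(0, 5 * p.alpha / p.gamma))
            got = closedloop_rates(state, p)
            want = closedloop_rates_reference(state, p)
            np.testing.assert_allclose(got, want, rtol=1e-10)

    def test_dark_fixed_point_without_kinase(self, simple_params):
        ss = closedloop_steady_state(simple_params.with_(K_t=0.0))
        assert (ss.X_star, ss.P_t, ss.Y) == (0.0, 0.0, 0.0)

    def test_output_tracks_stoichiometry(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            p = random_params(rng)
            ss = closedloop_steady_state(p)
            assert ss.Y == p.rho * ss.P_t

    def test_steady_state_matches_long_simulation(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            p = random_params(rng)
            ss = closedloop_steady_state(p)
            rate_scale = max(p.gamma, p.theta_k * max(p.K_t, 1e-3) / p.X_t)
            t_end = 200.0 / min(p.gamma, rate_scale)
            _, X, P, Y = simulate(p, (0.0, 0.0), np.linspace(0, t_end, 50))
            assert Y[-1] == pytest.approx(ss.Y, rel=1e-4)

    def test_vectorised_output_matches_scalar(self, quasi_integral_params):
        p = quasi_integral_params
        K = np.array([100.0, 50.0, 0.0])
        Y = closedloop_output(p, K, np.full(3, p.alpha), 0.0)
        assert Y[0] == pytest.approx(closedloop_steady_state(p).Y, rel=1e-9)
        assert Y[1] == pytest.approx(closedloop_steady_state(p.with_(K_t=50.0)).Y, rel=1e-9)
        assert Y[2] == 0.0

    def test_output_increasing_in_kinase(self, quasi_integral_params):
        Ks = np.linspace(10, 300, 30)
        Ys = closedloop_output(quasi_integral_params, Ks,
                               np.full(30, quasi_integral_params.alpha), 0.0)
        assert np.all(np.diff(Ys) > 0)


class TestSimulate:
    def test_constant_at_fixed_point(self, simple_params):
        ss = closedloop_steady_state(simple_params)
        _, X, P, _ = simulate(simple_params, (ss.X_star, ss.P_t), np.linspace(0, 20, 40))
        np.testing.assert_allclose(X, ss.X_star, rtol=1e-5)
        np.testing.assert_allclose(P, ss.P_t, rtol=1e-5)

    def test_open_loop_relaxes_to_transfer_root(self, simple_params):
        _, X, P, _ = simulate(simple_params, (0.0, 1.5), np.linspace(0, 200, 30),
                              hold_phosphatase=True)
        assert P[-1] == 1.5
        assert X[-1] == pytest.approx(gk_transfer(simple_params, None, 1.5), rel=1e-6)

    def test_solver_consistency_under_grid_refinement(self, simple_params):
        _, _, _, Y1 = simulate(simple_params, (0.0, 0.0), np.linspace(0, 50, 50))
        _, _, _, Y2 = simulate(simple_params, (0.0, 0.0), np.linspace(0, 50, 100))
        assert Y1[-1] == pytest.approx(Y2[-1], rel=1e-6)

    def test_trajectory_respects_bounds(self, simple_params):
        _, X, P, _ = simulate(simple_params, (simple_params.X_t, 0.0),
                              np.linspace(0, 100, 100))
        assert np.all(X >= 0) and np.all(X <= simple_params.X_t) and np.all(P >= 0)

    def test_rejects_bad_grid(self, simple_params):
        with pytest.raises(ValueError):
            simulate(simple_params, (0.0, 0.0), [1.0, 1.0, 2.0])


class TestQuasiIntegral:
    def test_printed_balance(self):
        p = CMCParams(theta_k=1.0, theta_p=1.5, K_Mk=1, K_Mp=1, X_t=10, K_t=3.0,
                      alpha=1, gamma=1, rho=2.0, phi=PromoterHill(K_D=5))
        assert quasi_integral_setpoint(p) == pytest.approx(4.0)

    def test_zero_kinase(self, simple_params):
        assert quasi_integral_setpoint(simple_params.with_(K_t=0.0)) == 0.0

    def test_independent_of_production_and_disturbance(self, quasi_integral_params):
        p = quasi_integral_params
        base = quasi_integral_setpoint(p)
        assert quasi_integral_setpoint(p.with_(alpha=2 * p.alpha)) == base
        assert quasi_integral_setpoint(p.with_(w=0.5)) == base

    def test_closed_loop_attains_setpoint(self, quasi_integral_params):
        ss = closedloop_steady_state(quasi_integral_params)
        assert ss.Y == pytest.approx(quasi_integral_setpoint(quasi_integral_params), rel=0.05)

    def test_linear_in_kinase_with_unit_slope_ratio(self, quasi_integral_params):
        p = quasi_integral_params
        Ks = np.array([50.0, 100.0, 200.0])
        Ys = np.array([closedloop_steady_state(p.with_(K_t=k)).Y for k in Ks])
        slope = np.polyfit(Ks, Ys, 1)[0]
        assert slope == pytest.approx(p.rho * p.theta_k / p.theta_p, rel=0.05)


class TestSensitivity:
    def test_open_loop_closed_form(self):
        assert sensitivity_ol(0.0) == 1.0
        assert sensitivity_ol(0.5) == pytest.approx(2.0)
        ws = np.linspace(0, 0.99, 50)
        vals = [sensitivity_ol(w) for w in ws]
        assert np.all(np.diff(vals) > 0)

    def test_open_loop_rejects_unit_disturbance(self):
        with pytest.raises(ValueError):
            sensitivity_ol(1.0)

    def test_saturated_promoter_disables_feedback(self, quasi_integral_params):
        # X* >> K_D: phi' ~ 0, loop gain vanishes, S_CL -> S_OL
        p = quasi_integral_params.with_(phi=PromoterHill(K_D=1e-3), w=0.3)
        res = sensitivity_cl(p)
        assert res.S_CL / res.S_OL == pytest.approx(1.0, abs=0.02)

    def test_quasi_integral_near_perfect_adaptation(self, quasi_integral_params):
        res = sensitivity_cl(quasi_integral_params.with_(w=0.5))
        assert res.S_CL < 0.05
        assert sensitivity_cl_fd(quasi_integral_params.with_(w=0.5)) < 0.05

    def test_analytic_matches_finite_difference(self):
        rng = np.random.default_rng(21)
        for _ in range(60):
            p = random_params(rng)
            res = sensitivity_cl(p)
            fd = sensitivity_cl_fd(p)
            assert res.S_CL == pytest.approx(fd, rel=0.01)
            assert res.S_CL < res.S_OL  # strict: loop gain is positive
            # FD oracle resolves the inequality only up to its own noise
            assert fd < res.S_OL * (1.0 + 1e-9)

    @given(st.integers(min_value=0, max_value=10_000))
    def test_closed_loop_never_less_robust(self, seed):
        p = random_params(np.random.default_rng(seed))
        res = sensitivity_cl(p)
        assert res.S_CL <= res.S_OL
        assert res.S_OL == pytest.approx(1.0 / (1.0 - p.w), rel=1e-12)

    def test_adaptation_improves_toward_zero_order_limit(self):
        # shrinking K_Mp and growing X_t (promoter unsaturated) drives S_CL down
        base = dict(theta_k=1.0, theta_p=1.0, K_Mk=1.0, alpha=1e4, gamma=1.0,
                    K_t=100.0, w=0.5)
        s_vals = []
        for f in (1.0, 10.0, 100.0):
            p = CMCParams(K_Mp=1.0 / f, X_t=100.0 * f, phi=PromoterHill(K_D=50.0 * f),
                          **base)
            s_vals.append(sensitivity_cl(p).S_CL)
        assert s_vals[0] > s_vals[1] > s_vals[2]


class TestValidation:
    def test_disturbance_bounds(self, simple_params):
        with pytest.raises(ValueError):
            simple_params.with_(w=1.0)
        with pytest.raises(ValueError):
            simple_params.with_(w=-0.1)

    def test_positivity(self, simple_params):
        for bad in ("theta_k", "alpha", "gamma", "X_t", "rho"):
            with pytest.raises(ValueError):
                simple_params.with_(**{bad: 0.0})

    def test_promoter_hill_constraints(self):
        with pytest.raises(ValueError):
            PromoterHill(K_D=-1.0)
        with pytest.raises(ValueError):
            PromoterHill(K_D=1.0, basal=1.0)
        phi = PromoterHill(K_D=10.0, basal=0.1)
        xs = np.linspace(0, 100, 200)
        vals = phi(xs)
        assert np.all(np.diff(vals) > 0) and vals[0] == 0.1 and np.all(vals < 1)

    def test_conservation_is_implicit(self, simple_params):
        # X(unphosphorylated) + X* = X_t by construction of the state
        x = gk_transfer(simple_params, 1.0, 1.0)
        assert 0 <= x <= simple_params.X_t
        assert (simple_params.X_t - x) + x == pytest.approx(simple_params.X_t)
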