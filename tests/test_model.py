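import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from flowtwin.model import (
    VALVE_LEAK_EPS,
    elastance,
    initial_state,
    intrinsic_peak_time,
    normalized_activation,
    ode_rhs,
    simulate,
    valve_pressure_gradient,
)
from flowtwin.parameters import ElastanceParams, ValveParams, default_parameters

LV_SHAPE = dict(E_max=2.0, E_min=0.06, R_C=1.9, R_R=21.9,
                alpha_S=0.22, alpha_D=0.40, t_max=0.34, V0=10.0)


class TestActivation:
    def test_zero_at_cycle_start(self):
        assert normalized_activation(0.0, ElastanceParams(**LV_SHAPE), 1.0) == 0.0

    def test_unity_at_end_systole(self):
        p = ElastanceParams(**LV_SHAPE)
        assert normalized_activation(p.t_max, p, 1.0) == pytest.approx(1.0)

    def test_matches_dense_grid_oracle(self):
        """With t_max at the dense-grid argmax of h, the normalized curve
        equals h/max(h) evaluated independently."""
        T = 1.0
        aS, aD, RC, RR = 0.3, 0.5, 2.0, 20.0
        t = np.linspace(T / 1e5, T, 100_000)
        xs = (t / (aS * T)) ** RC
        xd = (t / (aD * T)) ** RR
        h = xs / (1 + xs) / (1 + xd)
        g_oracle = h / h.max()
        t_peak = t[np.argmax(h)]
        p = ElastanceParams(E_max=2.0, E_min=0.05, R_C=RC, R_R=RR,
                            alpha_S=aS, alpha_D=aD, t_max=t_peak)
        g = normalized_activation(t, p, T)
        assert np.max(np.abs(g - g_oracle)) < 1e-10
        assert abs(intrinsic_peak_time(p, T, n=100_000) - t_peak) <= T / 1e5

    def test_overflow_rejected_with_exponent_named(self):
        p = ElastanceParams(E_max=2.0, E_min=0.05, R_C=2.0, R_R=6000.0,
                            alpha_S=0.3, alpha_D=1e-8, t_max=0.3)
        with pytest.raises(FloatingPointError, match="R_R"):
            normalized_activation(0.9, p, 1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        aS=st.floats(0.15, 0.35), aD=st.floats(0.36, 0.55),
        RC=st.floats(1.2, 3.0), RR=st.floats(10.0, 30.0),
        emax=st.floats(1.0, 4.0), emin=st.floats(0.02, 0.15),
    )
    def test_elastance_bounds_and_peak(self, aS, aD, RC, RR, emax, emin):
        """E_min <= E(t) <= E_max on a dense grid and E(t_max) = E_max,
        for randomized valid shapes with t_max at the intrinsic peak."""
        T = 1.0
        p = ElastanceParams(E_max=emax, E_min=emin, R_C=RC, R_R=RR,
                            alpha_S=aS, alpha_D=aD, t_max=0.3)
        p = ElastanceParams(**{**p.__dict__, "t_max": intrinsic_peak_time(p, T)})
        t = np.linspace(0, T, 2001, endpoint=False)
        E = elastance(t, p, T)
        assert np.all(E >= emin - 1e-9)
        assert np.all(E <= emax * (1 + 1e-6))
        assert elastance(p.t_max, p, T) == pytest.approx(emax, rel=1e-12)


class TestValveGradient:
    V = ValveParams(EOA=3.0, A_LVOT=4.0)  # ELCo = 12

    def test_zero_flow_zero_gradient(self):
        assert valve_pressure_gradient(0.0, 0.0, self.V) == 0.0

    def test_convective_term_hand_value(self):
        # rho/(2*12^2) * 400^2 * (0.06/133.322), hand-evaluated
        dp = valve_pressure_gradient(400.0, 0.0, self.V, B=0.0)
        assert dp == pytest.approx(0.2650225269147877, rel=1e-12)

    def test_antisymmetric_in_flow(self):
        dp = valve_pressure_gradient(317.0, 0.0, self.V, B=0.0)
        assert valve_pressure_gradient(-317.0, 0.0, self.V, B=0.0) == pytest.approx(-dp)

    def test_inertial_term_is_additive(self):
        conv = valve_pressure_gradient(200.0, 0.0, self.V, B=0.0)
        full = valve_pressure_gradient(200.0, 1000.0, self.V, B=0.002)
        assert full == pytest.approx(conv + 2.0)

    def test_invalid_valve_rejected(self):
        with pytest.raises(ValueError):
            ValveParams(EOA=5.0, A_LVOT=4.0)


class TestOdeRhs:
    def test_equilibrium_state_has_zero_derivative(self, default_params):
        """With all compartment pressures equal and no flow, nothing moves
        (valve leak terms multiply zero flow)."""
        p = default_params
        v = p.values
        P = 7.0
        t = 0.0  # LV activation is zero at cycle start
        from flowtwin.model import elastance as E
        tla = (t - v["t_onset_la"]) % v["T"]
        E_la = E(tla, p.la_elastance, v["T"])
        y = np.array([
            v["V0_la"] + P / E_la,
            v["V0_lv"] + P / v["E_min_lv"],
            v["V0_aa"] + P * v["C_aa"],
            v["V0_dsc"] + P * v["C_dsc"],
            v["V0_art"] + P * v["C_art"],
            v["V0_ven"] + P * v["C_ven"],
            0.0, 0.0, 0.0,
        ])
        dy = ode_rhs(t, y, p)
        assert np.max(np.abs(dy)) < 1e-9

    def test_closed_loop_volume_conservation(self, default_params, rng):
        """The six volume derivatives sum to zero at arbitrary states."""
        for _ in range(20):
            y = initial_state(default_params)
            y[:6] *= rng.uniform(0.8, 1.2, 6)
            y[6:] = rng.uniform(-50, 500, 3)
            dy = ode_rhs(rng.uniform(0, 1), y, default_params)
            assert abs(np.sum(dy[:6])) < 1e-10 * np.max(np.abs(dy))

    def test_nonfinite_state_rejected(self, default_params):
        y = initial_state(default_params)
        y[2] = np.nan
        with pytest.raises(FloatingPointError):
            ode_rhs(0.1, y, default_params)

    def test_rc_limit_matches_closed_form(self):
        """A single compliance C draining through R to a fixed pressure,
        integrated with the model's solver settings, matches the
        exponential solution to 0.1 %."""
        C, R, P_inf, V0 = 1.2, 0.9, 5.0, 100.0
        tau = R * C

        def rhs(t, y):
            return [-(y[0] / C - P_inf) / R]

        sol = solve_ivp(rhs, (0.0, 3.0), [V0], method="LSODA",
                        rtol=1e-6, atol=1e-8, dense_output=True)
        t = np.linspace(0, 3.0, 50)
        exact = C * P_inf + (V0 - C * P_inf) * np.exp(-t / tau)
        assert np.max(np.abs(sol.sol(t)[0] - exact) / exact) < 1e-3


class TestSimulate:
    def test_default_subject_converges_physiologically(self, default_sim):
        r = default_sim
        assert r.converged
        assert np.all(r.v_lv > 0) and np.all(r.v_la > 0)
        assert 90 < r.sbp < 160 and 50 < r.dbp < 95
        assert r.edv > r.esv > 0

    def test_mean_flow_balance_at_steady_state(self, default_sim):
        q_mv = default_sim.mean_flow("mitral_valve")
        q_av = default_sim.mean_flow("aortic_valve")
        assert abs(q_mv - q_av) / q_av < 10 * 1e-3

    def test_periodicity_drift_below_tolerance(self, default_sim):
        assert default_sim.drift_history[-1] < 1e-3

    def test_valve_unidirectionality(self, default_sim):
        assert default_sim.q_mv.min() >= -VALVE_LEAK_EPS
        assert default_sim.q_av.min() >= -VALVE_LEAK_EPS

    def test_total_volume_conserved_over_cycle(self, default_params, default_sim):
        from flowtwin.model import _rhs, pack_parameter_vector
        pv = pack_parameter_vector(default_params)
        y0 = default_sim.final_state
        sol = solve_ivp(_rhs, (0.0, 5.0), y0, args=(pv,), method="LSODA",
                        rtol=1e-6, atol=1e-8, dense_output=True)
        totals = np.sum(sol.sol(np.linspace(0, 5.0, 100))[:6], axis=0)
        assert totals.max() - totals.min() < 1e-6 * totals.mean()

    def test_halving_aortic_compliance_raises_pulse_pressure(
            self, default_params, default_sim):
        stiff = simulate(default_params.with_values(C_aa=0.15),
                         y0=default_sim.final_state)
        assert (stiff.sbp - stiff.dbp) > (default_sim.sbp - default_sim.dbp)

    def test_csv_export_round_trip(self, default_sim, tmp_path):
        import pandas as pd
        path = tmp_path / "sim.csv"
        default_sim.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns)[:3] == ["time_s", "p_lv_mmHg", "p_la_mmHg"]
        np.testing.assert_allclose(df["q_av_mL_s"], default_sim.q_av)
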