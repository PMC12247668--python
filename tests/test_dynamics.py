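import math

import numpy as np
import pytest

from hvcseq import (
    ActivationSpec,
    IntegrationBlowupError,
    NetworkParameters,
    NetworkState,
    InputProtocol,
    PulseEvent,
    activation,
    apply_boundary_compensation,
    build_connectivity,
    simulate,
    step,
)
from hvcseq.dynamics import SimulationTrace
from hvcseq.readout import track_bump


class TestActivation:
    def test_threshold_linear_at_zero(self):
        assert activation(0.0, ActivationSpec("threshold_linear")) == 0.0

    @pytest.mark.parametrize("family", ["threshold_linear", "threshold_quadratic"])
    def test_non_negative_and_non_decreasing(self, family):
        spec = ActivationSpec(family, gain=1.3, threshold=0.2)
        x = np.linspace(-5, 5, 1000)
        y = activation(x, spec)
        assert (y >= 0).all()
        assert (np.diff(y) >= 0).all()

    def test_global_unit_steeper_than_excitatory(self, default_params):
        # max finite-difference slope over the operating range
        x = np.linspace(0, 5, 1000)
        fg = activation(x, default_params.activation_specs["g"])
        fe = activation(x, default_params.activation_specs["E"])
        assert np.max(np.diff(fg)) > np.max(np.diff(fe))


def scalar_step_oracle(state, conn, params, uva, pulse_RA, pulse_X):
    """Element-wise scalar-loop evaluation of one Euler step (noise off)."""
    N = params.N
    spec = params.activation_specs

    def f(x, s):
        z = max(x - s.threshold, 0.0)
        return s.gain * (z * z if s.family == "threshold_quadratic" else z)

    fE_RA = [f(state.r_RA[j], spec["E"]) for j in range(N)]
    fE_X = [f(state.r_X[j], spec["E"]) for j in range(N)]
    fI = [f(state.r_I[j], spec["I"]) for j in range(N)]
    fg = f(state.r_g, spec["g"])
    fps = f(state.r_ps, spec["ps"])

    new_RA, new_X, new_I = [], [], []
    for i in range(N):
        d = -state.r_RA[i]
        for j in range(N):
            d += conn.W_X_RA[i, j] * fE_X[j] - conn.W_I_RA[i, j] * fI[j]
        d += -conn.w_g_RA * fg + conn.W_ps_RA[i] * fps + params.I_ext_1 + pulse_RA
        new_RA.append(max(state.r_RA[i] + params.dt / params.tau_E * d, 0.0))

        d = -state.r_X[i]
        for j in range(N):
            d += conn.W_RA_X[i, j] * fE_RA[j] - conn.W_I_X[i, j] * fI[j]
        d += -conn.w_g_X * fg + params.I_ext_2 + pulse_X
        new_X.append(max(state.r_X[i] + params.dt / params.tau_E * d, 0.0))

        d = -state.r_I[i]
        for j in range(N):
            d += conn.W_RA_I[i, j] * fE_RA[j] + conn.W_X_I[i, j] * fE_X[j]
        new_I.append(max(state.r_I[i] + params.dt / params.tau_I * d, 0.0))

    dg = -state.r_g + sum(conn.W_RA_g[j] * fE_RA[j] for j in range(N)) + sum(
        conn.W_X_g[j] * fE_X[j] for j in range(N)
    )
    dps = -state.r_ps + uva - conn.w_g_ps * fg
    new_g = max(state.r_g + params.dt / params.tau_g * dg, 0.0)
    new_ps = max(state.r_ps + params.dt / params.tau_ps * dps, 0.0)
    return new_RA, new_X, new_I, new_g, new_ps


class TestStep:
    def test_zero_state_is_fixed_point_without_drive(self, default_params):
        p = default_params
        conn = apply_boundary_compensation(build_connectivity(p), p)
        state = NetworkState.zeros(p.N)
        out = step(state, conn, p, InputProtocol(uva_drive=((0.0, 0.0),)))
        assert out.r_RA.sum() == 0 and out.r_X.sum() == 0 and out.r_I.sum() == 0
        assert out.r_g == 0 and out.r_ps == 0

    def test_matches_scalar_loop_oracle_n3(self):
        p = NetworkParameters(N=3, sigma=0.5)
        conn = apply_boundary_compensation(build_connectivity(p), p)
        rng = np.random.default_rng(0)
        state = NetworkState(
            r_RA=rng.uniform(0, 2, 3),
            r_X=rng.uniform(0, 2, 3),
            r_I=rng.uniform(0, 2, 3),
            r_g=0.7,
            r_ps=0.9,
            t=5.0,
        )
        proto = InputProtocol(
            uva_drive=((0.0, 1.0),),
            pulse_events=(PulseEvent("RA", 0.0, 10.0, 0.4),),
        )
        out = step(state, conn, p, proto)
        o_RA, o_X, o_I, o_g, o_ps = scalar_step_oracle(state, conn, p, 1.0, 0.4, 0.0)
        np.testing.assert_allclose(out.r_RA, o_RA, rtol=0, atol=1e-12)
        np.testing.assert_allclose(out.r_X, o_X, rtol=0, atol=1e-12)
        np.testing.assert_allclose(out.r_I, o_I, rtol=0, atol=1e-12)
        assert out.r_g == pytest.approx(o_g, abs=1e-12)
        assert out.r_ps == pytest.approx(o_ps, abs=1e-12)

    def test_fixed_point_preserved(self):
        # all couplings zero, pure leak to the external inputs
        p = NetworkParameters(N=4, sigma=0.5, I_ext_1=2.0, I_ext_2=1.5)
        for k in p.peak_weights:
            p.peak_weights[k] = 0.0
        conn = apply_boundary_compensation(build_connectivity(p), p)
        state = NetworkState(
            r_RA=np.full(4, 2.0), r_X=np.full(4, 1.5), r_I=np.zeros(4),
            r_g=0.0, r_ps=1.0, t=0.0,
        )
        out = step(state, conn, p, InputProtocol(uva_drive=((0.0, 1.0),)))
        assert np.max(np.abs(out.r_RA - state.r_RA)) < 1e-12
        assert np.max(np.abs(out.r_X - state.r_X)) < 1e-12
        assert abs(out.r_ps - state.r_ps) < 1e-12

    def test_dimension_mismatch_rejected(self, default_params, default_conn):
        with pytest.raises(ValueError, match="does not match"):
            step(NetworkState.zeros(7), default_conn, default_params, InputProtocol())


class TestSimulate:
    def test_no_drive_stays_silent(self, default_params, default_conn):
        proto = InputProtocol(uva_drive=((0.0, 0.0),))
        trace = simulate(default_params, default_conn, proto, 200.0, seed=0)
        assert trace.total_excitatory().max() == 0.0
        assert trace.r_ps.max() == 0.0

    def test_deterministic_without_noise(self, default_params, default_conn):
        proto = InputProtocol()
        a = simulate(default_params, default_conn, proto, 400.0, seed=1)
        b = simulate(default_params, default_conn, proto, 400.0, seed=2)
        assert np.array_equal(a.r_RA, b.r_RA)

    def test_deterministic_with_noise_given_seed(self, default_params, default_conn):
        proto = InputProtocol(noise_enabled=True)
        a = simulate(default_params, default_conn, proto, 500.0, seed=5)
        b = simulate(default_params, default_conn, proto, 500.0, seed=5)
        c = simulate(default_params, default_conn, proto, 500.0, seed=6)
        assert np.array_equal(a.r_RA, b.r_RA)
        assert not np.array_equal(a.r_RA, c.r_RA)

    def test_duration_shorter_than_step_rejected(self, default_params, default_conn):
        with pytest.raises(ValueError):
            simulate(default_params, default_conn, InputProtocol(), 0.01, seed=0)

    def test_blowup_reported(self):
        p = NetworkParameters(N=10, sigma=0.5)
        conn = apply_boundary_compensation(build_connectivity(p), p)
        state = NetworkState(
            r_RA=np.full(10, np.inf), r_X=np.full(10, 1.0), r_I=np.zeros(10),
            r_g=0.0, r_ps=0.0, t=0.0,
        )
        with pytest.raises(IntegrationBlowupError):
            simulate(p, conn, InputProtocol(), 10.0, seed=0, initial_state=state)

    def test_trace_roundtrip(self, tmp_path, default_params, default_conn):
        trace = simulate(default_params, default_conn, InputProtocol(), 50.0, seed=0)
        path = tmp_path / "trace.h5"
        trace.save(path)
        back = SimulationTrace.from_file(path)
        assert np.array_equal(back.r_RA, trace.r_RA)
        assert back.params_digest == trace.params_digest

    def test_dt_convergence_of_arrival_time(self, default_params):
        """Halving dt moves the bump's arrival at the chain end by < 5%."""
        arrivals = {}
        for dt in (0.1, 0.05):
            p = default_params.replace(dt=dt)
            conn = apply_boundary_compensation(build_connectivity(p), p)
            trace = simulate(p, conn, InputProtocol(), 1200.0, seed=0)
            track = track_bump(trace)
            k = np.flatnonzero(
                np.isfinite(track.position) & (track.position >= 0.9 * (p.N - 1))
            )
            assert k.size, f"bump never reached the end at dt={dt}"
            arrivals[dt] = float(track.times[k[0]])
        assert abs(arrivals[0.1] - arrivals[0.05]) / arrivals[0.05] < 0.05


class TestProtocol:
    def test_uva_schedule_lookup(self):
        proto = InputProtocol(uva_drive=((0.0, 1.0), (100.0, 0.0), (200.0, 0.5)))
        assert proto.uva_at(50.0) == 1.0
        assert proto.uva_at(150.0) == 0.0
        assert proto.uva_at(250.0) == 0.5

    def test_pulse_window_and_target(self):
        proto = InputProtocol(pulse_events=(PulseEvent("X", 10.0, 5.0, 2.0),))
        assert proto.pulse_at(12.0) == (0.0, 2.0)
        assert proto.pulse_at(15.0) == (0.0, 0.0)

    def test_invalid_pulse_target_rejected(self):
        from hvcseq import ConfigurationError

        with pytest.raises(ConfigurationError):
            PulseEvent("I", 0.0, 5.0, 1.0)

    def test_non_positive_duration_rejected(self):
        with pytest.raises(ValueError):
            PulseEvent("RA", 0.0, 0.0, 1.0)
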