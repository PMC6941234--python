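import math
import warnings
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fourpath.core import (
    PlasticityState,
    PresynEventTrain,
    VoltageTrace,
    advance_state,
    block_pathway,
    run_rule,
    update_weights,
)
from fourpath.params import PlasticityParams

DT = 0.025


def _run_stepwise(trace, events, params):
    s = PlasticityState.initial(params)
    counts = events.counts_on_grid(trace.t0, trace.dt, trace.n)
    for k in range(trace.n):
        s = advance_state(s, trace.samples[k], int(counts[k]), trace.dt,
                          params)
        s = update_weights(s, trace.dt, params)
    return s


class TestStateMachine:
    def test_stepwise_matches_vectorized(self, bump_trace, default_params):
        trace, events = bump_trace
        traj = run_rule(trace, events, default_params)
        s = _run_stepwise(trace, events, default_params)
        assert s.w_pre == pytest.approx(traj.final_w_pre, rel=1e-9, abs=1e-12)
        assert s.w_post == pytest.approx(traj.final_w_post, rel=1e-9)

    def test_subthreshold_voltage_gates_all_pathways(self, default_params):
        # resting voltage below every threshold: no change for any events
        trace = VoltageTrace.constant(-70.0, 300.0)
        events = PresynEventTrain(np.arange(10.0, 300.0, 25.0))
        traj = run_rule(trace, events, default_params, log_traces=True)
        for key in ("E", "X", "C", "P", "K"):
            assert np.all(traj.traces[key] == 0.0), key
        assert traj.final_w == default_params.w_pre_init \
            * default_params.w_post_init

    def test_no_events_gates_all_pathways(self, default_params):
        # strong depolarization but zero presynaptic events: no change
        t = np.arange(0, 200 + DT / 2, DT)
        u = -75 + 80 * np.exp(-((t - 100) / 15) ** 2)
        traj = run_rule(VoltageTrace(0.0, DT, u),
                        PresynEventTrain(np.array([])), default_params,
                        log_traces=True)
        for key in ("E", "X", "P", "K"):
            assert np.all(traj.traces[key] == 0.0), key
        assert np.all(traj.w == traj.w[0])

    def test_post_ltd_activation_peaks_at_one(self, default_params):
        # when C sits exactly between the two thresholds, P == 1
        p = default_params
        s = PlasticityState.initial(p)
        # preload the glutamate trace so G is saturated, then pick u so that
        # C = G * (u - theta_u_C) hits the midpoint of the band
        s.Gb, s.Ga = 30.0, 0.0
        g = math.tanh(p.b_G * 30.0)
        mid = 0.5 * (p.theta_C_minus + p.theta_C_plus)
        u = p.theta_u_C + mid / g
        out = advance_state(s, u, 0, DT, p)
        assert out.derived["P"] == pytest.approx(1.0, rel=1e-6)

    def test_event_decrement_matches_trace_value(self):
        # one event while T = 0.4 must change w_pre by exactly -A_preLTD * T
        p = PlasticityParams(a_pre_ltd=1.0, a_pre_ltp=0.0, a_post_ltd=0.0,
                             a_post_ltp=0.0)
        tbar = math.atanh(0.4) / p.b_T
        u = p.theta_u_T + tbar  # steady state of the T filter
        trace = VoltageTrace.constant(u, 400.0)
        events = PresynEventTrain(np.array([300.0]))
        traj = run_rule(trace, events, p, log_traces=True)
        k = int(round(300.0 / DT))
        assert traj.traces["T"][k] == pytest.approx(0.4, rel=1e-3)
        dw = traj.w_pre[k] - traj.w_pre[k - 1]
        assert dw == pytest.approx(-0.4, rel=1e-3)

    def test_update_weights_requires_advance(self, default_params):
        with pytest.raises(ValueError):
            update_weights(PlasticityState.initial(default_params), DT,
                           default_params)

    def test_invalid_inputs(self, default_params):
        s = PlasticityState.initial(default_params)
        with pytest.raises(ValueError):
            advance_state(s, float("nan"), 0, DT, default_params)
        with pytest.raises(ValueError):
            advance_state(s, -70.0, -1, DT, default_params)
        with pytest.raises(ValueError):
            advance_state(s, -70.0, 0, 0.0, default_params)
        with pytest.raises(ValueError):
            VoltageTrace(0.0, DT, np.array([]))


class TestRunRule:
    def test_deterministic(self, bump_trace, default_params):
        trace, events = bump_trace
        a = run_rule(trace, events, default_params)
        b = run_rule(trace, events, default_params)
        assert np.array_equal(a.w_pre, b.w_pre)
        assert np.array_equal(a.w_post, b.w_post)

    def test_events_outside_trace_warn_and_ignored(self, default_params):
        trace = VoltageTrace.constant(-70.0, 100.0)
        with pytest.warns(UserWarning, match="outside"):
            traj = run_rule(trace, PresynEventTrain(np.array([50.0, 500.0])),
                            default_params)
        assert traj.final_w == pytest.approx(1.0)

    def test_block_all_pathways_freezes_weights(self, bump_trace,
                                                default_params):
        trace, events = bump_trace
        p = default_params
        for pw in ("pre_ltd", "pre_ltp", "post_ltd", "post_ltp"):
            p = block_pathway(p, pw)
        traj = run_rule(trace, events, p)
        assert np.all(traj.w == traj.w[0])

    def test_block_unknown_pathway(self, default_params):
        with pytest.raises(ValueError):
            block_pathway(default_params, "ltd")

    def test_pathway_additivity_before_clipping(self, bump_trace):
        # Delta w of the full rule equals the sum of single-pathway runs
        trace, events = bump_trace
        p = PlasticityParams(a_pre_ltd=0.002, a_pre_ltp=0.05,
                             a_post_ltd=0.01, a_post_ltp=0.5)
        full = run_rule(trace, events, p, clip=False)
        dpre = dpost = 0.0
        for pw in ("pre_ltd", "pre_ltp", "post_ltd", "post_ltp"):
            iso = p
            for other in ("pre_ltd", "pre_ltp", "post_ltd", "post_ltp"):
                if other != pw:
                    iso = block_pathway(iso, other)
            t = run_rule(trace, events, iso, clip=False)
            dpre += t.final_w_pre - p.w_pre_init
            dpost += t.final_w_post - p.w_post_init
        assert full.final_w_pre - p.w_pre_init == pytest.approx(dpre,
                                                                abs=1e-12)
        assert full.final_w_post - p.w_post_init == pytest.approx(dpost,
                                                                  abs=1e-12)

    def test_dt_invariance_on_smooth_trace(self, default_params):
        # halving dt changes the final weights by < 0.1 % relative
        finals = []
        for dt in (0.025, 0.0125):
            t = np.arange(0, 250 + dt / 2, dt)
            u = (-70 + 30 * np.exp(-((t - 90) / 15) ** 2)
                 + 50 * np.exp(-((t - 110) / 5) ** 2))
            traj = run_rule(VoltageTrace(0.0, dt, u),
                            PresynEventTrain(np.array([85.0, 105.0])),
                            default_params)
            finals.append((traj.final_w_pre, traj.final_w_post))
        (p0, q0), (p1, q1) = finals
        assert abs(p1 - p0) / max(abs(p0), 1e-9) < 1e-3
        assert abs(q1 - q0) / max(abs(q0), 1e-9) < 1e-3

    def test_filter_oracle_against_ode_solver(self, default_params):
        # exponential-Euler voltage filters vs scipy's adaptive integrator
        from scipy.integrate import solve_ivp

        p = default_params
        dt = 0.025
        t = np.arange(0, 200 + dt / 2, dt)
        u = -70 + 45 * np.exp(-((t - 100) / 20) ** 2)
        traj = run_rule(VoltageTrace(0.0, dt, u),
                        PresynEventTrain(np.array([])), p, log_traces=True)

        def drive(tt):
            uu = -70 + 45 * np.exp(-((tt - 100) / 20) ** 2)
            return max(uu - p.theta_u_T, 0.0)

        sol = solve_ivp(lambda tt, y: (-y[0] + drive(tt)) / p.tau_T,
                        (0, 200), [0.0], t_eval=t, rtol=1e-8, atol=1e-10,
                        max_step=0.5)
        ref = np.tanh(p.b_T * sol.y[0])
        err = np.abs(traj.traces["T"] - ref) / ref.max()
        assert err.max() < 0.005


class TestInvariants:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_bounds_and_feedback(self, seed):
        """All tanh traces in [0,1), K_alpha + K_beta <= 1, weights within
        hard bounds, for random voltage excursions and event trains."""
        rng = np.random.default_rng(seed)
        dt = 0.05
        n = 4001
        t = dt * np.arange(n)
        u = np.full(n, -75.0)
        for _ in range(rng.integers(1, 5)):
            amp = rng.uniform(10, 120)
            width = rng.uniform(1, 30)
            u += amp * np.exp(-((t - rng.uniform(0, 200)) / width) ** 2)
        u = np.clip(u, -100, 50)
        ev = np.sort(rng.uniform(0, 200, rng.integers(0, 12)))
        p = PlasticityParams(a_pre_ltd=rng.uniform(0, 0.3),
                             a_pre_ltp=rng.uniform(0, 0.3),
                             a_post_ltd=rng.uniform(0, 0.3),
                             a_post_ltp=rng.uniform(0, 3.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            traj = run_rule(VoltageTrace(0.0, dt, u), PresynEventTrain(ev),
                            p, log_traces=True)
        tr = traj.traces
        # tanh keeps every trace below 1 mathematically; float64 rounds the
        # saturated tail to exactly 1.0
        for key in ("T", "Nalpha", "Nbeta", "Z", "G", "Kalpha", "Kbeta"):
            assert np.all(tr[key] >= 0.0) and np.all(tr[key] <= 1.0), key
        assert np.all(tr["Kalpha"] + tr["Kbeta"] <= 1.0 + 1e-12)
        assert np.all((traj.w_pre >= 0.0) & (traj.w_pre <= 1.0))
        assert np.all((traj.w_post >= 0.0) & (traj.w_post <= 5.0))

    def test_time_translation_invariance(self, default_params):
        # shifting voltage and events by a common offset leaves w unchanged
        dt = 0.025

        def run(shift):
            t = np.arange(0, 400 + dt / 2, dt)
            u = -75 + 60 * np.exp(-((t - 100 - shift) / 8) ** 2)
            return run_rule(
                VoltageTrace(0.0, dt, u),
                PresynEventTrain(np.array([95.0 + shift])),
                default_params).final_w

        assert run(0.0) == pytest.approx(run(50.0), rel=1e-9)
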