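"""Four-pathway plasticity rule as a step-wise state machine.

The rule watches two signals at a synapse: the local membrane potential
``u(t)`` and the train of presynaptic release events. Four coincidence
detectors convert them into pathway indicators:

* pre-LTD  ``E = D * T``: a presynaptic event sampling the low-passed
  supra-threshold voltage — detects post-before-pre order.
* pre-LTP  ``X = Z * N``: a slow presynaptic trace Z coinciding with a
  frequency-sensitive chain of two voltage filters N.
* post-LTD ``P``: quadratic activation of the glutamate/voltage coincidence
  C between two thresholds (the intermediate-calcium band).
* post-LTP ``K = Kalpha * Kbeta * Kgamma``: the portion of C above the upper
  threshold driving a three-stage cascade with negative feedback
  (``rho = 1 - Kbeta`` keeps ``Kalpha + Kbeta <= 1``).

The presynaptic weight factor w_pre (release efficacy, bounded [0, 1]) and
the postsynaptic factor w_post (receptor efficacy, bounded [0, 5]) integrate
the indicators; total weight is their product.

Two equivalent drivers exist: :func:`advance_state` advances one step at a
time (reference implementation, used in tests), while :func:`run_rule`
processes an entire voltage trace vectorized and is the fast path used by the
protocol layer. Both use per-trace exponential-Euler updates at fixed dt and
apply event jumps at the grid point of the event.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .params import (
    PATHWAYS,
    W_POST_BOUNDS,
    W_PRE_BOUNDS,
    PlasticityParams,
)

__all__ = [
    "VoltageTrace",
    "PresynEventTrain",
    "PlasticityState",
    "WeightTrajectory",
    "advance_state",
    "update_weights",
    "run_rule",
    "block_pathway",
]


@dataclass(frozen=True)
class VoltageTrace:
    """Uniformly sampled local membrane potential at a synapse site (mV)."""

    t0: float
    dt: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if not self.dt > 0.0:
            raise ValueError("dt must be > 0")
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("voltage samples must be finite")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def t_end(self) -> float:
        return self.t0 + (self.n - 1) * self.dt

    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)

    @classmethod
    def constant(cls, u: float, duration: float, dt: float = 0.025,
                 t0: float = 0.0) -> "VoltageTrace":
        n = int(round(duration / dt)) + 1
        return cls(t0, dt, np.full(n, float(u)))


@dataclass(frozen=True)
class PresynEventTrain:
    """Ordered times (ms) of presynaptic release events (delta pulses)."""

    event_times: np.ndarray

    def __post_init__(self) -> None:
        times = np.atleast_1d(np.asarray(self.event_times, dtype=float))
        object.__setattr__(self, "event_times", times)
        if times.size and (np.any(np.diff(times) < 0) or times[0] < 0):
            raise ValueError("event times must be non-decreasing and >= 0")

    @property
    def n(self) -> int:
        return self.event_times.size

    def counts_on_grid(self, t0: float, dt: float, n: int) -> np.ndarray:
        """Event counts per time step (events snapped to the nearest grid
        point); events outside the grid raise a warning and are dropped."""
        counts = np.zeros(n, dtype=float)
        if self.n == 0:
            return counts
        idx = np.round((self.event_times - t0) / dt).astype(int)
        inside = (idx >= 0) & (idx < n)
        if not np.all(inside):
            warnings.warn(
                f"{np.count_nonzero(~inside)} presynaptic events fall outside "
                "the voltage trace and are ignored",
                stacklevel=3,
            )
        np.add.at(counts, idx[inside], 1.0)
        return counts


@dataclass
class PlasticityState:
    """Stored filter states and weight factors of the rule at time ``t``."""

    t: float = 0.0
    Tbar: float = 0.0
    Nalphabar: float = 0.0
    Nbetabar: float = 0.0
    Za: float = 0.0
    Zb: float = 0.0
    Ga: float = 0.0
    Gb: float = 0.0
    Kbetabar: float = 0.0
    Kalpha_prev: float = 0.0
    Kgamma: float = 0.0
    w_pre: float = 0.5
    w_post: float = 2.0
    # derived values of the most recent step (diagnostics, not state)
    derived: dict = field(default_factory=dict)

    @classmethod
    def initial(cls, params: PlasticityParams, t: float = 0.0
                ) -> "PlasticityState":
        return cls(t=t, w_pre=params.w_pre_init, w_post=params.w_post_init)

    @property
    def w(self) -> float:
        return self.w_pre * self.w_post


def _decay(dt: float, tau: float) -> float:
    return math.exp(-dt / tau)


def advance_state(state: PlasticityState, u_t: float, events_in_step: int,
                  dt: float, params: PlasticityParams) -> PlasticityState:
    """Advance all traces by one step and compute the pathway indicators.

    Order within the step: apply event jumps to the Z/G components, advance
    the voltage-driven filters (exponential Euler with the current voltage
    sample as drive), advance the post-LTP cascade, then expose the derived
    indicators in ``state.derived``. Weights are *not* changed here; chain
    with :func:`update_weights`.
    """
    if not dt > 0.0:
        raise ValueError("dt must be > 0")
    if not np.isfinite(u_t):
        raise ValueError("voltage sample must be finite")
    if events_in_step < 0:
        raise ValueError("events_in_step must be >= 0")

    p = params
    s = replace(state)
    s.derived = {}

    # event jumps (normalized difference-of-exponentials kernels)
    _, eps_z = p.kernel_Z
    _, eps_g = p.kernel_G
    if events_in_step:
        s.Za = s.Za * _decay(dt, p.tau_Z_a) + eps_z * events_in_step
        s.Zb = s.Zb * _decay(dt, p.tau_Z_b) + eps_z * events_in_step
        s.Ga = s.Ga * _decay(dt, p.tau_G_a) + eps_g * events_in_step
        s.Gb = s.Gb * _decay(dt, p.tau_G_b) + eps_g * events_in_step
    else:
        s.Za *= _decay(dt, p.tau_Z_a)
        s.Zb *= _decay(dt, p.tau_Z_b)
        s.Ga *= _decay(dt, p.tau_G_a)
        s.Gb *= _decay(dt, p.tau_G_b)

    # voltage-driven filters
    aT = _decay(dt, p.tau_T)
    s.Tbar = aT * s.Tbar + (1.0 - aT) * max(u_t - p.theta_u_T, 0.0)
    aNa = _decay(dt, p.tau_N_alpha)
    s.Nalphabar = aNa * s.Nalphabar + (1.0 - aNa) * max(u_t - p.theta_u_N, 0.0)
    aNb = _decay(dt, p.tau_N_beta)
    s.Nbetabar = aNb * s.Nbetabar + (1.0 - aNb) * s.Nalphabar

    # derived traces
    T = math.tanh(p.b_T * s.Tbar)
    Nalpha = math.tanh(p.b_N_alpha * s.Nalphabar)
    Nbeta = math.tanh(p.b_N_beta * s.Nbetabar)
    N = max(Nalpha * Nbeta - p.theta_N, 0.0)
    Z = math.tanh(p.b_Z * (s.Zb - s.Za))
    G = math.tanh(p.b_G * (s.Gb - s.Ga))
    C = G * max(u_t - p.theta_u_C, 0.0)
    P = (max(C - p.theta_C_minus, 0.0) * max(p.theta_C_plus - C, 0.0)
         / p.p_norm)
    X = Z * N
    E = float(events_in_step) * T

    # post-LTP cascade: Kbeta first (from the previous Kalpha), then the
    # negative feedback rho, then the new Kalpha — guarantees
    # Kalpha + Kbeta <= 1 at every step.
    aKb = _decay(dt, p.tau_K_beta)
    s.Kbetabar = aKb * s.Kbetabar + (1.0 - aKb) * s.Kalpha_prev
    Kbeta = math.tanh(p.b_K_beta * p.s_K_beta * s.Kbetabar)
    rho = 1.0 - Kbeta
    Kalpha = math.tanh(p.b_K_alpha * max(C - p.theta_C_plus, 0.0)) * rho
    aKg = _decay(dt, p.tau_K_gamma)
    s.Kgamma = aKg * s.Kgamma + (1.0 - aKg) * Kbeta
    K = Kalpha * Kbeta * s.Kgamma
    s.Kalpha_prev = Kalpha

    s.t = state.t + dt
    s.derived = dict(
        T=T, Nalpha=Nalpha, Nbeta=Nbeta, N=N, Z=Z, G=G, C=C, P=P, X=X, E=E,
        Kalpha=Kalpha, Kbeta=Kbeta, Kgamma=s.Kgamma, K=K, rho=rho,
        events=float(events_in_step),
    )
    return s


def update_weights(state: PlasticityState, dt: float,
                   params: PlasticityParams, clip: bool = True
                   ) -> PlasticityState:
    """Apply the weight updates for the indicators computed in the current
    step and (optionally) clip to the hard bounds.

    The pre-LTD term is event-based (no ``eta``, no ``dt``): each event
    decrements w_pre by ``a_pre_ltd * T``. The three integrated pathways
    scale with ``eta * dt``.
    """
    d = state.derived
    if not d:
        raise ValueError("advance_state must run before update_weights")
    p = params
    s = replace(state)
    s.w_pre = (state.w_pre
               - p.a_pre_ltd * d["E"]
               + p.a_pre_ltp * d["X"] * p.eta * dt)
    s.w_post = (state.w_post
                + (-p.a_post_ltd * d["P"] + p.a_post_ltp * d["K"])
                * p.eta * dt)
    if clip:
        s.w_pre = min(max(s.w_pre, W_PRE_BOUNDS[0]), W_PRE_BOUNDS[1])
        s.w_post = min(max(s.w_post, W_POST_BOUNDS[0]), W_POST_BOUNDS[1])
    return s


def block_pathway(params: PlasticityParams, pathway: str) -> PlasticityParams:
    """Return a copy of ``params`` with one pathway's amplitude zeroed."""
    if pathway not in PATHWAYS:
        raise ValueError(f"unknown pathway {pathway!r}; one of {PATHWAYS}")
    return params.block(pathway)


@dataclass(frozen=True)
class WeightTrajectory:
    """Per-step weight factors plus (optionally) the full trace log."""

    t: np.ndarray
    w_pre: np.ndarray
    w_post: np.ndarray
    traces: dict | None = None

    @property
    def w(self) -> np.ndarray:
        return self.w_pre * self.w_post

    @property
    def final_w_pre(self) -> float:
        return float(self.w_pre[-1])

    @property
    def final_w_post(self) -> float:
        return float(self.w_post[-1])

    @property
    def final_w(self) -> float:
        return float(self.w_pre[-1] * self.w_post[-1])


def _first_order(drive: np.ndarray, dt: float, tau: float) -> np.ndarray:
    """Exponential-Euler low-pass: x[k] = a x[k-1] + (1-a) drive[k]."""
    a = math.exp(-dt / tau)
    return lfilter([1.0 - a], [1.0, -a], drive)


def _event_component(ev: np.ndarray, dt: float, tau: float,
                     eps: float) -> np.ndarray:
    """Event-jump exponential: x[k] = a x[k-1] + eps * ev[k]."""
    a = math.exp(-dt / tau)
    return lfilter([eps], [1.0, -a], ev)


def _kchain_and_weights(cplus, E_step, X, P, dt, p):
    """Sequential part of the rule: post-LTP cascade and weight updates.

    ``cplus`` is ``[C - theta_C_plus]+`` per step, ``E_step`` the event-based
    pre-LTD decrement per step. Returns the K traces and the clipped weight
    trajectories.
    """
    n = cplus.size
    aKb = math.exp(-dt / p.tau_K_beta)
    aKg = math.exp(-dt / p.tau_K_gamma)
    bKa, bKb_s = p.b_K_alpha, p.b_K_beta * p.s_K_beta
    eta_dt = p.eta * dt
    g_ltp = p.a_pre_ltp * eta_dt
    g_pltd = p.a_post_ltd * eta_dt
    g_pltp = p.a_post_ltp * eta_dt

    Kalpha = np.empty(n)
    Kbeta = np.empty(n)
    Kgamma = np.empty(n)
    w_pre = np.empty(n)
    w_post = np.empty(n)

    kbb = 0.0   # Kbetabar
    ka_prev = 0.0
    kg = 0.0
    wpre = p.w_pre_init
    wpost = p.w_post_init
    lo_pre, hi_pre = W_PRE_BOUNDS
    lo_post, hi_post = W_POST_BOUNDS
    tanh = math.tanh
    for k in range(n):
        kbb = aKb * kbb + (1.0 - aKb) * ka_prev
        kb = tanh(bKb_s * kbb)
        ka = tanh(bKa * cplus[k]) * (1.0 - kb)
        kg = aKg * kg + (1.0 - aKg) * kb
        ka_prev = ka
        Kalpha[k] = ka
        Kbeta[k] = kb
        Kgamma[k] = kg

        wpre += -p.a_pre_ltd * E_step[k] + g_ltp * X[k]
        wpost += -g_pltd * P[k] + g_pltp * ka * kb * kg
        if wpre < lo_pre:
            wpre = lo_pre
        elif wpre > hi_pre:
            wpre = hi_pre
        if wpost < lo_post:
            wpost = lo_post
        elif wpost > hi_post:
            wpost = hi_post
        w_pre[k] = wpre
        w_post[k] = wpost
    return Kalpha, Kbeta, Kgamma, w_pre, w_post


def _kchain_jit_body(cplus, E_step, X, P, aKb, aKg, bKa, bKb_s, a_pre_ltd,
                     g_ltp, g_pltd, g_pltp, w0, w1):
    n = cplus.size
    Kalpha = np.empty(n)
    Kbeta = np.empty(n)
    Kgamma = np.empty(n)
    w_pre = np.empty(n)
    w_post = np.empty(n)
    kbb = 0.0
    ka_prev = 0.0
    kg = 0.0
    wpre = w0
    wpost = w1
    for k in range(n):
        kbb = aKb * kbb + (1.0 - aKb) * ka_prev
        kb = math.tanh(bKb_s * kbb)
        ka = math.tanh(bKa * cplus[k]) * (1.0 - kb)
        kg = aKg * kg + (1.0 - aKg) * kb
        ka_prev = ka
        Kalpha[k] = ka
        Kbeta[k] = kb
        Kgamma[k] = kg
        wpre += -a_pre_ltd * E_step[k] + g_ltp * X[k]
        wpost += -g_pltd * P[k] + g_pltp * ka * kb * kg
        if wpre < 0.0:
            wpre = 0.0
        elif wpre > 1.0:
            wpre = 1.0
        if wpost < 0.0:
            wpost = 0.0
        elif wpost > 5.0:
            wpost = 5.0
        w_pre[k] = wpre
        w_post[k] = wpost
    return Kalpha, Kbeta, Kgamma, w_pre, w_post


try:  # optional compiled fast path; semantics identical to the python loop
    from numba import njit as _njit

    _kchain_numba = _njit(cache=False)(_kchain_jit_body)
except Exception:  # pragma: no cover
    _kchain_numba = None


def run_rule(voltage: VoltageTrace, events: PresynEventTrain,
             params: PlasticityParams, log_traces: bool = False,
             clip: bool = True) -> WeightTrajectory:
    """Run the plasticity rule over a full voltage trace.

    Deterministic given its inputs; weights start from the initial values in
    ``params``. With ``clip=False`` the hard weight bounds are not enforced
    (used to verify pathway additivity).
    """
    p = params
    u = voltage.samples
    dt = voltage.dt
    n = u.size
    ev = events.counts_on_grid(voltage.t0, dt, n)

    # linear filters, fully vectorized
    Tbar = _first_order(np.maximum(u - p.theta_u_T, 0.0), dt, p.tau_T)
    Nabar = _first_order(np.maximum(u - p.theta_u_N, 0.0), dt, p.tau_N_alpha)
    Nbbar = _first_order(Nabar, dt, p.tau_N_beta)
    _, eps_z = p.kernel_Z
    _, eps_g = p.kernel_G
    Za = _event_component(ev, dt, p.tau_Z_a, eps_z)
    Zb = _event_component(ev, dt, p.tau_Z_b, eps_z)
    Ga = _event_component(ev, dt, p.tau_G_a, eps_g)
    Gb = _event_component(ev, dt, p.tau_G_b, eps_g)

    T = np.tanh(p.b_T * Tbar)
    Nalpha = np.tanh(p.b_N_alpha * Nabar)
    Nbeta = np.tanh(p.b_N_beta * Nbbar)
    N = np.maximum(Nalpha * Nbeta - p.theta_N, 0.0)
    Z = np.tanh(p.b_Z * (Zb - Za))
    G = np.tanh(p.b_G * (Gb - Ga))
    C = G * np.maximum(u - p.theta_u_C, 0.0)
    P = (np.maximum(C - p.theta_C_minus, 0.0)
         * np.maximum(p.theta_C_plus - C, 0.0) / p.p_norm)
    X = Z * N
    E_step = ev * T
    cplus = np.maximum(C - p.theta_C_plus, 0.0)

    if not clip:
        Kalpha, Kbeta, Kgamma, w_pre, w_post = _kchain_and_weights_noclip(
            cplus, E_step, X, P, dt, p)
    elif _kchain_numba is not None:
        aKb = math.exp(-dt / p.tau_K_beta)
        aKg = math.exp(-dt / p.tau_K_gamma)
        Kalpha, Kbeta, Kgamma, w_pre, w_post = _kchain_numba(
            cplus, E_step, X, P, aKb, aKg, p.b_K_alpha,
            p.b_K_beta * p.s_K_beta, p.a_pre_ltd, p.a_pre_ltp * p.eta * dt,
            p.a_post_ltd * p.eta * dt, p.a_post_ltp * p.eta * dt,
            p.w_pre_init, p.w_post_init)
    else:
        Kalpha, Kbeta, Kgamma, w_pre, w_post = _kchain_and_weights(
            cplus, E_step, X, P, dt, p)

    traces = None
    if log_traces:
        K = Kalpha * Kbeta * Kgamma
        traces = dict(u=u, events=ev, T=T, Nalpha=Nalpha, Nbeta=Nbeta, N=N,
                      Z=Z, G=G, C=C, P=P, X=X, E=E_step, Kalpha=Kalpha,
                      Kbeta=Kbeta, Kgamma=Kgamma, K=K)
    return WeightTrajectory(t=voltage.times(), w_pre=w_pre, w_post=w_post,
                            traces=traces)


def _kchain_and_weights_noclip(cplus, E_step, X, P, dt, p):
    """As :func:`_kchain_and_weights` but without the hard weight bounds.

    The K cascade does not depend on the weights, so the weight integrals
    become plain cumulative sums."""
    n = cplus.size
    aKb = math.exp(-dt / p.tau_K_beta)
    aKg = math.exp(-dt / p.tau_K_gamma)
    if _kchain_numba is not None:
        Kalpha, Kbeta, Kgamma, _, _ = _kchain_numba(
            cplus, E_step, X, P, aKb, aKg, p.b_K_alpha,
            p.b_K_beta * p.s_K_beta, 0.0, 0.0, 0.0, 0.0,
            p.w_pre_init, p.w_post_init)
    else:
        Kalpha, Kbeta, Kgamma, _, _ = _kchain_and_weights(
            cplus, E_step, np.zeros(n), np.zeros(n), dt,
            replace_amplitudes_zero(p))
    eta_dt = p.eta * dt
    K = Kalpha * Kbeta * Kgamma
    w_pre = p.w_pre_init + np.cumsum(
        -p.a_pre_ltd * E_step + p.a_pre_ltp * eta_dt * X)
    w_post = p.w_post_init + np.cumsum(
        (-p.a_post_ltd * P + p.a_post_ltp * K) * eta_dt)
    return Kalpha, Kbeta, Kgamma, w_pre, w_post


def replace_amplitudes_zero(p: PlasticityParams) -> PlasticityParams:
    from dataclasses import replace as _replace
    return _replace(p, a_pre_ltd=0.0, a_pre_ltp=0.0, a_post_ltd=0.0,
                    a_post_ltp=0.0)
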