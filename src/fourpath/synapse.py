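"""AMPA/NMDA synaptic conductances coupled to the plasticity weights.

The AMPA limb is a normalized difference of exponentials scaled by the
*current* postsynaptic weight factor; the NMDA limb reuses the glutamate
trace G of the plasticity rule, is gated by the voltage-dependent Mg2+
block, and is deliberately scaled by the *initial* postsynaptic weight —
only the AMPA limb and the presynaptic factor feed learning back into the
electrical response within a simulation.

Sign convention: ``I_syn = g_syn * (V - E_syn)`` is positive outward; the
neuron model injects ``-I_syn`` into the compartment, so an event at
``V < E_syn`` depolarizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import PresynEventTrain, VoltageTrace
from .params import PlasticityParams, SynapseParams, double_exp_kernel

__all__ = ["SynapseState", "mg_block", "synapse_step", "run_synapse"]


def mg_block(u, slope: float = 0.08, scale: float = 3.57):
    """Voltage-dependent Mg2+ unblock factor of the NMDA conductance.

    ``1 / (1 + exp(-slope*u)/scale)``, strictly increasing in ``u``, with
    limits 0 and 1. Accepts scalars or arrays.
    """
    from scipy.special import expit

    u = np.asarray(u, dtype=float)
    # algebraically 1/(1 + exp(-slope*u)/scale); expit form avoids overflow
    out = expit(slope * u + math.log(scale))
    return float(out) if out.ndim == 0 else out


@dataclass
class SynapseState:
    """AMPA kernel components (nS) plus the shared NMDA gating trace G."""

    gA_a: float = 0.0
    gA_b: float = 0.0
    G_a: float = 0.0
    G_b: float = 0.0

    def g_trace(self, b_G: float) -> float:
        return math.tanh(b_G * (self.G_b - self.G_a))


def synapse_step(state: SynapseState, event: int, u: float, dt: float,
                 w_pre: float, w_post: float, w_post_init: float,
                 params: SynapseParams,
                 plasticity: PlasticityParams | None = None,
                 ) -> tuple[float, float]:
    """Advance the synapse one step; returns ``(g_syn nS, I_syn nA)``.

    ``u`` is the local membrane potential (mV) driving the Mg2+ block and
    the driving force. ``plasticity`` supplies the saturation slope and time
    constants of the shared glutamate trace G (defaults used if omitted).
    """
    if not dt > 0.0:
        raise ValueError("dt must be > 0")
    sp = params
    _, eps_a = sp.kernel_ampa
    if plasticity is not None:
        tau_ga, tau_gb = plasticity.tau_G_a, plasticity.tau_G_b
        b_G = plasticity.b_G
    else:
        tau_ga, tau_gb = sp.tau_nmda_a, sp.tau_nmda_b
        b_G = 0.5 * math.log(10.0)
    _, eps_g = double_exp_kernel(tau_ga, tau_gb)

    state.gA_a = state.gA_a * math.exp(-dt / sp.tau_ampa_a) \
        + eps_a * event * sp.g_max
    state.gA_b = state.gA_b * math.exp(-dt / sp.tau_ampa_b) \
        + eps_a * event * sp.g_max
    state.G_a = state.G_a * math.exp(-dt / tau_ga) + eps_g * event
    state.G_b = state.G_b * math.exp(-dt / tau_gb) + eps_g * event

    g_ampa = sp.s_ampa * w_post * (state.gA_b - state.gA_a)
    g_nmda = (sp.s_nmda * w_post_init * state.g_trace(b_G) * sp.g_max
              * mg_block(u, sp.mg_slope, sp.mg_scale))
    g_syn = w_pre * (g_ampa + g_nmda)
    assert g_syn >= 0.0, "negative synaptic conductance"
    i_syn = g_syn * (u - sp.e_syn) * 1e-3  # nS * mV -> nA
    return g_syn, i_syn


def run_synapse(voltage: VoltageTrace, events: PresynEventTrain,
                params: SynapseParams, w_pre: float, w_post: float,
                w_post_init: float | None = None,
                plasticity: PlasticityParams | None = None) -> dict:
    """Vectorized synapse response to a voltage trace and event train.

    Weights are held fixed over the trace (one-sweep quasi-static coupling).
    Returns arrays ``g_ampa``, ``g_nmda``, ``g_syn`` (nS) and ``i_syn``
    (nA, positive outward).
    """
    from scipy.signal import lfilter

    if w_post_init is None:
        w_post_init = w_post
    sp = params
    dt = voltage.dt
    u = voltage.samples
    ev = events.counts_on_grid(voltage.t0, dt, u.size)
    _, eps_a = sp.kernel_ampa
    if plasticity is not None:
        tau_ga, tau_gb, b_G = (plasticity.tau_G_a, plasticity.tau_G_b,
                               plasticity.b_G)
    else:
        tau_ga, tau_gb = sp.tau_nmda_a, sp.tau_nmda_b
        b_G = 0.5 * math.log(10.0)
    _, eps_g = double_exp_kernel(tau_ga, tau_gb)

    def comp(tau, eps, scale=1.0):
        a = math.exp(-dt / tau)
        return lfilter([eps * scale], [1.0, -a], ev)

    gA = comp(sp.tau_ampa_b, eps_a, sp.g_max) \
        - comp(sp.tau_ampa_a, eps_a, sp.g_max)
    G = np.tanh(b_G * (comp(tau_gb, eps_g) - comp(tau_ga, eps_g)))
    g_ampa = sp.s_ampa * w_post * gA
    g_nmda = (sp.s_nmda * w_post_init * G * sp.g_max
              * mg_block(u, sp.mg_slope, sp.mg_scale))
    g_syn = w_pre * (g_ampa + g_nmda)
    return dict(g_ampa=g_ampa, g_nmda=g_nmda, g_syn=g_syn,
                i_syn=g_syn * (u - sp.e_syn) * 1e-3, G=G)
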