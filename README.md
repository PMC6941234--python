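# fourpath

A simulator for voltage-dependent long-term synaptic plasticity in
dendrites. Four phenomenological signaling pathways — presynaptically and
postsynaptically expressed LTD and LTP — read the *local* membrane
potential at a synapse together with the presynaptic release times, so that
one fixed rule reproduces rate-, timing- **and** location-dependent
plasticity once it is embedded in a dendritic tree. The package bundles the
plasticity rule, an AMPA/NMDA synapse model, a reduced compartmental
pyramidal-neuron model with phenomenological backpropagating APs, dendritic
Ca²⁺ plateaus and NMDA-spike-like events, and the standard stimulation
protocols (voltage clamp, burst pairing, burst-timing patterns,
dendritic-spike pairing, subthreshold cluster activation, random basal/tuft
drive, heterosynaptic cluster interactions).

It is written for computational neuroscientists who want to explore how
classical STDP, calcium-threshold rules and dendritic spikes fit together,
without carrying a full biophysically detailed cell model around.

## The rule

Local voltage `u(t)` (mV) and the presynaptic event train
`D(t) = Σ_i δ(t − t_i)` drive four coincidence detectors:

* **pre-LTD** `E = D · T` — `T = tanh(b_T · T̄)`, where `T̄` low-passes the
  suprathreshold voltage `[u − θ_u^T]₊` (τ_T). An event arriving while the
  dendrite was recently depolarized (post-before-pre) depresses the
  presynaptic weight: `Δw_pre = −A_preLTD · T` per event.
* **pre-LTP** `X = Z · N` — `Z` is a slow normalized
  difference-of-exponentials event trace (τ_Za, τ_Zb); `N = [N_α · N_β − θ_N]₊`
  chains two voltage filters so that only *repeated* postsynaptic
  depolarization (bursts at ≥10 Hz) opens the pathway.
* **post-LTD** `P` — the glutamate trace `G` (like `Z`, with τ_Ga = 2 ms,
  τ_Gb = 50 ms) times suprathreshold voltage gives the calcium-like
  coincidence `C = G · [u − θ_u^C]₊`; `P` is a quadratic bump of `C`
  between `θ_C⁻` and `θ_C⁺`, normalized to peak at 1 — the intermediate-
  calcium band of classical calcium-threshold rules.
* **post-LTP** `K = K_α K_β K_γ` — the portion of `C` above `θ_C⁺` drives a
  three-stage cascade (CaMKII-like) with negative feedback
  `ρ = 1 − K_β`, so `K_α + K_β ≤ 1` and `K` requires sustained or rapidly
  repeated high-calcium episodes.

Weights integrate the indicators
(`ẇ_pre = −A_preLTD·E + A_preLTP·X·η`,
`ẇ_post = (−A_postLTD·P + A_postLTP·K)·η`, η = 0.025 ms⁻¹) with hard
bounds `w_pre ∈ [0,1]`, `w_post ∈ [0,5]`; the synaptic weight is
`w = w_pre · w_post`, initialized at `0.5 × 2 = 1`. Repetitive protocols
simulate one sweep and extrapolate
`w_final = clip(w_pre,init + n·Δw_pre) · clip(w_post,init + n·Δw_post)`.

The synapse feeds back into the electrical model through
`g_AMPA = s_AMPA · w_post · g_max · (kernel)` and
`g_NMDA = s_NMDA · w_post,init · G · g_max / (1 + e^(−0.08u)/3.57)`
(the last factor is the Mg²⁺ block), with
`I_syn = w_pre (g_AMPA + g_NMDA)(V − E_syn)`.

Three calibrated parameter sets ship with the package (`set1`–`set3`,
shared kinetics, per-set pathway amplitudes); see `docs/methods.md` for
values and calibration targets.

## Worked example

```python
from fourpath.protocols import voltage_clamp_experiment, clamp_band_edges, \
    burst_pairing_experiment

scan = voltage_clamp_experiment("set1")          # 61 clamps, 10 sweeps each
print(clamp_band_edges(scan))
# (-60.0, -26.461729286608925)   # mV: no change below -60, LTD band,
#                                # LTP above ~-26

for f in (0.1, 10, 30, 50):
    r = burst_pairing_experiment(f, dt_ms=-10.0, site_um=90.0)
    print(f"{f:5.1f} Hz post-pre at 90 um: r = {r:.2f}")
#   0.1 Hz post-pre at 90 um: r = 0.73
#  10.0 Hz post-pre at 90 um: r = 0.72
#  30.0 Hz post-pre at 90 um: r = 1.10
#  50.0 Hz post-pre at 90 um: r = 1.83
```

`r` is the relative weight change (1.0 = no change). The first call shows
the voltage-clamp band structure of the rule itself; the second shows the
frequency switch of post-pre burst pairing at a proximal apical synapse
(depression at low rates, potentiation above ~27 Hz), which emerges from
trace summation — not from any explicit frequency parameter.

The same protocols are available from the shell, e.g.
`fourpath vclamp --out scan.csv` or
`fourpath burst-pairing --frequency 50 --timing -10 --site 90`.

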