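# Methods

## Model overview

The plasticity rule treats a synapse as four parallel coincidence
detectors that read two signals: the local membrane potential `u(t)` at the
synapse (mV, used as a bare number) and the presynaptic release times
(delta pulses). Every internal trace is a first-order filter advanced by
exponential Euler at a fixed step, and every saturation is
`tanh(b·x)` with `b = ln(m)/2`, so the saturation parameter `m > 1`
directly sets `tanh(b·1) = (m−1)/(m+1)`. Presynaptic event traces (`Z`,
`G`, and the AMPA conductance kernel) are differences of two exponentials;
an isolated event produces a kernel that peaks at exactly 1 at
`ω = τ_a τ_b/(τ_b−τ_a) · ln(τ_b/τ_a)`, which fixes the event-jump size
`ε = 1/(e^(−ω/τ_b) − e^(−ω/τ_a))`. The jump is applied to both exponential
components directly at the event's grid point.

Pathway indicators and weight updates are described in the README. Two
discrete-time choices matter:

* Within a step the order is: apply event jumps → advance filters (current
  voltage sample as drive) → compute derived traces → update weights →
  clip to the hard bounds.
* In the post-LTP cascade, `K_β` is computed from the *previous* step's
  `K_α` before the feedback `ρ = 1 − K_β` gates the new
  `K_α = tanh(b_Kα·[C−θ_C⁺]₊)·ρ`. This ordering makes `K_α + K_β ≤ 1` hold
  exactly at every step rather than up to an O(dt) error.

The pre-LTD pathway is event-based (each event decrements `w_pre` by
`A_preLTD·T` with no `η` or `dt` factor) and is therefore exactly invariant
to the integration step; the three integrated pathways carry `η·dt`
(η = 0.025 ms⁻¹) for the same reason. Halving the step from the default
dt = 0.025 ms changes final weights by well under 0.1 % on smooth inputs
(tested).

Two equivalent drivers exist: a per-step reference implementation
(`advance_state`/`update_weights`) and a vectorized fast path (`run_rule`)
that evaluates all linear filters with IIR filtering and runs only the
nonlinear cascade and the clipped weight integration sequentially (compiled
with numba when available, plain Python otherwise). Both produce identical
trajectories; the tests assert this.

## Reduced neuron model

The published experiments used a biophysically detailed layer-5b pyramidal
cell; this package deliberately replaces it with a reduced model, so the
detailed cell's quantitative behaviors are treated as calibration targets
rather than emergent guarantees. The reduced cell is a passive
compartmental tree (~170 compartments, ~25,000 µm² membrane): soma
(35×35 µm), an axon stub, a tapering apical trunk (600 µm, 5→2.5 µm) with
three thin oblique branches, two thin tuft branches extending the apical
path to ~1,190 µm (tapering to 0.35 µm for a steep input-resistance
gradient), and eight basal branches (250 µm). Passive constants:
Cm = 1 µF/cm², Rm = 15 kΩ·cm², Ra = 150 Ω·cm, E_rest = −75 mV. The apical
membrane carries a distance-dependent leak (factor
`1 + 8·(min(x,700)/1200)²`), a stand-in for the h-type conductance gradient
of these cells; without it, slow charge injected at the soma spreads far
too effectively into the distal apical dendrite of a purely passive tree.

The cable is integrated implicitly (prefactorized sparse LU,
unconditionally stable); time-varying local conductances (synapses, boost)
are handled by an exponentially exact local sub-step, so arbitrarily strong
synapses on sub-µm branches remain stable at dt = 0.025 ms.

Active events are phenomenological:

* **Axo-somatic APs** fire when the somatic potential crosses −53 mV from
  below (refractory 6 ms) or are forced by the protocols' somatic step
  currents (5 ms @ 2.7 nA, 5 ms @ 2.1 nA, 2 ms @ 5.5 nA presets). Each AP
  injects a **bAP template** along the whole tree: peak 100 mV above rest
  at the soma, exponential attenuation with λ = 220 µm, width
  2·(1 + x/400 µm) ms, conduction 500 µm/ms. Composed voltages are clipped
  to [−100, +50] mV.
* A **Ca²⁺-spike zone** at 600 µm integrates fast local depolarization
  (bAP templates weighted ×3 plus the synaptically driven cable component
  ×0.25, low-passed with τ = 12 ms) and fires a plateau (50 mV at the
  zone, ~40 ms, attenuating steeply toward the soma and mildly into the
  tuft) when the trigger crosses 9.5 mV. Slow somatic-injection charge and
  the boost current are excluded from the trigger — with the detailed
  cell's active conductances that charge never reaches the nexus, and
  including it would make the trigger frequency-blind. Calibrated so that
  three APs at 200 Hz fire the plateau ~20 ms after the first AP while
  five APs at ≤50 Hz never do.
* Thin apical branches (diameter ≤ 1.3 µm) carry a **boost conductance**
  (3 mS/cm², reversal +10 mV) with fast activation above −25 mV and slow
  (40 ms) inactivation: strong local input ignites a self-terminating
  plateau, the reduced model's counterpart of dendritic Na⁺/Ca²⁺
  electrogenesis and the substrate of NMDA-spike-like events. The
  channel-block mode (used by the cluster protocol) disables both the
  boost and the Ca²⁺ zone.

Within one sweep the voltage is simulated with synaptic weights frozen at
their sweep-initial values and the plasticity rule is then evaluated on the
recorded local voltage (quasi-static coupling). Per-sweep weight changes
are small, and the NMDA conductance is pinned to the initial postsynaptic
weight by design, so the approximation is second order in the per-sweep
change.

## Protocols

Each preset binds the printed stimulus numbers (step currents, sweep
counts, synapse conductances, sites). Sweeps are simulated singly from a
reset state; `n` repetitions are extrapolated linearly in each weight
factor with clipping before the product. The timing convention is
`Δt > 0` ⇔ presynaptic event leads the first step current. Two
protocol-level shortcuts:

* At 0.1 Hz intra-burst frequency the five pre/post pairs of one sweep are
  ≥10 s apart while the slowest trace decays with τ = 150 ms, so one pair
  is simulated and the repetition count absorbs the factor five
  (10 sweeps × 5 pairs = 50 pair repetitions). Exact up to clipping.
* The spatiotemporal window (41 apical sites × 101 timings = 4,141 rule
  evaluations) reuses a single stimulus-evoked voltage profile per site
  plus a per-site single-event EPSP template, superposed at each timing.
  The synaptic contribution is small against bAP/plateau depolarization in
  these stimuli, making the superposition error negligible for the map.

Stochastic protocols draw per-synapse event trains from per-synapse
substreams of a single seed (Poisson per time bin, or the 8 Hz sinusoidal
per-millisecond activation probability `max(0, 0.005 + 0.05·sin)` for
synchronized clusters), so runs are bit-reproducible and adding a synapse
does not perturb the others' draws.

## Parameter sets

The three shipped sets share all kinetics, thresholds and slopes and
differ only in the four pathway amplitudes, mirroring the two-stage fit:
stage 1 adjusted the shared constants against qualitative targets, stage 2
tuned amplitudes per protocol family. The calibration module mechanizes
this as deterministic coordinate descent; the shipped values were selected
against these targets:

* shared kinetics — clamp band edges (no change ≤ −60 mV from
  θ_u^T = −60; depression→potentiation crossover near −28 mV, set by the
  pre-LTP product threshold θ_N = 0.75 with θ_u^N = −31 mV); burst
  selectivity (a single pre/post pair must not open pre-LTP: its N-product
  stays ≈0.67 < θ_N, while bursts ≥10 Hz saturate it); the post-LTD band
  θ_C⁻ = 15, θ_C⁺ = 35 with θ_u^C = −72 mV keeps post pathways silent
  below −53 mV, making post-LTD require more depolarization than pre-LTD.
* set 1 (clamp + burst pairing): A = (0.00273, 0.0434, 0.000123, 1.094)
  for (pre-LTD, pre-LTP, post-LTD, post-LTP); places the post-pre
  frequency crossover at ~27 Hz and keeps 0.1 Hz pairing neutral.
* set 2 (burst-timing patterns): A = (0.00394, 0.00034, 0.0000454, 1.584);
  changes are carried almost entirely by pre-LTD and post-LTP.
* set 3 (dendritic spikes, clusters, background drive):
  A = (0.00214, 0.01348, 0.01832, 0.362); post-LTD is relatively stronger
  so that long plateau depolarization in the intermediate-calcium band
  produces the distal pre-post depression, yet still an order of magnitude
  below post-LTP.

In every set the post-LTD amplitude is small against post-LTP: brief APs
then induce negligible depression even at delayed pre-post timings, while
long plateaus integrate appreciable amounts — the duration-based reading
of calcium-threshold rules.

## What the synthetic data does and does not show

The fixture generator and the reduced neuron emulate the *structure* of the
signals the rule consumes — attenuating bAPs, delayed long plateaus,
EPSP-like bumps, Poisson and sinusoidally modulated trains — not the
detailed cell's quantitative voltage landscape. Passing tests therefore
show that the rule produces the published sign patterns and crossovers
when its inputs have those features; absolute plasticity magnitudes at
distal sites, the exact shape of the spatiotemporal windows, and the
dendritic-spike probabilities of the random-input protocol depend on the
replaced cell model and are reproduced qualitatively only. Receptor
desensitization, stochastic release, short-term plasticity and
metaplasticity are out of scope.

## Numerical choices and degenerate inputs

dt = 0.025 ms everywhere (protocol presets); events snap to the nearest
grid point, and events outside a trace raise a warning and are dropped.
Voltage traces must be finite; empty traces are rejected. `tanh` keeps all
saturating traces strictly below 1; weights are clipped after every step
and after sweep extrapolation. The clamp scan places the single event at
500 ms so the slowest voltage filter (τ_Nβ = 150 ms) is ≥96 % equilibrated;
the residual shifts the measured crossover by well under the reported
resolution. Problem sizes in the tests (seed counts of the stochastic
protocols, reduced window grids) are chosen so the whole suite runs in
minutes on one CPU while every qualitative claim is still exercised at the
printed stimulus numbers.

## Known limitations

* The reduced cell's input resistances, bAP amplitudes and plateau shape
  are calibrated to qualitative descriptions; quantities that depend on
  the detailed cell's channel kinetics (e.g. exact distal LTD magnitudes,
  BAC-firing statistics) should not be read quantitatively.
* The Ca²⁺ trigger's exclusion of somatic-injection charge is a modeling
  device of the reduction, not a biophysical claim.
* Heterosynaptic interactions are purely voltage-mediated here.
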