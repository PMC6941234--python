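"""The seven stimulation protocols and the sweep-extrapolation rule.

Each protocol binds a parameter set, synapse settings, stimulus timings and
a sweep count. Sweeps are simulated singly from a reset state and the final
outcome of ``n`` repetitions is extrapolated linearly in the weight factors
(the repetition shortcut); an explicit multi-sweep mode exists for oracle
checks.

Timing convention: ``dt_ms > 0`` means the presynaptic event leads the first
postsynaptic step current by ``dt_ms`` (pre-post); negative values are
post-pre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import PresynEventTrain, VoltageTrace, run_rule
from .neuron import (
    ActiveEventConfig,
    Morphology,
    StepCurrent,
    SynapsePlacement,
    detect_dendritic_spikes,
    load_morphology,
    simulate,
)
from .params import (
    W_POST_BOUNDS,
    W_PRE_BOUNDS,
    PlasticityParams,
    SynapseParams,
    read_parameter_set,
)

__all__ = [
    "PROTOCOL_PRESETS",
    "PlasticityWindow",
    "extrapolate_sweeps",
    "relative_change",
    "voltage_clamp_experiment",
    "burst_pairing_experiment",
    "burst_timing_experiment",
    "dendritic_spike_experiment",
    "spatiotemporal_window",
    "subthreshold_cluster_experiment",
    "basal_tuft_experiment",
    "heterosynaptic_experiment",
]

#: Printed stimulus numbers of every preset (frozen; asserted in tests).
PROTOCOL_PRESETS: dict = {
    "vclamp": dict(parameter_set="set1", sweeps=10, clamp_range=(-75.0, -15.0)),
    "burst_pairing": dict(
        parameter_set="set1", sites_um=(90.0, 669.0),
        frequencies_hz=(0.1, 10.0, 20.0, 40.0, 50.0), timings_ms=(10.0, -10.0),
        spikes_per_burst=5, step_ms=5.0, step_na=2.7,
        sweeps_low=10, sweeps=15, g_max=3.5, s_ampa=0.5, s_nmda=0.5),
    "burst_timing": dict(
        parameter_set="set2", site_um=55.0, region="basal",
        step_ms=5.0, step_na=2.1, sweeps=60, g_max=3.5, s_ampa=0.5,
        s_nmda=0.5),
    "dendritic_spike": dict(
        parameter_set="set3", sites_um=(90.0, 669.0), post_spikes=3,
        post_freq_hz=200.0, step_ms=2.0, step_na=5.5, sweeps=100,
        g_max=3.5, s_ampa=0.5, s_nmda=0.5, timings_ms=(10.0, -10.0)),
    "cluster": dict(
        parameter_set="set3", n_synapses=4, interval_ms=0.1, sweeps=50,
        g_max=2.5, s_ampa=0.8, s_nmda=0.2),
    "basal_tuft": dict(
        parameter_set="set3", n_basal_bg=50, n_tuft_bg=300, bg_g_max=2.5,
        plastic_per_zone=10, basal_site_um=32.0, apical_site_um=672.0,
        rate_hz=10.0, window_ms=100.0, n_seeds=100, g_max=2.5, s_ampa=0.8,
        s_nmda=0.2),
    "hetero": dict(
        parameter_set="set3", cluster_size=8, sites_um=(950.0, 1077.0),
        duration_ms=350.0, g_max=2.5, s_ampa=0.5, s_nmda=0.5,
        uniform_rate_hz=8.0, sin_freq_hz=8.0, sin_amp=0.05, sin_offset=0.005),
    "window": dict(n_sites=41, timing_range_ms=(-50.0, 50.0), timing_step_ms=1.0),
}

DT = 0.025  # ms, integration step used throughout


def _params(params) -> PlasticityParams:
    if isinstance(params, PlasticityParams):
        return params
    return read_parameter_set(params)


def extrapolate_sweeps(w_pre_sweep: float, w_post_sweep: float, n: int,
                       params: PlasticityParams) -> float:
    """Final total weight after ``n`` sweeps from single-sweep outcomes.

    Each factor is extrapolated linearly from its initial value and clipped
    to its hard bounds before the product is taken.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    wpre = params.w_pre_init + (w_pre_sweep - params.w_pre_init) * n
    wpost = params.w_post_init + (w_post_sweep - params.w_post_init) * n
    wpre = min(max(wpre, W_PRE_BOUNDS[0]), W_PRE_BOUNDS[1])
    wpost = min(max(wpost, W_POST_BOUNDS[0]), W_POST_BOUNDS[1])
    return wpre * wpost


def relative_change(w_final: float, params: PlasticityParams) -> float:
    """Relative weight change r = w_final / w_init (1.0 = no change)."""
    return w_final / (params.w_pre_init * params.w_post_init)


# -- 1: voltage clamp ---------------------------------------------------------

def voltage_clamp_experiment(params="set1", clamp_grid=None, sweeps: int = 10,
                             event_time: float = 500.0,
                             duration: float = 800.0, dt: float = DT,
                             pathway_contributions: bool = False
                             ) -> pd.DataFrame:
    """Relative weight change vs clamped voltage for one presynaptic event.

    The local potential is held constant over the whole sweep; a single
    event is delivered after the voltage filters have equilibrated, and the
    outcome of ``sweeps`` repetitions is extrapolated. Optionally also
    reports the absolute weight contribution of each pathway in isolation.
    """
    p = _params(params)
    if clamp_grid is None:
        lo, hi = PROTOCOL_PRESETS["vclamp"]["clamp_range"]
        clamp_grid = np.arange(lo, hi + 0.5, 1.0)
    events = PresynEventTrain(np.array([event_time]))
    rows = []
    for u in clamp_grid:
        trace = VoltageTrace.constant(u, duration, dt)
        traj = run_rule(trace, events, p)
        w_final = extrapolate_sweeps(traj.final_w_pre, traj.final_w_post,
                                     sweeps, p)
        row = dict(clamp_mv=float(u), r=relative_change(w_final, p))
        if pathway_contributions:
            for pw in ("pre_ltd", "pre_ltp", "post_ltd", "post_ltp"):
                iso = p
                for other in ("pre_ltd", "pre_ltp", "post_ltd", "post_ltp"):
                    if other != pw:
                        iso = iso.block(other)
                tr = run_rule(trace, events, iso)
                dwp = (tr.final_w_pre - p.w_pre_init) * sweeps
                dwq = (tr.final_w_post - p.w_post_init) * sweeps
                row[pw] = dwp if pw.startswith("pre") else dwq
        rows.append(row)
    return pd.DataFrame(rows)


def clamp_band_edges(df: pd.DataFrame, tol: float = 1e-9
                     ) -> tuple[float, float]:
    """(no-change edge, depression-to-potentiation crossing) in mV from a
    voltage-clamp scan.

    The first value is the largest clamp at or below which r == 1 for the
    whole subthreshold band; the second is where r crosses 1 from below
    between the depression and potentiation bands (linear interpolation).
    """
    v = df["clamp_mv"].to_numpy()
    r = df["r"].to_numpy()
    changed = np.abs(r - 1.0) > tol
    if not changed.any():
        return float(v[-1]), math.nan
    first_change = int(np.argmax(changed))
    no_change_edge = float(v[first_change - 1]) if first_change else math.nan
    crossing = math.nan
    for i in range(first_change, v.size - 1):
        if r[i] < 1.0 <= r[i + 1]:
            frac = (1.0 - r[i]) / (r[i + 1] - r[i])
            crossing = float(v[i] + frac * (v[i + 1] - v[i]))
            break
    return no_change_edge, crossing


# -- shared sweep driver ------------------------------------------------------

def _sweep_outcome(morph, cfg, stimuli, synapses, duration, p, dt=DT,
                   seed=None):
    """Simulate one sweep and run the rule on each plastic synapse's local
    voltage; returns list of (w_pre_sweep, w_post_sweep) and the SimResult."""
    res = simulate(morph, cfg, stimuli, synapses, duration, dt=dt, seed=seed,
                   plasticity=p)
    outcomes = []
    for j, s in enumerate(synapses):
        if not s.plastic:
            outcomes.append(None)
            continue
        traj = run_rule(res.synapse_traces[j], res.synapse_events[j], p)
        outcomes.append((traj.final_w_pre, traj.final_w_post))
    return outcomes, res


def _default_morph_cfg(morph=None, cfg=None):
    return (morph if morph is not None else load_morphology("reduced_l5"),
            cfg if cfg is not None else ActiveEventConfig())


# -- 2: pre/post burst pairing (rate x timing x location) --------------------

def burst_pairing_experiment(frequency: float, dt_ms: float,
                             site_um: float = 90.0, params="set1",
                             sweeps: int | None = None, morph=None, cfg=None,
                             explicit_sweeps: bool = False,
                             return_detail: bool = False):
    """Relative weight change for five pre + five post spikes at an
    intra-burst frequency, shifted by ``dt_ms`` (positive = pre leads).

    At 0.1 Hz the five pairs of a burst are >= 10 s apart, so one pair is
    simulated and the repetition count absorbs the factor five (10 sweeps x
    5 pairs = 50 pair repetitions); at 10-50 Hz the full burst is simulated
    and 15 sweeps are extrapolated.
    """
    preset = PROTOCOL_PRESETS["burst_pairing"]
    p = _params(params)
    morph, cfg = _default_morph_cfg(morph, cfg)
    sp = SynapseParams(g_max=preset["g_max"], s_ampa=preset["s_ampa"],
                       s_nmda=preset["s_nmda"])
    n_spikes = preset["spikes_per_burst"]
    if frequency <= 1.0:
        n_spikes_sim = 1
        n = (sweeps or preset["sweeps_low"]) * n_spikes
        period = 0.0
    else:
        n_spikes_sim = n_spikes
        n = sweeps or preset["sweeps"]
        period = 1000.0 / frequency
    t0 = 100.0
    t_pre0 = t0 + max(0.0, -dt_ms)
    t_post0 = t_pre0 + dt_ms
    pre_times = t_pre0 + period * np.arange(n_spikes_sim)
    stim = StepCurrent(onset=t_post0, duration=preset["step_ms"],
                       amplitude=preset["step_na"], count=n_spikes_sim,
                       frequency=max(frequency, 1e-3))
    duration = max(pre_times[-1], t_post0 + period * (n_spikes_sim - 1)) + 300.0
    syn = SynapsePlacement(distance=site_um, params=sp,
                           events=PresynEventTrain(pre_times),
                           region="apical", plastic=True,
                           w_pre=p.w_pre_init, w_post=p.w_post_init,
                           w_post_init=p.w_post_init)
    if explicit_sweeps:
        return _explicit_sweeps_pairing(morph, cfg, stim, syn, duration, p, n)
    outcomes, res = _sweep_outcome(morph, cfg, [stim], [syn], duration, p)
    wps, wqs = outcomes[0]
    w_final = extrapolate_sweeps(wps, wqs, n, p)
    r = relative_change(w_final, p)
    if return_detail:
        return r, dict(w_pre_sweep=wps, w_post_sweep=wqs, n=n, sim=res)
    return r


def _explicit_sweeps_pairing(morph, cfg, stim, syn, duration, p, n):
    """Oracle mode: concatenate n sweeps with full state reset between
    sweeps but carrying the weights forward (no extrapolation)."""
    wpre, wpost = p.w_pre_init, p.w_post_init
    for _ in range(n):
        import dataclasses
        pp = dataclasses.replace(p, w_pre_init=wpre, w_post_init=wpost)
        outcomes, _ = _sweep_outcome(morph, cfg, [stim], [syn], duration, pp)
        wpre, wpost = outcomes[0]
    return relative_change(wpre * wpost, p)


# -- 3: single pre events vs postsynaptic bursts ------------------------------

@dataclass(frozen=True)
class BurstPattern:
    """One cell of the burst-timing protocol family."""
    n_pre: int = 1
    n_post: int = 3
    freq_hz: float = 50.0
    dt_ms: float = 10.0

    def describe(self) -> str:
        return (f"{self.n_pre}pre+{self.n_post}post@{self.freq_hz:g}Hz,"
                f"dt={self.dt_ms:+g}ms")


def burst_timing_experiment(pattern: BurstPattern, params="set2",
                            sweeps: int | None = None, morph=None, cfg=None
                            ) -> float:
    """Relative change for one presynaptic event paired with a burst of 0-3
    postsynaptic spikes on a proximal basal dendrite."""
    preset = PROTOCOL_PRESETS["burst_timing"]
    if pattern.n_post < 0 or pattern.n_pre < 0:
        raise ValueError("spike counts must be >= 0")
    p = _params(params)
    morph, cfg = _default_morph_cfg(morph, cfg)
    sp = SynapseParams(g_max=preset["g_max"], s_ampa=preset["s_ampa"],
                       s_nmda=preset["s_nmda"])
    n = sweeps or preset["sweeps"]
    period = 1000.0 / pattern.freq_hz
    t0 = 100.0
    t_pre0 = t0 + max(0.0, -pattern.dt_ms)
    t_post0 = t_pre0 + pattern.dt_ms
    pre_times = t_pre0 + period * np.arange(pattern.n_pre)
    stimuli = []
    if pattern.n_post > 0:
        stimuli.append(StepCurrent(
            onset=t_post0, duration=preset["step_ms"],
            amplitude=preset["step_na"], count=pattern.n_post,
            frequency=pattern.freq_hz))
    last = max(pre_times[-1] if pattern.n_pre else t0,
               t_post0 + period * max(pattern.n_post - 1, 0))
    syn = SynapsePlacement(distance=preset["site_um"], params=sp,
                           events=PresynEventTrain(pre_times),
                           region="basal", plastic=True,
                           w_pre=p.w_pre_init, w_post=p.w_post_init,
                           w_post_init=p.w_post_init)
    outcomes, _ = _sweep_outcome(morph, cfg, stimuli, [syn], last + 300.0, p)
    wps, wqs = outcomes[0]
    return relative_change(extrapolate_sweeps(wps, wqs, n, p), p)


# -- 4: burst-induced dendritic spikes ---------------------------------------

def dendritic_spike_experiment(dt_ms: float, site_um: float, params="set3",
                               sweeps: int | None = None, morph=None,
                               cfg=None, return_detail: bool = False):
    """Relative change for one presynaptic event paired (+/-10 ms) with a
    200-Hz triplet of somatic APs that evokes a distal Ca2+ plateau."""
    preset = PROTOCOL_PRESETS["dendritic_spike"]
    p = _params(params)
    morph, cfg = _default_morph_cfg(morph, cfg)
    sp = SynapseParams(g_max=preset["g_max"], s_ampa=preset["s_ampa"],
                       s_nmda=preset["s_nmda"])
    n = sweeps or preset["sweeps"]
    t0 = 100.0
    t_pre = t0 + max(0.0, -dt_ms)
    t_post = t_pre + dt_ms
    stim = StepCurrent(onset=t_post, duration=preset["step_ms"],
                       amplitude=preset["step_na"],
                       count=preset["post_spikes"],
                       frequency=preset["post_freq_hz"])
    syn = SynapsePlacement(distance=site_um, params=sp,
                           events=PresynEventTrain(np.array([t_pre])),
                           region="apical", plastic=True,
                           w_pre=p.w_pre_init, w_post=p.w_post_init,
                           w_post_init=p.w_post_init)
    outcomes, res = _sweep_outcome(morph, cfg, [stim], [syn],
                                   t_post + 400.0, p)
    wps, wqs = outcomes[0]
    r = relative_change(extrapolate_sweeps(wps, wqs, n, p), p)
    if return_detail:
        return r, res
    return r


# -- 5: spatiotemporal plasticity window --------------------------------------

@dataclass(frozen=True)
class PlasticityWindow:
    """Relative weight change over (path distance x burst timing)."""

    distances_um: np.ndarray
    timings_ms: np.ndarray
    matrix: np.ndarray             # shape (n_sites, n_timings)
    n_simulations: int

    def __post_init__(self):
        if self.matrix.shape != (self.distances_um.size,
                                 self.timings_ms.size):
            raise ValueError("window matrix shape mismatch")


def spatiotemporal_window(protocol: str = "burst_pairing",
                          frequency: float = 10.0, params=None,
                          timings=None, n_sites: int = 41,
                          morph=None, cfg=None, sweeps: int | None = None
                          ) -> PlasticityWindow:
    """Relative weight change on a grid of synapse locations along the
    apical path x burst timings.

    The stimulus-evoked voltage profile is simulated once per protocol and
    reused across timings; the synapse's own local EPSP is simulated once
    per site and superposed at the event time (the synaptic contribution is
    small relative to bAP/plateau depolarization at these stimuli). Each
    grid cell is one evaluation of the plasticity rule: 41 x 101 = 4,141.
    """
    wcfg = PROTOCOL_PRESETS["window"]
    if timings is None:
        lo, hi = wcfg["timing_range_ms"]
        timings = np.arange(lo, hi + 0.5 * wcfg["timing_step_ms"],
                            wcfg["timing_step_ms"])
    timings = np.asarray(timings, dtype=float)
    morph, cfg = _default_morph_cfg(morph, cfg)
    if protocol == "burst_pairing":
        preset = PROTOCOL_PRESETS["burst_pairing"]
        p = _params(params or preset["parameter_set"])
        n_spikes = preset["spikes_per_burst"] if frequency > 1.0 else 1
        period = 1000.0 / frequency if frequency > 1.0 else 0.0
        n = sweeps or (preset["sweeps"] if frequency > 1.0
                       else preset["sweeps_low"] * 5)
        stim = StepCurrent(onset=200.0, duration=preset["step_ms"],
                           amplitude=preset["step_na"], count=n_spikes,
                           frequency=max(frequency, 1e-3))
        pre_count = n_spikes
    elif protocol == "dendritic_spike":
        preset = PROTOCOL_PRESETS["dendritic_spike"]
        p = _params(params or preset["parameter_set"])
        period = 1000.0 / preset["post_freq_hz"]
        stim = StepCurrent(onset=200.0, duration=preset["step_ms"],
                           amplitude=preset["step_na"],
                           count=preset["post_spikes"],
                           frequency=preset["post_freq_hz"])
        n = sweeps or preset["sweeps"]
        pre_count = 1
    else:
        raise ValueError(f"no window preset for protocol {protocol!r}")
    sp = SynapseParams(g_max=preset["g_max"], s_ampa=preset["s_ampa"],
                       s_nmda=preset["s_nmda"])
    duration = 200.0 + period * 5 + float(np.max(np.abs(timings))) + 350.0

    sites = morph.apical_sites(n_sites)
    dists = morph.path_distance[sites]
    profile = simulate(
        morph, cfg, [stim], [], duration, dt=DT, plasticity=p,
        record_sites={f"s{i}": float(d) for i, d in enumerate(dists)})

    # per-site single-event EPSP template (deviation from rest)
    epsp = {}
    for i, d in enumerate(dists):
        syn = SynapsePlacement(distance=float(d), params=sp,
                               events=PresynEventTrain(np.array([50.0])),
                               region="apical", plastic=False,
                               w_pre=p.w_pre_init, w_post=p.w_post_init,
                               w_post_init=p.w_post_init)
        r = simulate(morph, cfg, [], [syn], 300.0, dt=DT, plasticity=p)
        epsp[i] = r.synapse_traces[0].samples - r.synapse_traces[0].samples[0]
        k0 = int(round(50.0 / DT))
        epsp[i] = epsp[i][k0:]

    n_sim = 0
    mat = np.empty((dists.size, timings.size))
    n_steps = profile.site_traces["s0"].n
    for i in range(dists.size):
        base = profile.site_traces[f"s{i}"].samples
        for j, tshift in enumerate(timings):
            # pre events lead the first step current by tshift
            pre_times = 200.0 - tshift + period * np.arange(pre_count)
            u = base.copy()
            for tp in pre_times:
                k0 = int(round(tp / DT))
                seg = epsp[i][: n_steps - k0]
                u[k0:k0 + seg.size] += seg
            traj = run_rule(VoltageTrace(0.0, DT, np.clip(u, -100.0, 50.0)),
                            PresynEventTrain(pre_times), p)
            mat[i, j] = relative_change(
                extrapolate_sweeps(traj.final_w_pre, traj.final_w_post, n, p),
                p)
            n_sim += 1
    return PlasticityWindow(distances_um=dists, timings_ms=timings,
                            matrix=mat, n_simulations=n_sim)


# -- 6: subthreshold cluster activation ---------------------------------------

def subthreshold_cluster_experiment(site_um: float, channel_block: bool = False,
                                    params="set3", region: str = "apical",
                                    sweeps: int | None = None, morph=None,
                                    cfg=None) -> float:
    """Mean relative change of a cluster of four synapses activated in rapid
    succession (0.1 ms apart), without somatic stimulation."""
    preset = PROTOCOL_PRESETS["cluster"]
    p = _params(params)
    morph, cfg = _default_morph_cfg(morph, cfg)
    if channel_block:
        cfg = cfg.blocked()
    sp = SynapseParams(g_max=preset["g_max"], s_ampa=preset["s_ampa"],
                       s_nmda=preset["s_nmda"])
    n = sweeps or preset["sweeps"]
    t0 = 100.0
    syns = [SynapsePlacement(distance=site_um, params=sp,
                             events=PresynEventTrain(
                                 np.array([t0 + j * preset["interval_ms"]])),
                             region=region, plastic=True,
                             w_pre=p.w_pre_init, w_post=p.w_post_init,
                             w_post_init=p.w_post_init)
            for j in range(preset["n_synapses"])]
    outcomes, _ = _sweep_outcome(morph, cfg, [], syns, t0 + 400.0, p)
    rs = [relative_change(extrapolate_sweeps(wp, wq, n, p), p)
          for wp, wq in outcomes]
    return float(np.mean(rs))


# -- 7: random basal and tuft inputs (BAC firing) ------------------------------

def basal_tuft_experiment(condition: str, n_seeds: int = 100, seed: int = 0,
                          params="set3", morph=None, cfg=None,
                          window_ms: float | None = None) -> dict:
    """Random background drive of basal and/or tuft synapses with plastic
    probes near both spiking zones.

    Returns per-seed final weights of the basal and apical probe synapses
    and the probability of a dendritic spike (plateau) per trial.
    """
    if condition not in ("basal", "tuft", "both"):
        raise ValueError("condition must be basal | tuft | both")
    preset = PROTOCOL_PRESETS["basal_tuft"]
    p = _params(params)
    morph, cfg = _default_morph_cfg(morph, cfg)
    window = window_ms or preset["window_ms"]
    t_on = 50.0
    duration = t_on + window + 100.0
    bg_sp = SynapseParams(g_max=preset["bg_g_max"], s_ampa=1.0, s_nmda=0.0)
    pl_sp = SynapseParams(g_max=preset["g_max"], s_ampa=preset["s_ampa"],
                          s_nmda=preset["s_nmda"])
    basal_comps = np.flatnonzero(morph.kind == "basal")
    tuft_comps = np.flatnonzero(morph.kind == "tuft")
    rate = preset["rate_hz"]

    basal_w, apical_w, spikes = [], [], 0
    root = np.random.SeedSequence(seed)
    for trial_ss in root.spawn(n_seeds):
        rng = np.random.default_rng(trial_ss)
        syns = []
        active_basal = condition in ("basal", "both")
        active_tuft = condition in ("tuft", "both")

        def train(active):
            if not active:
                return PresynEventTrain(np.array([]))
            n_ev = rng.poisson(rate * window / 1000.0)
            return PresynEventTrain(np.sort(t_on + rng.random(n_ev) * window))

        for c in rng.choice(basal_comps, preset["n_basal_bg"]):
            syns.append(SynapsePlacement(
                distance=float(morph.path_distance[c]), params=bg_sp,
                events=train(active_basal), region="basal", comp=int(c)))
        for c in rng.choice(tuft_comps, preset["n_tuft_bg"]):
            syns.append(SynapsePlacement(
                distance=float(morph.path_distance[c]), params=bg_sp,
                events=train(active_tuft), region="tuft", comp=int(c)))
        plastic = []
        for _ in range(preset["plastic_per_zone"]):
            plastic.append(SynapsePlacement(
                distance=preset["basal_site_um"], params=pl_sp,
                events=train(active_basal), region="basal", plastic=True,
                w_pre=p.w_pre_init, w_post=p.w_post_init,
                w_post_init=p.w_post_init, label="basal"))
        for _ in range(preset["plastic_per_zone"]):
            plastic.append(SynapsePlacement(
                distance=preset["apical_site_um"], params=pl_sp,
                events=train(active_tuft), region="apical", plastic=True,
                w_pre=p.w_pre_init, w_post=p.w_post_init,
                w_post_init=p.w_post_init, label="apical"))
        syns += plastic
        outcomes, res = _sweep_outcome(
            morph, cfg, [], syns, duration, p,
            seed=int(rng.integers(2 ** 31 - 1)))
        for s, out in zip(syns, outcomes):
            if out is None:
                continue
            w = out[0] * out[1]
            (basal_w if s.label == "basal" else apical_w).append(w)
        if res.plateau_onsets.size:
            spikes += 1
    w0 = p.w_pre_init * p.w_post_init
    return dict(
        basal_weights=np.asarray(basal_w) / w0,
        apical_weights=np.asarray(apical_w) / w0,
        dendritic_spike_probability=spikes / n_seeds,
        n_seeds=n_seeds,
    )


# -- 8: heterosynaptic effects / NMDA spikes ----------------------------------

def _activation_train(mode: str, duration: float, rng,
                      preset=None) -> PresynEventTrain:
    """Per-synapse event train: 'uniform' Poisson or 'synchronized'
    sinusoidal activation probability, decided in 1-ms bins."""
    preset = preset or PROTOCOL_PRESETS["hetero"]
    n_bins = int(duration)
    t_bins = np.arange(n_bins, dtype=float)
    if mode == "uniform":
        prob = np.full(n_bins, preset["uniform_rate_hz"] * 1e-3)
    elif mode == "synchronized":
        prob = np.maximum(
            preset["sin_offset"] + preset["sin_amp"]
            * np.sin(2 * np.pi * preset["sin_freq_hz"] * t_bins / 1000.0),
            0.0)
    else:
        raise ValueError("mode must be uniform | synchronized")
    hits = rng.random(n_bins) < prob
    return PresynEventTrain(t_bins[hits] + 0.5)


def heterosynaptic_experiment(mode_a: str = "synchronized",
                              mode_b: str = "uniform", seed: int = 0,
                              params="set3", morph=None, cfg=None) -> dict:
    """Two clusters of eight synapses on a thin tuft branch (a distal, b
    proximal); returns voltages, summed conductances, weight trajectories
    and the mean relative change per cluster."""
    preset = PROTOCOL_PRESETS["hetero"]
    p = _params(params)
    morph, cfg = _default_morph_cfg(morph, cfg)
    duration = preset["duration_ms"]
    sp = SynapseParams(g_max=preset["g_max"], s_ampa=preset["s_ampa"],
                       s_nmda=preset["s_nmda"])
    site_b, site_a = sorted(preset["sites_um"])
    root = np.random.SeedSequence(seed)
    streams = root.spawn(2 * preset["cluster_size"])
    syns = []
    for i in range(preset["cluster_size"]):
        rng = np.random.default_rng(streams[i])
        syns.append(SynapsePlacement(
            distance=site_a, params=sp,
            events=_activation_train(mode_a, duration, rng),
            region="apical", plastic=True, w_pre=p.w_pre_init,
            w_post=p.w_post_init, w_post_init=p.w_post_init, label="a"))
    for i in range(preset["cluster_size"]):
        rng = np.random.default_rng(streams[preset["cluster_size"] + i])
        syns.append(SynapsePlacement(
            distance=site_b, params=sp,
            events=_activation_train(mode_b, duration, rng),
            region="apical", plastic=True, w_pre=p.w_pre_init,
            w_post=p.w_post_init, w_post_init=p.w_post_init, label="b"))
    res = simulate(morph, cfg, [], syns, duration + 50.0, dt=DT,
                   plasticity=p,
                   record_sites=dict(a=site_a, b=site_b))
    from .synapse import run_synapse

    w0 = p.w_pre_init * p.w_post_init
    out = dict(voltage_a=res.site_traces["a"], voltage_b=res.site_traces["b"],
               weights={"a": [], "b": []}, g_ampa={"a": 0.0, "b": 0.0},
               g_nmda={"a": 0.0, "b": 0.0})
    g_sum = {("a", "g_ampa"): None, ("a", "g_nmda"): None,
             ("b", "g_ampa"): None, ("b", "g_nmda"): None}
    for j, s in enumerate(syns):
        traj = run_rule(res.synapse_traces[j], res.synapse_events[j], p)
        out["weights"][s.label].append(traj.w_pre * traj.w_post / w0)
        g = run_synapse(res.synapse_traces[j], res.synapse_events[j], sp,
                        p.w_pre_init, p.w_post_init, p.w_post_init, p)
        for key in ("g_ampa", "g_nmda"):
            cur = g_sum[(s.label, key)]
            g_sum[(s.label, key)] = g[key] if cur is None else cur + g[key]
    out["g_ampa"] = {lbl: g_sum[(lbl, "g_ampa")] for lbl in "ab"}
    out["g_nmda"] = {lbl: g_sum[(lbl, "g_nmda")] for lbl in "ab"}
    out["mean_r_a"] = float(np.mean([w[-1] for w in out["weights"]["a"]]))
    out["mean_r_b"] = float(np.mean([w[-1] for w in out["weights"]["b"]]))
    out["nmda_spikes"] = detect_dendritic_spikes(
        res.site_traces["a"], threshold=-40.0, min_duration=10.0)
    return out
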