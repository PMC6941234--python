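"""Reduced dendritic neuron: passive cable plus phenomenological active events.

This stands in for a detailed layer-5b pyramidal cell model. The membrane is
passive and integrated implicitly (unconditionally stable) on a compartmental
tree; the three classes of active behavior that matter for synaptic
plasticity are phenomenological:

* axo-somatic action potentials — triggered by a somatic voltage threshold
  or forced by the step-current stimuli of the standard protocols — inject
  backpropagating-AP voltage templates along the tree, with peak amplitude
  decaying and width growing with path distance;
* a dendritic Ca2+-spike zone near the end of the apical trunk fires a long
  plateau when the low-pass-filtered local depolarization crosses threshold;
  the plateau invades the tuft and attenuates steeply toward the soma;
* thin apical branches carry a blockable depolarization-activated boost
  conductance (a surrogate for dendritic Na+/Ca2+ channels); NMDA
  regenerativity itself emerges from the synapse's Mg2+ block on
  high-input-resistance branches.

Voltages are clipped to the physiological window [-100, +50] mV when
composing the passive solution with templates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.sparse import csc_matrix
from scipy.sparse.linalg import splu

from .core import PresynEventTrain, VoltageTrace
from .params import PlasticityParams, SynapseParams, double_exp_kernel
from .synapse import mg_block

__all__ = [
    "Morphology",
    "ActiveEventConfig",
    "StepCurrent",
    "SynapsePlacement",
    "load_morphology",
    "simulate",
    "bap_playback",
    "detect_dendritic_spikes",
]

V_CEIL = 50.0
V_FLOOR = -100.0
E_REST = -75.0


class MorphologyError(ValueError):
    pass


class PlacementError(MorphologyError):
    pass


@dataclass(frozen=True)
class SectionSpec:
    name: str
    parent: str | None
    length: float          # um
    diam_start: float      # um
    diam_end: float
    nseg: int
    kind: str              # soma | axon | apical | tuft | basal


@dataclass
class Morphology:
    """Compartmentalized tree with per-compartment geometry and path
    distances to the soma (um)."""

    names: list[str]
    kind: np.ndarray            # str per compartment
    parent: np.ndarray          # int index, -1 for root
    length: np.ndarray          # um
    diam: np.ndarray            # um
    path_distance: np.ndarray   # um, compartment center to soma center
    section_of: np.ndarray      # section name per compartment
    apical_path: np.ndarray     # ordered comp indices soma -> apical tip

    @property
    def n(self) -> int:
        return self.parent.size

    def area_cm2(self) -> np.ndarray:
        return np.pi * self.diam * self.length * 1e-8

    def locate(self, distance: float, region: str = "apical") -> int:
        """Compartment index closest to ``distance`` um from the soma within
        a region ('apical' walks the main apical path; otherwise matched by
        section kind)."""
        if region == "apical":
            cand = self.apical_path
        else:
            cand = np.flatnonzero(self.kind == region)
            if cand.size == 0:
                raise PlacementError(f"no compartments of kind {region!r}")
        d = self.path_distance[cand]
        if distance > d.max() + 30.0 or distance < -1e-9:
            raise PlacementError(
                f"distance {distance} um unreachable in region {region!r} "
                f"(max {d.max():.0f} um)")
        return int(cand[np.argmin(np.abs(d - distance))])

    def apical_sites(self, n_sites: int = 41) -> np.ndarray:
        """~Evenly spaced compartments along the apical path (soma end to
        tip), used for voltage profiles and plasticity windows."""
        d = self.path_distance[self.apical_path]
        targets = np.linspace(d.min(), d.max(), n_sites)
        idx = [int(self.apical_path[np.argmin(np.abs(d - t))])
               for t in targets]
        return np.array(idx)


def _build_from_sections(sections: list[SectionSpec]) -> Morphology:
    by_name = {s.name: s for s in sections}
    names, kinds, parents, lengths, diams, secof = [], [], [], [], [], []
    first_comp: dict[str, int] = {}
    last_comp: dict[str, int] = {}
    for s in sections:
        if s.parent is not None and s.parent not in by_name:
            raise MorphologyError(f"section {s.name} has unknown parent")
        dx = s.length / s.nseg
        for j in range(s.nseg):
            frac = (j + 0.5) / s.nseg
            d = s.diam_start + (s.diam_end - s.diam_start) * frac
            idx = len(parents)
            if j == 0:
                parent = -1 if s.parent is None else last_comp[s.parent]
                first_comp[s.name] = idx
            else:
                parent = idx - 1
            parents.append(parent)
            lengths.append(dx)
            diams.append(d)
            kinds.append(s.kind)
            secof.append(s.name)
        last_comp[s.name] = len(parents) - 1
    parent = np.array(parents)
    length = np.array(lengths)
    # path distance (center to center along the tree; soma center = 0)
    dist = np.zeros(parent.size)
    for i in range(parent.size):
        p = parent[i]
        if p < 0:
            dist[i] = 0.0
        elif kinds[p] == "soma":
            dist[i] = length[i] / 2.0
        else:
            dist[i] = dist[p] + (length[p] + length[i]) / 2.0
    # main apical path: soma + sections flagged apical/tuft forming the
    # longest root-to-tip chain
    apical = [i for i, k in enumerate(kinds) if k in ("apical", "tuft")]
    if apical:
        tip = max(apical, key=lambda i: dist[i])
        path = [tip]
        while parent[path[-1]] >= 0 and kinds[parent[path[-1]]] != "soma":
            path.append(parent[path[-1]])
        path = path[::-1]
    else:
        path = []
    return Morphology(
        names=[s.name for s in sections],
        kind=np.array(kinds), parent=parent, length=length,
        diam=np.array(diams), path_distance=dist,
        section_of=np.array(secof), apical_path=np.array(path, dtype=int),
    )


def _reduced_l5_sections() -> list[SectionSpec]:
    """Reduced pyramidal-cell stand-in: a tapering apical trunk with thin
    oblique side branches, two thin tuft branches past the Ca2+ zone, and a
    basal skirt providing a realistic somatic load (~25,000 um2 total
    membrane). Thin distal branches give the steep input-resistance gradient
    that the subthreshold-cluster and NMDA-spike behaviors rely on."""
    secs = [
        SectionSpec("soma", None, 35.0, 35.0, 35.0, 1, "soma"),
        SectionSpec("axon", "soma", 60.0, 1.5, 1.0, 2, "axon"),
        SectionSpec("trunk1", "soma", 150.0, 5.0, 4.2, 6, "apical"),
        SectionSpec("trunk2", "trunk1", 150.0, 4.2, 3.5, 6, "apical"),
        SectionSpec("trunk3", "trunk2", 150.0, 3.5, 2.9, 6, "apical"),
        SectionSpec("trunk4", "trunk3", 150.0, 2.9, 2.5, 6, "apical"),
        SectionSpec("oblique_0", "trunk1", 180.0, 0.9, 0.4, 6, "apical"),
        SectionSpec("oblique_1", "trunk2", 180.0, 0.9, 0.4, 6, "apical"),
        SectionSpec("oblique_2", "trunk3", 180.0, 0.9, 0.4, 6, "apical"),
        SectionSpec("tuft_a", "trunk4", 600.0, 1.4, 0.35, 24, "tuft"),
        SectionSpec("tuft_b", "trunk4", 500.0, 1.2, 0.35, 20, "tuft"),
    ]
    for i in range(8):
        secs.append(SectionSpec(f"basal_{i}", "soma", 250.0, 2.5, 0.6,
                                10, "basal"))
    return secs


_SWC_KIND = {1: "soma", 2: "axon", 3: "basal", 4: "apical"}


def _load_swc(path: Path) -> Morphology:
    """Minimal SWC reader: every sample becomes one compartment."""
    ids, kinds, xyz, radii, parents = [], [], [], [], []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise MorphologyError(f"{path}:{ln}: expected 7 columns")
        try:
            sid, t = int(parts[0]), int(parts[1])
            x, y, z, r = map(float, parts[2:6])
            pid = int(parts[6])
        except ValueError as exc:
            raise MorphologyError(f"{path}:{ln}: {exc}") from None
        ids.append(sid)
        kinds.append(_SWC_KIND.get(t, "basal"))
        xyz.append((x, y, z))
        radii.append(r)
        parents.append(pid)
    index = {sid: i for i, sid in enumerate(ids)}
    parent_idx = np.empty(len(ids), dtype=int)
    for i, pid in enumerate(parents):
        if pid == -1:
            parent_idx[i] = -1
        elif pid not in index:
            raise MorphologyError(f"sample {ids[i]} has unknown parent {pid}")
        else:
            parent_idx[i] = index[pid]
    # cycle check: walk each node to root
    for i in range(len(ids)):
        seen, j = set(), i
        while j >= 0:
            if j in seen:
                raise MorphologyError("SWC describes a cycle, not a tree")
            seen.add(j)
            j = parent_idx[j]
    xyz = np.asarray(xyz)
    seg_len = np.zeros(len(ids))
    for i, p in enumerate(parent_idx):
        if p >= 0:
            seg_len[i] = float(np.linalg.norm(xyz[i] - xyz[p]))
    dist = np.zeros(len(ids))
    for i, p in enumerate(parent_idx):
        dist[i] = seg_len[i] + (dist[p] if p >= 0 else 0.0)
    kinds_arr = np.array(kinds)
    apical = [i for i, k in enumerate(kinds) if k == "apical"]
    if apical:
        tip = max(apical, key=lambda i: dist[i])
        chain = [tip]
        while parent_idx[chain[-1]] >= 0:
            chain.append(parent_idx[chain[-1]])
        path_idx = np.array(chain[::-1], dtype=int)
    else:
        path_idx = np.array([], dtype=int)
    return Morphology(
        names=["swc"], kind=kinds_arr, parent=parent_idx,
        length=np.where(seg_len > 0, seg_len, 1.0),
        diam=2.0 * np.asarray(radii), path_distance=dist,
        section_of=np.array([f"swc_{sid}" for sid in ids]),
        apical_path=path_idx,
    )


def load_morphology(source: str | Path = "reduced_l5") -> Morphology:
    """Load a morphology from the builtin preset or an SWC file."""
    if isinstance(source, (str, Path)) and str(source) == "reduced_l5":
        return _build_from_sections(_reduced_l5_sections())
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"no such morphology: {source}")
    return _load_swc(path)


# -- active events ------------------------------------------------------------

@dataclass(frozen=True)
class ActiveEventConfig:
    """Phenomenological active-event parameters of the reduced neuron."""

    # backpropagating AP template
    bap_amp: float = 100.0          # mV above rest at the soma
    bap_lambda: float = 220.0       # um attenuation length constant
    bap_width0: float = 2.0         # ms decay time constant at the soma
    bap_width_lambda: float = 400.0  # um; width grows 1 + x/lambda_w
    bap_rise: float = 0.3           # ms
    bap_velocity: float = 500.0     # um/ms propagation speed
    # dendritic Ca2+ spike
    ca_zone_distance: float = 600.0  # um trigger site on the apical path
    ca_threshold: float = 9.5       # mV low-passed depolarization threshold
    ca_tau: float = 12.0             # ms integration time constant
    ca_delay: float = 8.5            # ms onset delay after trigger
    ca_amp: float = 50.0             # mV plateau amplitude at the zone
    ca_rise: float = 3.0             # ms
    ca_duration: float = 40.0        # ms plateau
    ca_fall: float = 8.0             # ms
    ca_lambda_distal: float = 900.0  # um attenuation into the tuft
    ca_lambda_proximal: float = 150.0  # um attenuation toward the soma
    ca_refractory: float = 150.0     # ms
    ca_bap_gain: float = 3.0         # weight of bAP templates in the trigger
    ca_syn_gain: float = 0.25        # weight of synaptic drive in the trigger
    # dendritic boost conductance (surrogate Na+/Ca2+ channels): fast
    # activation above ~-30 mV with slow inactivation, so strong local
    # input ignites a self-limiting plateau on thin branches
    boost_density: float = 3.0e-3    # S/cm2 on thin apical branches
    boost_diam_max: float = 1.3      # um; boost only on thinner comps
    boost_vhalf: float = -25.0       # mV activation midpoint
    boost_kslope: float = 3.5        # mV
    boost_erev: float = 10.0         # mV
    boost_tau: float = 2.0           # ms activation time constant
    boost_h_vhalf: float = -40.0     # mV inactivation midpoint
    boost_h_kslope: float = 7.0      # mV
    boost_h_tau: float = 40.0        # ms inactivation time constant
    # somatic AP generation
    ap_threshold: float = -53.0      # mV
    ap_refractory: float = 6.0       # ms
    ap_delay: float = 0.5            # ms from pulse onset (forced mode)
    channel_block: bool = False      # disables Ca spike + boost (apical)

    def blocked(self) -> "ActiveEventConfig":
        return replace(self, channel_block=True)


def _template_shape(t: np.ndarray, rise: float, decay) -> np.ndarray:
    """Difference-of-exponentials pulse, peak normalized to 1, zero for t<0.

    ``decay`` may be an array (per-compartment widths)."""
    decay = np.asarray(decay, dtype=float)
    omega = rise * decay / (decay - rise) * np.log(decay / rise)
    eps = 1.0 / (np.exp(-omega / decay) - np.exp(-omega / rise))
    tt = np.maximum(np.asarray(t, dtype=float), 0.0)
    out = eps * (np.exp(-tt / decay) - np.exp(-tt / rise))
    return np.where(np.asarray(t) < 0.0, 0.0, out)


def bap_contribution(cfg: ActiveEventConfig, distance, t_since_spike):
    """Voltage added by one backpropagating AP at path distance(s) ``distance``
    (um), ``t_since_spike`` ms after the somatic spike."""
    distance = np.asarray(distance, dtype=float)
    amp = cfg.bap_amp * np.exp(-distance / cfg.bap_lambda)
    width = cfg.bap_width0 * (1.0 + distance / cfg.bap_width_lambda)
    t = np.asarray(t_since_spike, dtype=float) - distance / cfg.bap_velocity
    return amp * _template_shape(t, cfg.bap_rise, width)


def _plateau_envelope(t: np.ndarray, cfg: ActiveEventConfig) -> np.ndarray:
    """Rise / plateau / exponential-fall envelope of the Ca2+ spike."""
    t = np.asarray(t, dtype=float)
    rise = np.clip(t / cfg.ca_rise, 0.0, 1.0)
    fall = np.where(t > cfg.ca_rise + cfg.ca_duration,
                    np.exp(-(t - cfg.ca_rise - cfg.ca_duration) / cfg.ca_fall),
                    1.0)
    return np.where(t < 0.0, 0.0, rise * fall)


def plateau_contribution(cfg: ActiveEventConfig, distance, t_since_onset):
    """Voltage added by a dendritic Ca2+ plateau centered at the trigger
    zone; steep attenuation toward the soma, shallow into the tuft."""
    distance = np.asarray(distance, dtype=float)
    dx = distance - cfg.ca_zone_distance
    profile = np.where(dx >= 0.0, np.exp(-dx / cfg.ca_lambda_distal),
                       np.exp(dx / cfg.ca_lambda_proximal))
    return cfg.ca_amp * profile * _plateau_envelope(
        np.asarray(t_since_onset, dtype=float), cfg)


def bap_playback(distance: float, spike_times, cfg: ActiveEventConfig
                 | None = None, duration: float | None = None,
                 dt: float = 0.025, rest: float = E_REST,
                 plateau_onsets=()) -> VoltageTrace:
    """Deterministic voltage template: resting baseline plus superposed
    distance-attenuated bAPs (and optional Ca2+ plateaus) at one site.

    Isolates the plasticity rule from cable integration; linear by
    construction.
    """
    cfg = cfg or ActiveEventConfig()
    spike_times = np.atleast_1d(np.asarray(spike_times, dtype=float))
    if duration is None:
        last = max([0.0, *spike_times.tolist(), *list(plateau_onsets)])
        duration = last + 150.0
    n = int(round(duration / dt)) + 1
    t = dt * np.arange(n)
    u = np.full(n, rest)
    for ts in spike_times:
        u += bap_contribution(cfg, distance, t - ts)
    for po in plateau_onsets:
        u += plateau_contribution(cfg, distance, t - po)
    return VoltageTrace(0.0, dt, np.clip(u, V_FLOOR, V_CEIL))


def detect_dendritic_spikes(trace: VoltageTrace, threshold: float = -30.0,
                            min_duration: float = 10.0) -> list[tuple[float, float]]:
    """Intervals (start, end) ms where the voltage stays above ``threshold``
    for at least ``min_duration`` ms."""
    above = trace.samples >= threshold
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]
    out = []
    for s, e in zip(starts, ends):
        if (e - s) * trace.dt >= min_duration:
            out.append((trace.t0 + s * trace.dt, trace.t0 + e * trace.dt))
    return out


# -- stimuli and synapses -----------------------------------------------------

@dataclass(frozen=True)
class StepCurrent:
    """Somatic step-current train: ``count`` pulses of ``duration`` ms and
    ``amplitude`` nA at ``frequency`` Hz starting at ``onset`` ms."""

    onset: float
    duration: float
    amplitude: float
    count: int = 1
    frequency: float = 1.0
    forced_ap: bool = True

    def pulse_onsets(self) -> np.ndarray:
        period = 1000.0 / self.frequency if self.count > 1 else 0.0
        return self.onset + period * np.arange(self.count)


@dataclass
class SynapsePlacement:
    """One synapse on the tree: location, conductance settings, events."""

    distance: float
    params: SynapseParams
    events: PresynEventTrain | None = None
    region: str = "apical"
    plastic: bool = False
    rate_hz: float | None = None       # Poisson rate if events is None
    w_pre: float = 0.5
    w_post: float = 2.0
    w_post_init: float = 2.0
    label: str = ""
    comp: int | None = None            # explicit compartment (overrides locate)


@dataclass
class SimResult:
    dt: float
    ap_times: np.ndarray
    plateau_onsets: np.ndarray
    site_traces: dict              # label -> VoltageTrace (total voltage)
    synapse_traces: list           # VoltageTrace per synapse (total voltage)
    synapse_events: list           # PresynEventTrain per synapse
    ca_trigger: np.ndarray | None = None  # low-passed zone trigger variable


class PassiveCable:
    """Implicit-Euler integrator for the passive tree (prefactorized)."""

    def __init__(self, morph: Morphology, dt: float = 0.025,
                 cm: float = 1.0, rm: float = 15000.0, ra: float = 150.0,
                 e_pas: float = E_REST, leak_gradient: float = 8.0,
                 leak_gradient_scale: float = 1200.0):
        self.morph = morph
        self.dt = dt
        self.e_pas = e_pas
        area = morph.area_cm2()
        self.c = area * cm * 1e3      # nF  (so C/dt * u is in nA, like g*u)
        # distance-dependent leak on the apical arbor (h-current surrogate):
        # keeps distal dendrites electrically isolated from slow somatic
        # charge, as in the detailed cell
        factor = np.ones(morph.n)
        apical = np.isin(morph.kind, ("apical", "tuft"))
        # grows along the trunk, saturates past the Ca2+ zone so thin tuft
        # branches keep a workable membrane time constant
        d_eff = np.minimum(morph.path_distance[apical], 700.0)
        factor[apical] += leak_gradient * (d_eff / leak_gradient_scale) ** 2
        self.g_pas = area / rm * 1e6 * factor  # uS
        n = morph.n
        # axial conductances (uS): series half-cylinder resistances
        d_cm = morph.diam * 1e-4
        l_cm = morph.length * 1e-4
        r_half = ra * (l_cm / 2.0) / (np.pi * d_cm ** 2 / 4.0)  # ohm
        rows, cols, vals = [], [], []
        diag = self.c / dt + self.g_pas
        for i in range(n):
            p = morph.parent[i]
            if p < 0:
                continue
            g = 1.0 / (r_half[i] + r_half[p]) * 1e6  # uS
            diag[i] += g
            diag[p] += g
            rows += [i, p]
            cols += [p, i]
            vals += [-g, -g]
        rows += list(range(n))
        cols += list(range(n))
        vals += list(diag)
        self._lu = splu(csc_matrix((vals, (rows, cols)), shape=(n, n)))

    def step(self, u: np.ndarray, i_inj: np.ndarray) -> np.ndarray:
        """One implicit step; ``i_inj`` in nA per compartment (inward +)."""
        rhs = self.c / self.dt * u + self.g_pas * self.e_pas + i_inj
        return self._lu.solve(rhs)


def simulate(morph: Morphology, active_cfg: ActiveEventConfig,
             stimuli: list[StepCurrent], synapses: list[SynapsePlacement],
             duration: float, dt: float = 0.025, seed: int | None = None,
             record_sites: dict | None = None,
             plasticity: PlasticityParams | None = None) -> SimResult:
    """Run the reduced neuron for ``duration`` ms.

    Synaptic conductances are solved locally implicitly (split step) so
    arbitrarily strong synapses on thin branches stay stable; bAP and
    plateau templates are composed additively with the cable solution and
    feed back into the synaptic driving force and Mg2+ unblock.
    Deterministic given ``seed`` (used only to draw Poisson event trains for
    placements that specify a rate instead of explicit events).
    """
    if dt <= 0.0:
        raise ValueError("dt must be > 0")
    for st in stimuli:
        if st.onset > duration:
            raise ValueError("stimulus outside simulation window")
    n_steps = int(round(duration / dt)) + 1
    n = morph.n
    cable = PassiveCable(morph, dt)
    plast = plasticity or PlasticityParams()

    # resolve synapse compartments and event trains
    ss = np.random.SeedSequence(0 if seed is None else seed)
    streams = ss.spawn(max(len(synapses), 1))
    syn_comp = np.array([s.comp if s.comp is not None
                         else morph.locate(s.distance, s.region)
                         for s in synapses], dtype=int)
    syn_events: list[PresynEventTrain] = []
    for j, s in enumerate(synapses):
        if s.events is not None:
            syn_events.append(s.events)
        elif s.rate_hz is not None:
            rng = np.random.default_rng(streams[j])
            p = s.rate_hz * 1e-3 * dt
            draws = rng.random(n_steps) < p
            syn_events.append(
                PresynEventTrain(dt * np.flatnonzero(draws)))
        else:
            syn_events.append(PresynEventTrain(np.array([])))
    ev_grid = np.zeros((len(synapses), n_steps))
    for j, tr in enumerate(syn_events):
        ev_grid[j] = tr.counts_on_grid(0.0, dt, n_steps)

    # per-synapse kernel constants
    n_syn = len(synapses)
    eps_a = np.array([s.params.kernel_ampa[1] for s in synapses])
    dec_aa = np.array([math.exp(-dt / s.params.tau_ampa_a) for s in synapses])
    dec_ab = np.array([math.exp(-dt / s.params.tau_ampa_b) for s in synapses])
    _, eps_g = plast.kernel_G
    dec_ga = math.exp(-dt / plast.tau_G_a)
    dec_gb = math.exp(-dt / plast.tau_G_b)
    g_max = np.array([s.params.g_max for s in synapses])
    s_ampa = np.array([s.params.s_ampa for s in synapses])
    s_nmda = np.array([s.params.s_nmda for s in synapses])
    e_syn = np.array([s.params.e_syn for s in synapses])
    w_pre = np.array([s.w_pre for s in synapses])
    w_post = np.array([s.w_post for s in synapses])
    w_post_init = np.array([s.w_post_init for s in synapses])
    gA_a = np.zeros(n_syn)
    gA_b = np.zeros(n_syn)
    G_a = np.zeros(n_syn)
    G_b = np.zeros(n_syn)

    # stimulus currents per step (soma compartment 0)
    i_stim = np.zeros(n_steps)
    forced_ap_times: list[float] = []
    for st in stimuli:
        for onset in st.pulse_onsets():
            k0 = int(round(onset / dt))
            k1 = int(round((onset + st.duration) / dt))
            i_stim[k0:min(k1, n_steps)] += st.amplitude
            if st.forced_ap:
                forced_ap_times.append(onset + active_cfg.ap_delay)
    forced_ap_times.sort()

    # boost conductance (blockable surrogate dendritic channels)
    area = morph.area_cm2()
    boost_mask = ((np.isin(morph.kind, ("apical", "tuft")))
                  & (morph.diam <= active_cfg.boost_diam_max))
    g_boost_max = np.where(
        boost_mask & (not active_cfg.channel_block),
        active_cfg.boost_density * area * 1e6, 0.0)  # uS

    dists = morph.path_distance
    zone_comp = morph.locate(active_cfg.ca_zone_distance, "apical")

    record_sites = record_sites or {}
    site_comp = {lbl: (morph.locate(d, "apical") if np.isscalar(d) else d)
                 for lbl, d in record_sites.items()}
    rec = {lbl: np.empty(n_steps) for lbl in site_comp}
    rec_syn = np.empty((n_syn, n_steps))
    rec_calp = np.empty(n_steps)

    u = np.full(n, E_REST)          # cable voltage
    # synapse-driven component alone (no stimulus injection, no boost):
    # the Ca2+ zone triggers on fast local depolarization — bAP templates
    # plus synaptic drive — not on slow passively spread somatic-injection
    # charge or on the boost's response to it (both artifacts of the
    # passive reduction, absent with the detailed cell's active channels)
    track_syn = n_syn > 0
    u_syn_cable = np.full(n, E_REST) if track_syn else None
    u_tot = u.copy()
    m_boost = np.zeros(n)           # boost activation
    h_boost = np.ones(n)            # boost inactivation
    ap_times: list[float] = []
    plateau_onsets: list[float] = []
    ca_lp = 0.0
    last_ap = -1e9
    prev_soma_below = True
    next_forced = 0
    c_over = cable.c  # uF per comp

    for k in range(n_steps):
        t = k * dt
        # --- active templates from existing events (evaluated at t)
        overlay_bap = np.zeros(n)
        for ts in ap_times[-8:]:
            if t - ts < 80.0 + dists.max() / active_cfg.bap_velocity:
                overlay_bap += bap_contribution(active_cfg, dists, t - ts)
        overlay = overlay_bap.copy()
        for po in plateau_onsets[-3:]:
            rel = t - po
            if -1.0 < rel < active_cfg.ca_rise + active_cfg.ca_duration \
                    + 6.0 * active_cfg.ca_fall:
                overlay += plateau_contribution(active_cfg, dists, rel)
        u_tot = np.clip(u + overlay, V_FLOOR, V_CEIL)

        # --- record
        for lbl, ci in site_comp.items():
            rec[lbl][k] = u_tot[ci]
        rec_syn[:, k] = u_tot[syn_comp]

        # --- somatic AP generation
        if next_forced < len(forced_ap_times) and \
                t >= forced_ap_times[next_forced] - 0.5 * dt:
            if t - last_ap >= active_cfg.ap_refractory * 0.5:
                ap_times.append(t)
                last_ap = t
            next_forced += 1
        soma_v = u_tot[0]
        if (soma_v >= active_cfg.ap_threshold and prev_soma_below
                and t - last_ap >= active_cfg.ap_refractory):
            ap_times.append(t)
            last_ap = t
        prev_soma_below = soma_v < active_cfg.ap_threshold

        # --- Ca2+ spike trigger: low-passed fast depolarization at the zone
        # (bAP templates + synaptically driven cable component), excluding
        # the plateau's own contribution (no self-excitation)
        u_trig = E_REST + active_cfg.ca_bap_gain * overlay_bap[zone_comp]
        if track_syn:
            u_trig += active_cfg.ca_syn_gain * (u_syn_cable[zone_comp]
                                                - E_REST)
        ca_lp += dt / active_cfg.ca_tau * (
            (min(u_trig, V_CEIL) - E_REST) - ca_lp)
        rec_calp[k] = ca_lp
        if (not active_cfg.channel_block
                and ca_lp >= active_cfg.ca_threshold
                and (not plateau_onsets
                     or t - plateau_onsets[-1] >= active_cfg.ca_refractory)):
            plateau_onsets.append(t + active_cfg.ca_delay)

        # --- synaptic kernels (event jumps then use-at-step, as in the rule)
        evk = ev_grid[:, k]
        gA_a = gA_a * dec_aa + eps_a * evk * g_max
        gA_b = gA_b * dec_ab + eps_a * evk * g_max
        G_a = G_a * dec_ga + eps_g * evk
        G_b = G_b * dec_gb + eps_g * evk
        u_syn = u_tot[syn_comp]
        g_ampa = s_ampa * w_post * (gA_b - gA_a)
        g_nmda = (s_nmda * w_post_init * np.tanh(plast.b_G * (G_b - G_a))
                  * g_max * mg_block(u_syn))
        g_syn = w_pre * (g_ampa + g_nmda) * 1e-3   # uS

        # --- split step A: local conductances, exponentially exact
        g_loc = np.zeros(n)
        gE_loc = np.zeros(n)
        np.add.at(g_loc, syn_comp, g_syn)
        np.add.at(gE_loc, syn_comp, g_syn * e_syn)
        if g_boost_max.any():
            m_inf = 1.0 / (1.0 + np.exp(-(u_tot - active_cfg.boost_vhalf)
                                        / active_cfg.boost_kslope))
            h_inf = 1.0 / (1.0 + np.exp((u_tot - active_cfg.boost_h_vhalf)
                                        / active_cfg.boost_h_kslope))
            m_boost += dt / active_cfg.boost_tau * (m_inf - m_boost)
            h_boost += dt / active_cfg.boost_h_tau * (h_inf - h_boost)
            gb = g_boost_max * m_boost * h_boost
            g_loc += gb
            gE_loc += gb * active_cfg.boost_erev
        active = g_loc > 0.0
        if active.any():
            e_loc = gE_loc[active] / g_loc[active]
            u_tot_a = u_tot[active]
            decay = np.exp(-g_loc[active] * dt / c_over[active])
            delta = (e_loc + (u_tot_a - e_loc) * decay) - u_tot_a
            u[active] += delta
        if track_syn and g_syn.any():
            # synapse-only component (boost excluded)
            dly = np.zeros(n)
            np.add.at(dly, syn_comp,
                      -(g_syn * (u_tot[syn_comp] - e_syn))
                      * dt / c_over[syn_comp])
            u_syn_cable += dly

        # --- split step B: passive cable, implicit
        i_inj = np.zeros(n)
        i_inj[0] = i_stim[k]
        u = cable.step(u, i_inj)
        if track_syn:
            u_syn_cable = cable.step(u_syn_cable, np.zeros(n))

    return SimResult(
        dt=dt,
        ap_times=np.asarray(ap_times),
        plateau_onsets=np.asarray(plateau_onsets),
        site_traces={lbl: VoltageTrace(0.0, dt, rec[lbl])
                     for lbl in site_comp},
        synapse_traces=[VoltageTrace(0.0, dt, rec_syn[j])
                        for j in range(n_syn)],
        synapse_events=syn_events,
        ca_trigger=rec_calp,
    )
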