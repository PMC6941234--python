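import math

import numpy as np
import pytest

from fourpath.core import PresynEventTrain
from fourpath.neuron import (
    ActiveEventConfig,
    MorphologyError,
    PassiveCable,
    PlacementError,
    SectionSpec,
    StepCurrent,
    SynapsePlacement,
    _build_from_sections,
    bap_playback,
    detect_dendritic_spikes,
    load_morphology,
    simulate,
)
from fourpath.params import SynapseParams


class TestMorphology:
    def test_builtin_preset_contract(self, morph):
        # all printed synapse sites must be resolvable on the apical path
        path_d = morph.path_distance[morph.apical_path]
        assert path_d.max() >= 1100.0
        for site in (90.0, 669.0, 672.0, 950.0, 1077.0):
            idx = morph.locate(site, "apical")
            assert abs(morph.path_distance[idx] - site) < 30.0
        assert morph.locate(55.0, "basal") >= 0
        assert morph.apical_sites(41).size == 41

    def test_tree_has_no_cycles(self, morph):
        for i in range(morph.n):
            seen, j = set(), i
            while j >= 0:
                assert j not in seen
                seen.add(j)
                j = morph.parent[j]

    def test_path_distance_monotone_along_apical_path(self, morph):
        d = morph.path_distance[morph.apical_path]
        assert np.all(np.diff(d) > 0)

    def test_unreachable_distance_rejected(self, morph):
        with pytest.raises(PlacementError):
            morph.locate(5000.0, "apical")
        with pytest.raises(PlacementError):
            morph.locate(100.0, "no_such_region")


class TestSWC:
    def test_toy_path_distance(self, tmp_path):
        # 3 collinear points, 10 um apart: tip distance = sum of segments
        f = tmp_path / "toy.swc"
        f.write_text("# toy\n"
                     "1 1 0 0 0 5 -1\n"
                     "2 3 10 0 0 1 1\n"
                     "3 3 20 0 0 1 2\n")
        m = load_morphology(f)
        assert m.n == 3
        assert m.path_distance[2] == pytest.approx(20.0)

    def test_cycle_rejected(self, tmp_path):
        f = tmp_path / "cycle.swc"
        f.write_text("1 1 0 0 0 5 3\n"
                     "2 3 10 0 0 1 1\n"
                     "3 3 20 0 0 1 2\n")
        with pytest.raises(MorphologyError, match="cycle"):
            load_morphology(f)

    def test_malformed_line_reports_number(self, tmp_path):
        f = tmp_path / "bad.swc"
        f.write_text("1 1 0 0 0 5 -1\nnot a record\n")
        with pytest.raises(MorphologyError, match=":2"):
            load_morphology(f)

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            load_morphology("/nonexistent/cell.swc")


class TestPassiveCable:
    def test_steady_state_attenuation_matches_analytic(self):
        # uniform sealed cylinder, constant current at one end: the voltage
        # profile follows cosh((L-x)/lambda)/cosh(L/lambda)
        rm, ra, diam_um, length_um = 15000.0, 150.0, 2.0, 1000.0
        m = _build_from_sections([
            SectionSpec("cable", None, length_um, diam_um, diam_um, 100,
                        "basal")])
        cable = PassiveCable(m, dt=0.1, rm=rm, ra=ra, leak_gradient=0.0)
        u = np.full(m.n, -75.0)
        i_inj = np.zeros(m.n)
        i_inj[0] = 0.05  # nA
        for _ in range(6000):  # 600 ms >> membrane tau
            u = cable.step(u, i_inj)
        profile = u + 75.0
        lam = math.sqrt(rm * (diam_um * 1e-4) / (4.0 * ra))  # cm
        x = m.path_distance * 1e-4
        L = length_um * 1e-4
        ref = np.cosh((L - x) / lam) / math.cosh(L / lam)
        rel = np.abs(profile / profile[0] - ref / ref[0]) / (ref / ref[0])
        assert rel.max() < 0.02

    def test_rest_is_stable(self, morph, active_cfg):
        res = simulate(morph, active_cfg, [], [], 100.0,
                       record_sites={"soma": 0.0, "mid": 300.0,
                                     "tip": 1180.0})
        for tr in res.site_traces.values():
            assert np.all(np.abs(tr.samples + 75.0) < 0.5)


class TestActiveEvents:
    def test_burst_evokes_one_ap_per_pulse_and_attenuates(self, morph,
                                                          active_cfg):
        stim = StepCurrent(onset=100.0, duration=5.0, amplitude=2.7,
                           count=5, frequency=50.0)
        res = simulate(morph, active_cfg, [stim], [], 400.0,
                       record_sites={"prox": 90.0, "distal": 669.0})
        assert len(res.ap_times) == 5
        prox = res.site_traces["prox"].samples.max()
        distal = res.site_traces["distal"].samples.max()
        assert prox > distal + 30.0  # strong bAP attenuation
        assert len(res.plateau_onsets) == 0

    def test_rapid_triplet_triggers_delayed_plateau(self, morph, active_cfg):
        stim = StepCurrent(onset=100.0, duration=2.0, amplitude=5.5,
                           count=3, frequency=200.0)
        res = simulate(morph, active_cfg, [stim], [], 400.0,
                       record_sites={"distal": 669.0})
        assert len(res.plateau_onsets) == 1
        delay = res.plateau_onsets[0] - res.ap_times[0]
        assert 12.0 < delay < 28.0  # plateau ~20 ms after the first AP
        spikes = detect_dendritic_spikes(res.site_traces["distal"],
                                         threshold=-40.0, min_duration=10.0)
        assert len(spikes) == 1
        # plateau outlasts an AP by far
        assert spikes[0][1] - spikes[0][0] > 5.0 * 3.0

    def test_voltage_stays_in_physiological_window(self, morph, active_cfg):
        stim = StepCurrent(onset=50.0, duration=2.0, amplitude=5.5,
                           count=3, frequency=200.0)
        res = simulate(morph, active_cfg, [stim], [], 300.0,
                       record_sites={f"s{i}": float(d) for i, d in
                                     enumerate(range(0, 1150, 100))})
        for tr in res.site_traces.values():
            assert tr.samples.max() <= 50.0 and tr.samples.min() >= -100.0

    def test_channel_block_never_boosts_epsps(self, morph, active_cfg):
        sp = SynapseParams(g_max=2.5, s_ampa=0.8, s_nmda=0.2)
        for site in (900.0, 1100.0, 1180.0):
            syns = [SynapsePlacement(distance=site, params=sp,
                                     events=PresynEventTrain(
                                         np.array([100.0 + 0.1 * j])),
                                     region="apical") for j in range(4)]
            ctrl = simulate(morph, active_cfg, [], syns, 300.0,
                            record_sites={"s": site})
            blk = simulate(morph, active_cfg.blocked(), [], syns, 300.0,
                           record_sites={"s": site})
            assert blk.site_traces["s"].samples.max() \
                <= ctrl.site_traces["s"].samples.max() + 1e-9


class TestBapPlayback:
    def test_empty_spike_list_is_flat(self):
        tr = bap_playback(90.0, [], duration=100.0)
        assert np.all(tr.samples == -75.0)

    def test_peak_decreases_with_distance(self):
        spikes = [50.0, 70.0]
        peaks = [bap_playback(d, spikes).samples.max()
                 for d in (30.0, 90.0, 300.0, 669.0, 1000.0)]
        assert np.all(np.diff(peaks) < 0)

    def test_template_superposition(self):
        cfg = ActiveEventConfig()
        a = bap_playback(90.0, [50.0], cfg, duration=200.0)
        b = bap_playback(90.0, [70.0], cfg, duration=200.0)
        ab = bap_playback(90.0, [50.0, 70.0], cfg, duration=200.0)
        super_ = a.samples + b.samples + 75.0
        # linear superposition wherever the clip ceiling is not hit
        mask = super_ < 49.0
        assert np.allclose(ab.samples[mask], super_[mask], atol=1e-9)


class TestDetectDendriticSpikes:
    def test_flat_trace(self):
        tr = bap_playback(90.0, [], duration=100.0)
        assert detect_dendritic_spikes(tr, -30.0, 10.0) == []

    def test_synthetic_plateau_counted_once(self):
        from fourpath.core import VoltageTrace

        u = np.full(8001, -75.0)
        u[2000:3600] = -20.0  # 40 ms plateau at dt=0.025
        tr = VoltageTrace(0.0, 0.025, u)
        events = detect_dendritic_spikes(tr, -30.0, 10.0)
        assert len(events) == 1
        start, end = events[0]
        assert end - start == pytest.approx(40.0, abs=0.1)

    def test_brief_crossings_filtered(self):
        from fourpath.core import VoltageTrace

        u = np.full(8001, -75.0)
        u[1000:1200] = -20.0  # 5 ms
        u[3000:3240] = -20.0  # 6 ms
        tr = VoltageTrace(0.0, 0.025, u)
        assert detect_dendritic_spikes(tr, -30.0, 10.0) == []
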