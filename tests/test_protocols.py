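import numpy as np
import pytest

from fourpath.params import read_parameter_set
from fourpath.protocols import (
    PROTOCOL_PRESETS,
    BurstPattern,
    PlasticityWindow,
    burst_pairing_experiment,
    extrapolate_sweeps,
    heterosynaptic_experiment,
    relative_change,
    spatiotemporal_window,
)


class TestPresetTable:
    """The preset constants are the protocols' published stimulus numbers;
    they are frozen here so accidental edits fail loudly."""

    def test_step_currents(self):
        bp = PROTOCOL_PRESETS["burst_pairing"]
        assert (bp["step_ms"], bp["step_na"]) == (5.0, 2.7)
        bt = PROTOCOL_PRESETS["burst_timing"]
        assert (bt["step_ms"], bt["step_na"]) == (5.0, 2.1)
        ds = PROTOCOL_PRESETS["dendritic_spike"]
        assert (ds["step_ms"], ds["step_na"]) == (2.0, 5.5)
        assert (ds["post_spikes"], ds["post_freq_hz"]) == (3, 200.0)

    def test_sweep_counts_and_sites(self):
        assert PROTOCOL_PRESETS["vclamp"]["sweeps"] == 10
        bp = PROTOCOL_PRESETS["burst_pairing"]
        assert (bp["sweeps_low"], bp["sweeps"]) == (10, 15)
        assert bp["sites_um"] == (90.0, 669.0)
        assert bp["frequencies_hz"] == (0.1, 10.0, 20.0, 40.0, 50.0)
        assert PROTOCOL_PRESETS["burst_timing"]["sweeps"] == 60
        assert PROTOCOL_PRESETS["burst_timing"]["site_um"] == 55.0
        assert PROTOCOL_PRESETS["dendritic_spike"]["sweeps"] == 100
        assert PROTOCOL_PRESETS["cluster"]["sweeps"] == 50
        assert PROTOCOL_PRESETS["cluster"]["interval_ms"] == 0.1

    def test_synapse_settings(self):
        for name in ("burst_pairing", "burst_timing", "dendritic_spike"):
            pr = PROTOCOL_PRESETS[name]
            assert (pr["g_max"], pr["s_ampa"], pr["s_nmda"]) \
                == (3.5, 0.5, 0.5)
        cl = PROTOCOL_PRESETS["cluster"]
        assert (cl["g_max"], cl["s_ampa"], cl["s_nmda"]) == (2.5, 0.8, 0.2)
        bt = PROTOCOL_PRESETS["basal_tuft"]
        assert (bt["n_basal_bg"], bt["n_tuft_bg"]) == (50, 300)
        assert (bt["basal_site_um"], bt["apical_site_um"]) == (32.0, 672.0)
        assert bt["rate_hz"] == 10.0 and bt["window_ms"] == 100.0
        he = PROTOCOL_PRESETS["hetero"]
        assert he["cluster_size"] == 8
        assert he["sites_um"] == (950.0, 1077.0)
        assert he["duration_ms"] == 350.0
        assert (he["sin_freq_hz"], he["sin_amp"], he["sin_offset"]) \
            == (8.0, 0.05, 0.005)

    def test_window_grid(self):
        w = PROTOCOL_PRESETS["window"]
        lo, hi = w["timing_range_ms"]
        n_timings = int(round((hi - lo) / w["timing_step_ms"])) + 1
        assert n_timings == 101
        assert w["n_sites"] * n_timings == 4141


class TestExtrapolation:
    def test_no_change_is_identity(self, set1):
        for n in (1, 10, 100):
            w = extrapolate_sweeps(set1.w_pre_init, set1.w_post_init, n, set1)
            assert w == pytest.approx(set1.w_pre_init * set1.w_post_init)

    def test_single_sweep_is_product(self, set1):
        assert extrapolate_sweeps(0.6, 2.4, 1, set1) \
            == pytest.approx(0.6 * 2.4)

    def test_factors_clipped_before_product(self, set1):
        # large per-sweep gains saturate at the hard bounds 1 and 5
        w = extrapolate_sweeps(0.9, 4.0, 50, set1)
        assert w == pytest.approx(1.0 * 5.0)
        assert extrapolate_sweeps(0.0, 0.0, 50, set1) == 0.0

    def test_invalid_sweep_count(self, set1):
        with pytest.raises(ValueError):
            extrapolate_sweeps(0.5, 2.0, 0, set1)

    def test_matches_explicit_sweeps_without_clipping(self):
        # n=3 explicit single-sweep repetitions == linear extrapolation
        r_extr = burst_pairing_experiment(10.0, 10.0, 90.0, "set1", sweeps=3)
        r_expl = burst_pairing_experiment(10.0, 10.0, 90.0, "set1", sweeps=3,
                                          explicit_sweeps=True)
        assert r_expl == pytest.approx(r_extr, abs=1e-9)

    def test_relative_change_scale(self, set1):
        assert relative_change(1.0, set1) == pytest.approx(1.0)
        assert relative_change(1.5, set1) == pytest.approx(1.5)


class TestBurstPattern:
    def test_description(self):
        assert BurstPattern(1, 3, 50.0, -10.0).describe() \
            == "1pre+3post@50Hz,dt=-10ms"


class TestWindow:
    def test_shape_validation(self):
        with pytest.raises(ValueError):
            PlasticityWindow(np.arange(3.0), np.arange(4.0),
                             np.zeros((4, 3)), 12)

    def test_small_window_end_to_end(self, morph, active_cfg):
        w = spatiotemporal_window("burst_pairing", frequency=10.0,
                                  timings=np.array([-30.0, 0.0, 30.0]),
                                  n_sites=5, morph=morph, cfg=active_cfg)
        assert w.matrix.shape == (5, 3)
        assert w.n_simulations == 15
        assert np.all(np.isfinite(w.matrix))
        # distant timings at the proximal site change weights less than
        # near-coincident ones
        assert abs(w.matrix[0, 1] - 1.0) >= abs(w.matrix[0, 0] - 1.0) - 0.25


class TestStochasticProtocols:
    def test_hetero_deterministic_given_seed(self):
        a = heterosynaptic_experiment("synchronized", "uniform", seed=7)
        b = heterosynaptic_experiment("synchronized", "uniform", seed=7)
        assert a["mean_r_a"] == b["mean_r_a"]
        assert a["mean_r_b"] == b["mean_r_b"]
        assert np.array_equal(a["voltage_a"].samples, b["voltage_a"].samples)

    def test_hetero_invalid_mode(self):
        with pytest.raises(ValueError):
            heterosynaptic_experiment("bursty", "uniform", seed=0)


class TestParameterSetsAreCalibrated:
    def test_post_ltd_amplitude_low_relative_to_post_ltp(self):
        # shared design property of all shipped sets
        for name in ("set1", "set2", "set3"):
            p = read_parameter_set(name)
            assert p.a_post_ltd < 0.1 * p.a_post_ltp
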