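"""Synthetic voltage and event fixtures.

These emulate the signal structure the plasticity rule consumes — resting
baselines, backpropagating-AP trains with distance-dependent attenuation,
long Ca2+-spike plateaus, EPSP-like bumps, Poisson event trains and
sinusoidally modulated activation — without running the neuron model.
Generation is pure: the same spec always yields the same output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import PresynEventTrain, VoltageTrace
from .neuron import ActiveEventConfig, E_REST, bap_playback, \
    plateau_contribution
from .params import double_exp_kernel

__all__ = ["FixtureSpec", "generate_fixture"]

_KINDS = ("flat", "bap_train", "plateau", "epsp_bump", "poisson_train",
          "sinusoidal_train")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic fixture; ``kind`` selects the generator and
    ``options`` carries kind-specific parameters."""

    kind: str
    duration: float = 500.0      # ms
    dt: float = 0.025
    seed: int = 0
    options: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; "
                             f"one of {_KINDS}")


def generate_fixture(spec: FixtureSpec):
    """Build the fixture; returns a VoltageTrace or a PresynEventTrain."""
    o = spec.options
    n = int(round(spec.duration / spec.dt)) + 1
    t = spec.dt * np.arange(n)
    if spec.kind == "flat":
        return VoltageTrace.constant(o.get("u", E_REST), spec.duration,
                                     spec.dt)
    if spec.kind == "bap_train":
        return bap_playback(o.get("distance", 90.0),
                            o.get("spike_times", [100.0]),
                            o.get("config", ActiveEventConfig()),
                            duration=spec.duration, dt=spec.dt)
    if spec.kind == "plateau":
        cfg = o.get("config", ActiveEventConfig())
        u = np.full(n, E_REST) + plateau_contribution(
            cfg, o.get("distance", cfg.ca_zone_distance),
            t - o.get("onset", 100.0))
        return VoltageTrace(0.0, spec.dt, u)
    if spec.kind == "epsp_bump":
        tau_r = o.get("tau_rise", 1.0)
        tau_d = o.get("tau_decay", 15.0)
        _, eps = double_exp_kernel(tau_r, tau_d)
        rel = t - o.get("onset", 100.0)
        shape = np.where(rel < 0, 0.0,
                         eps * (np.exp(-np.maximum(rel, 0) / tau_d)
                                - np.exp(-np.maximum(rel, 0) / tau_r)))
        return VoltageTrace(0.0, spec.dt,
                            E_REST + o.get("amplitude", 10.0) * shape)
    if spec.kind == "poisson_train":
        rate = o.get("rate_hz", 10.0)
        if rate < 0:
            raise ValueError("rate must be >= 0")
        rng = np.random.default_rng(spec.seed)
        hits = rng.random(n) < rate * 1e-3 * spec.dt
        return PresynEventTrain(t[hits])
    if spec.kind == "sinusoidal_train":
        # activation probability per 1-ms bin: max(0, offset + amp*sin)
        amp = o.get("amplitude", 0.05)
        offset = o.get("offset", 0.005)
        freq = o.get("freq_hz", 8.0)
        n_bins = int(spec.duration)
        tb = np.arange(n_bins, dtype=float)
        prob = np.maximum(offset + amp * np.sin(2 * np.pi * freq * tb / 1e3),
                          0.0)
        rng = np.random.default_rng(spec.seed)
        hits = rng.random(n_bins) < prob
        return PresynEventTrain(tb[hits] + 0.5)
    raise AssertionError("unreachable")
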