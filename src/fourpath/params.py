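"""Parameter containers for the plasticity rule and the synapse model.

The plasticity rule is driven entirely by the local membrane potential ``u``
(in mV, used as a bare number) and the times of presynaptic release events.
Every filtered trace is first-order with a time constant ``tau_*`` (ms) and is
squashed by ``tanh(b * x)`` where the slope ``b`` derives from a saturation
parameter ``m > 1`` via ``b = ln(m)/2`` — chosen so that ``tanh(b * 1)``
equals ``(m - 1)/(m + 1)``, i.e. ``m`` directly sets how strongly a unit
input saturates.

Presynaptic event traces (Z, G and the AMPA conductance) are differences of
two exponentials. A single event makes the difference peak at exactly 1 at
time ``omega`` after the event; ``epsilon`` is the jump applied to both
components that achieves this normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "PlasticityParams",
    "SynapseParams",
    "saturating_slope",
    "double_exp_kernel",
    "read_parameter_set",
    "write_parameter_set",
    "preset_names",
]

PATHWAYS = ("pre_ltd", "pre_ltp", "post_ltd", "post_ltp")

W_PRE_BOUNDS = (0.0, 1.0)
W_POST_BOUNDS = (0.0, 5.0)


class ParameterError(ValueError):
    """Raised when a parameter value violates a model invariant."""


def saturating_slope(m: float) -> float:
    """Slope ``b`` of the tanh saturation for saturation parameter ``m``.

    ``b = ln(m)/2`` so that ``tanh(b * 1) = (m - 1)/(m + 1)``.

    Parameters
    ----------
    m : float
        Saturation parameter, must be > 1 (``m -> 1`` removes saturation).
    """
    if not m > 1.0:
        raise ParameterError(f"saturation parameter must be > 1, got {m}")
    return 0.5 * math.log(m)


def double_exp_kernel(tau_a: float, tau_b: float) -> tuple[float, float]:
    """Peak time ``omega`` and normalization ``epsilon`` of a
    difference-of-exponentials kernel.

    For a kernel ``epsilon * (exp(-t/tau_b) - exp(-t/tau_a))`` started by a
    unit event, the peak occurs at
    ``omega = tau_a*tau_b/(tau_b - tau_a) * ln(tau_b/tau_a)`` and ``epsilon``
    is chosen such that the peak value is exactly 1.

    Returns
    -------
    (omega, epsilon) : tuple of float
        Peak time (ms) and event-jump size (unitless).
    """
    if not (tau_b > tau_a > 0.0):
        raise ParameterError(
            f"need tau_b > tau_a > 0, got tau_a={tau_a}, tau_b={tau_b}"
        )
    omega = tau_a * tau_b / (tau_b - tau_a) * math.log(tau_b / tau_a)
    epsilon = 1.0 / (math.exp(-omega / tau_b) - math.exp(-omega / tau_a))
    return omega, epsilon


@dataclass(frozen=True)
class PlasticityParams:
    """All constants of the four-pathway plasticity rule.

    Time constants in ms, voltage thresholds in mV (absolute scale, resting
    potential around -75 mV lies below all of them), everything else
    unitless. The four amplitudes ``a_pre_ltd`` .. ``a_post_ltp`` set the
    impact of each pathway; ``eta`` (per ms) makes the three continuously
    integrated pathways invariant to the integration step.
    """

    # -- pre-LTD: low-pass of supra-threshold voltage, sampled at events
    tau_T: float = 10.0
    theta_u_T: float = -60.0
    m_T: float = 1.7
    # -- pre-LTP: two chained voltage filters (N) x slow event trace (Z)
    tau_N_alpha: float = 10.0
    tau_N_beta: float = 150.0
    theta_u_N: float = -30.0
    m_N_alpha: float = 2.0
    m_N_beta: float = 10.0
    theta_N: float = 0.3
    tau_Z_a: float = 1.0
    tau_Z_b: float = 15.0
    m_Z: float = 6.0
    # -- post pathways: glutamate trace (G) x supra-threshold voltage -> C
    tau_G_a: float = 2.0
    tau_G_b: float = 50.0
    m_G: float = 10.0
    theta_u_C: float = -68.0
    theta_C_minus: float = 15.0
    theta_C_plus: float = 35.0
    # -- post-LTP cascade
    m_K_alpha: float = 1.5
    tau_K_beta: float = 15.0
    m_K_beta: float = 1.7
    s_K_beta: float = 10.0
    tau_K_gamma: float = 20.0
    # -- pathway amplitudes and learning rate
    a_pre_ltd: float = 1.0
    a_pre_ltp: float = 1.0
    a_post_ltd: float = 1.0
    a_post_ltp: float = 1.0
    eta: float = 0.025
    # -- weight factors
    w_pre_init: float = 0.5
    w_post_init: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "tau_T", "tau_N_alpha", "tau_N_beta", "tau_Z_a", "tau_Z_b",
            "tau_G_a", "tau_G_b", "tau_K_beta", "tau_K_gamma",
        ):
            if not getattr(self, name) > 0.0:
                raise ParameterError(f"{name} must be > 0")
        for name in ("m_T", "m_N_alpha", "m_N_beta", "m_Z", "m_G",
                     "m_K_alpha", "m_K_beta"):
            if not getattr(self, name) > 1.0:
                raise ParameterError(f"{name} must be > 1")
        for name in ("a_pre_ltd", "a_pre_ltp", "a_post_ltd", "a_post_ltp"):
            if getattr(self, name) < 0.0:
                raise ParameterError(f"{name} must be >= 0")
        if not self.theta_C_plus > self.theta_C_minus:
            raise ParameterError("theta_C_plus must exceed theta_C_minus")
        if not self.eta > 0.0:
            raise ParameterError("eta must be > 0")
        if not self.s_K_beta > 0.0:
            raise ParameterError("s_K_beta must be > 0")
        if not self.tau_Z_b > self.tau_Z_a:
            raise ParameterError("tau_Z_b must exceed tau_Z_a")
        if not self.tau_G_b > self.tau_G_a:
            raise ParameterError("tau_G_b must exceed tau_G_a")
        lo, hi = W_PRE_BOUNDS
        if not lo <= self.w_pre_init <= hi:
            raise ParameterError(f"w_pre_init outside {W_PRE_BOUNDS}")
        lo, hi = W_POST_BOUNDS
        if not lo <= self.w_post_init <= hi:
            raise ParameterError(f"w_post_init outside {W_POST_BOUNDS}")

    # cached derived constants ------------------------------------------------

    @property
    def b_T(self) -> float:
        return saturating_slope(self.m_T)

    @property
    def b_N_alpha(self) -> float:
        return saturating_slope(self.m_N_alpha)

    @property
    def b_N_beta(self) -> float:
        return saturating_slope(self.m_N_beta)

    @property
    def b_Z(self) -> float:
        return saturating_slope(self.m_Z)

    @property
    def b_G(self) -> float:
        return saturating_slope(self.m_G)

    @property
    def b_K_alpha(self) -> float:
        return saturating_slope(self.m_K_alpha)

    @property
    def b_K_beta(self) -> float:
        return saturating_slope(self.m_K_beta)

    @property
    def kernel_Z(self) -> tuple[float, float]:
        """(omega, epsilon) of the Z event kernel."""
        return double_exp_kernel(self.tau_Z_a, self.tau_Z_b)

    @property
    def kernel_G(self) -> tuple[float, float]:
        """(omega, epsilon) of the G event kernel."""
        return double_exp_kernel(self.tau_G_a, self.tau_G_b)

    @property
    def p_norm(self) -> float:
        """Divisor normalizing the quadratic post-LTD activation to max 1."""
        return ((self.theta_C_plus - self.theta_C_minus) / 2.0) ** 2

    def block(self, pathway: str) -> "PlasticityParams":
        """Copy with one pathway's amplitude set to zero.

        ``pathway`` is one of ``pre_ltd``, ``pre_ltp``, ``post_ltd``,
        ``post_ltp`` (mimics pharmacological blockade of that route).
        """
        if pathway not in PATHWAYS:
            raise ParameterError(
                f"unknown pathway {pathway!r}; expected one of {PATHWAYS}"
            )
        return replace(self, **{f"a_{pathway}": 0.0})

    def scaled(self, name: str, factor: float) -> "PlasticityParams":
        """Copy with one named parameter multiplied by ``factor``."""
        if name not in {f.name for f in fields(self)}:
            raise ParameterError(f"unknown parameter {name!r}")
        return replace(self, **{name: getattr(self, name) * factor})


@dataclass(frozen=True)
class SynapseParams:
    """AMPA/NMDA synapse constants.

    ``g_max`` (nS) is the peak conductance scale; ``s_ampa`` / ``s_nmda``
    split it between receptor types. The NMDA Mg2+ block is the sigmoid
    ``1/(1 + exp(-mg_slope*u)/mg_scale)`` of local voltage ``u`` (mV).
    """

    g_max: float = 3.5
    s_ampa: float = 0.5
    s_nmda: float = 0.5
    tau_ampa_a: float = 0.2
    tau_ampa_b: float = 2.0
    tau_nmda_a: float = 2.0
    tau_nmda_b: float = 50.0
    e_syn: float = 0.0
    mg_slope: float = 0.08
    mg_scale: float = 3.57

    def __post_init__(self) -> None:
        if not self.g_max > 0.0:
            raise ParameterError("g_max must be > 0")
        if self.s_ampa < 0.0 or self.s_nmda < 0.0:
            raise ParameterError("receptor ratios must be >= 0")
        if not self.tau_ampa_b > self.tau_ampa_a > 0.0:
            raise ParameterError("need tau_ampa_b > tau_ampa_a > 0")
        if not self.tau_nmda_b > self.tau_nmda_a > 0.0:
            raise ParameterError("need tau_nmda_b > tau_nmda_a > 0")

    @property
    def kernel_ampa(self) -> tuple[float, float]:
        """(omega, epsilon) of the AMPA conductance kernel."""
        return double_exp_kernel(self.tau_ampa_a, self.tau_ampa_b)


# -- parameter-set files ------------------------------------------------------

_FIELD_NAMES = {f.name for f in fields(PlasticityParams)}


def preset_names() -> list[str]:
    """Names of the parameter sets shipped with the package."""
    pkg_data = resources.files("fourpath") / "data"
    return sorted(
        p.name.removesuffix(".yaml")
        for p in pkg_data.iterdir()
        if p.name.endswith(".yaml")
    )


def read_parameter_set(source: str | Path) -> PlasticityParams:
    """Load a plasticity parameter set from a preset name or a YAML file.

    The file format is one mapping with a ``plasticity`` section of
    ``field: value`` pairs. Unknown keys are rejected and every loaded set is
    validated against the full invariant list.
    """
    path = Path(source)
    if not path.suffix and not path.exists():
        candidate = resources.files("fourpath") / "data" / f"{source}.yaml"
        if not candidate.is_file():
            raise FileNotFoundError(
                f"unknown preset {source!r}; shipped presets: {preset_names()}"
            )
        text = candidate.read_text()
    else:
        text = path.read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "plasticity" not in doc:
        raise ParameterError("parameter file needs a 'plasticity' section")
    section = doc["plasticity"]
    unknown = set(section) - _FIELD_NAMES
    if unknown:
        raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
    return PlasticityParams(**{k: float(v) for k, v in section.items()})


def write_parameter_set(params: PlasticityParams, path: str | Path) -> None:
    """Write a parameter set to YAML, round-trippable via
    :func:`read_parameter_set`."""
    doc = {"plasticity": {f.name: getattr(params, f.name)
                          for f in fields(PlasticityParams)}}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
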