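"""Two-stage parameter fitting and one-at-a-time sensitivity analysis.

The shipped parameter sets were produced with this machinery: stage 1
adjusts time constants, thresholds and saturation slopes against qualitative
targets (band edges, kernel shapes); stage 2 freezes those and fine-tunes
only the four pathway amplitudes against protocol outcomes. "Manual search"
is mechanized as deterministic coordinate descent over bounded
multiplicative grids so the presets are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import PresynEventTrain, VoltageTrace, run_rule
from .params import PlasticityParams

__all__ = ["CalibrationTarget", "FitResult", "fit_parameters",
           "sensitivity_scan", "rest_activation_flags"]

STAGE1_NAMES = (
    "tau_T", "theta_u_T", "m_T", "tau_N_alpha", "tau_N_beta", "theta_u_N",
    "m_N_alpha", "m_N_beta", "theta_N", "tau_Z_a", "tau_Z_b", "m_Z",
    "tau_G_a", "tau_G_b", "m_G", "theta_u_C", "theta_C_minus",
    "theta_C_plus", "m_K_alpha", "tau_K_beta", "m_K_beta", "s_K_beta",
    "tau_K_gamma",
)
STAGE2_NAMES = ("a_pre_ltd", "a_pre_ltp", "a_post_ltd", "a_post_ltp")


@dataclass(frozen=True)
class CalibrationTarget:
    """One calibration constraint on an observable of the model.

    ``observable`` maps a parameter set to a scalar (e.g. the relative
    weight change of a protocol preset). ``kind`` is ``value`` (squared
    error against ``target`` scaled by ``tolerance``) or ``sign``
    (hinge penalty unless sign(observable - 1) matches sign(target)).
    """

    name: str
    observable: Callable[[PlasticityParams], float]
    target: float
    kind: str = "value"
    tolerance: float = 1.0
    weight: float = 1.0

    def penalty(self, params: PlasticityParams) -> float:
        v = self.observable(params)
        if self.kind == "value":
            return self.weight * ((v - self.target) / self.tolerance) ** 2
        if self.kind == "sign":
            margin = (v - 1.0) * np.sign(self.target)
            return self.weight * max(0.0, self.tolerance - margin) ** 2
        raise ValueError(f"unknown target kind {self.kind!r}")


@dataclass
class FitResult:
    params: PlasticityParams
    loss: float
    residuals: dict
    history: list = field(default_factory=list)

    def worst_offenders(self, k: int = 3) -> list[str]:
        return sorted(self.residuals, key=self.residuals.get)[::-1][:k]


def _total_loss(params, targets):
    return float(sum(t.penalty(params) for t in targets))


def fit_parameters(start: PlasticityParams,
                   targets: Sequence[CalibrationTarget], stage: int = 2,
                   factors: Sequence[float] = (0.5, 0.8, 1.25, 2.0),
                   rounds: int = 2, seed: int = 0,
                   names: Sequence[str] | None = None) -> FitResult:
    """Deterministic coordinate descent on one stage's parameter group.

    Stage 1 searches kinetics/threshold/slope parameters with amplitudes
    frozen; stage 2 searches only the four pathway amplitudes. Each round
    visits every free parameter in a fixed order (shuffled reproducibly by
    ``seed``) and keeps the best multiplicative factor. Returns the fitted
    set with its residuals; infeasible targets remain visible as the worst
    offenders rather than failing silently.
    """
    if stage not in (1, 2):
        raise ValueError("stage must be 1 or 2")
    free = list(names if names is not None
                else (STAGE1_NAMES if stage == 1 else STAGE2_NAMES))
    targets = list(targets)
    if not targets:
        return FitResult(start, 0.0, {})
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(free)))
    params = start
    loss = _total_loss(params, targets)
    history = [loss]
    for _ in range(rounds):
        for i in order:
            name = free[i]
            best = (loss, params)
            for f in factors:
                try:
                    cand = params.scaled(name, f)
                except Exception:
                    continue
                cl = _total_loss(cand, targets)
                if cl < best[0] - 1e-12:
                    best = (cl, cand)
            loss, params = best
            history.append(loss)
    residuals = {t.name: t.penalty(params) for t in targets}
    return FitResult(params, loss, residuals, history)


def rest_activation_flags(params: PlasticityParams, rest: float = -75.0,
                          duration: float = 400.0) -> dict:
    """True per pathway indicator that is active at resting potential with a
    single presynaptic event (a pathological regime)."""
    trace = VoltageTrace.constant(rest, duration)
    events = PresynEventTrain(np.array([duration / 2.0]))
    traj = run_rule(trace, events, params, log_traces=True)
    tr = traj.traces
    tol = 1e-12
    return dict(
        pre_ltd=bool(np.max(tr["E"]) > tol),
        pre_ltp=bool(np.max(tr["X"]) > tol),
        post_ltd=bool(np.max(tr["P"]) > tol),
        post_ltp=bool(np.max(tr["K"]) > tol),
    )


def sensitivity_scan(params: PlasticityParams,
                     observables: dict[str, Callable[[PlasticityParams], float]],
                     factors: Sequence[float] = (0.5, 0.8, 1.25, 2.0),
                     names: Sequence[str] | None = None) -> pd.DataFrame:
    """One-at-a-time scan: scale each parameter by each factor, re-evaluate
    every observable, and flag configurations where a pathway is active at
    resting potential. One row per (parameter, factor)."""
    for f in factors:
        if not f > 0:
            raise ValueError("factors must be > 0")
    names = list(names if names is not None
                 else STAGE1_NAMES + STAGE2_NAMES)
    base = {k: fn(params) for k, fn in observables.items()}
    rows = []
    for name in names:
        for f in factors:
            try:
                cand = params.scaled(name, f)
            except Exception as exc:
                rows.append(dict(parameter=name, factor=f, valid=False,
                                 error=str(exc)))
                continue
            row = dict(parameter=name, factor=f, valid=True, error="")
            for k, fn in observables.items():
                row[f"d_{k}"] = fn(cand) - base[k]
            row["rest_active"] = any(rest_activation_flags(cand).values())
            rows.append(row)
    return pd.DataFrame(rows)
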