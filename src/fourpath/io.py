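"""Run configuration and result serialization (CSV / HDF5)."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

__all__ = ["RunConfig", "write_results", "read_window", "write_window",
           "trajectory_frame"]

log = logging.getLogger("fourpath")


@dataclass
class RunConfig:
    """Everything needed to reproduce one run: protocol preset plus
    overrides, parameter-set reference, step size, duration and seed."""

    protocol: str
    parameter_set: str = "set1"
    overrides: dict = field(default_factory=dict)
    dt: float = 0.025
    duration: float | None = None
    seed: int = 0
    output: str | None = None

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def log_provenance(self) -> None:
        import fourpath

        log.info("run %s: config hash %s, seed %d, parameter set %s, "
                 "fourpath %s", self.protocol, self.config_hash(), self.seed,
                 self.parameter_set, fourpath.__version__)


def trajectory_frame(traj, traces: bool = True) -> pd.DataFrame:
    """Tabular view of a WeightTrajectory (t, weights and, if logged, every
    intermediate trace)."""
    data = {"t": traj.t, "w_pre": traj.w_pre, "w_post": traj.w_post,
            "w": traj.w}
    if traces and traj.traces:
        for k, v in traj.traces.items():
            data[k] = v
    return pd.DataFrame(data)


def write_results(results, path: str | Path, fmt: str | None = None) -> Path:
    """Write scalar tables as CSV or array payloads as HDF5.

    ``results`` may be a DataFrame (CSV) or a mapping of name -> array
    (HDF5); the format is inferred from the suffix when ``fmt`` is None.
    """
    path = Path(path)
    fmt = fmt or ("hdf5" if path.suffix in (".h5", ".hdf5") else "csv")
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        if not isinstance(results, pd.DataFrame):
            results = pd.DataFrame(results)
        results.to_csv(path, index=False)
    elif fmt == "hdf5":
        with h5py.File(path, "w") as f:
            for key, value in dict(results).items():
                f.create_dataset(key, data=np.asarray(value))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def write_window(window, path: str | Path, config: dict | None = None) -> Path:
    """Persist a PlasticityWindow with its axes and config metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        d = f.create_dataset("relative_change", data=window.matrix)
        f.create_dataset("distances_um", data=window.distances_um)
        f.create_dataset("timings_ms", data=window.timings_ms)
        d.attrs["n_simulations"] = window.n_simulations
        if config:
            d.attrs["config"] = json.dumps(config, default=str)
    return path


def read_window(path: str | Path):
    from .protocols import PlasticityWindow

    with h5py.File(path, "r") as f:
        return PlasticityWindow(
            distances_um=f["distances_um"][()],
            timings_ms=f["timings_ms"][()],
            matrix=f["relative_change"][()],
            n_simulations=int(f["relative_change"].attrs["n_simulations"]),
        )
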