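"""Configuration loading and delimited-text readers/writers.

Run configurations are YAML documents; recordings and trajectories travel
as tab-separated tables with unit-bearing headers, precise enough
(17 significant digits) to round-trip losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import OccupancyTrajectory
from .models import CONDITION_PRESETS
from .synthetic import Recording

__all__ = [
    "RunConfig",
    "load_config",
    "dump_config",
    "read_recording",
    "write_recording",
    "write_trajectory",
    "read_trajectory",
]

_KNOWN_KEYS = {
    "model", "preset", "protocol", "voltage_mV", "voltages_mV",
    "concentration_uM", "concentrations_uM", "duration_s", "wash_times_s",
    "output_dir", "seed", "verbosity", "variants",
}

_PROTOCOLS = {"simulate", "cr", "iv", "two_pulse", "ion_sweep", "synth", "energy"}


@dataclass
class RunConfig:
    """Validated description of a simulation/analysis run.

    Voltages are accepted in mV at this boundary and stored in volts.
    """

    model: str = "DAT"
    preset: str = "physiological"
    protocol: str = "iv"
    voltage: float = -0.060
    voltages: list[float] = field(
        default_factory=lambda: [-0.09, -0.07, -0.05, -0.03, -0.01, 0.01, 0.03]
    )
    concentration: float = 30e-6
    concentrations: list[float] = field(
        default_factory=lambda: [1e-6, 3e-6, 1e-5, 3e-5, 1e-4, 3e-4, 6e-4]
    )
    duration: float = 15.0
    wash_times: list[float] | None = None
    output_dir: str = "results"
    seed: int = 0
    verbosity: int = 1
    variants: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "preset": self.preset,
            "protocol": self.protocol,
            "voltage_mV": self.voltage * 1e3,
            "voltages_mV": [v * 1e3 for v in self.voltages],
            "concentration_uM": self.concentration * 1e6,
            "concentrations_uM": [c * 1e6 for c in self.concentrations],
            "duration_s": self.duration,
            "wash_times_s": self.wash_times,
            "output_dir": self.output_dir,
            "seed": self.seed,
            "verbosity": self.verbosity,
            "variants": dict(self.variants),
        }


def _config_from_dict(raw: dict) -> RunConfig:
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
    cfg = RunConfig()
    cfg.model = str(raw.get("model", cfg.model)).upper()
    if cfg.model not in {"DAT", "NET", "SERT"}:
        raise ValueError(f"unknown model {cfg.model!r}")
    cfg.preset = raw.get("preset", cfg.preset)
    if cfg.preset not in CONDITION_PRESETS:
        raise ValueError(f"unknown preset {cfg.preset!r}")
    cfg.protocol = raw.get("protocol", cfg.protocol)
    if cfg.protocol not in _PROTOCOLS:
        raise ValueError(f"unknown protocol {cfg.protocol!r}")
    if "voltage_mV" in raw:
        cfg.voltage = float(raw["voltage_mV"]) * 1e-3
    if "voltages_mV" in raw:
        cfg.voltages = [float(v) * 1e-3 for v in raw["voltages_mV"]]
    if "concentration_uM" in raw:
        cfg.concentration = float(raw["concentration_uM"]) * 1e-6
    if "concentrations_uM" in raw:
        cfg.concentrations = [float(c) * 1e-6 for c in raw["concentrations_uM"]]
    cfg.duration = float(raw.get("duration_s", cfg.duration))
    if raw.get("wash_times_s") is not None:
        cfg.wash_times = [float(t) for t in raw["wash_times_s"]]
    cfg.output_dir = str(raw.get("output_dir", cfg.output_dir))
    cfg.seed = int(raw.get("seed", cfg.seed))
    cfg.verbosity = int(raw.get("verbosity", cfg.verbosity))
    cfg.variants = dict(raw.get("variants") or {})
    return cfg


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys reject."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("configuration must be a mapping")
    return _config_from_dict(raw)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


_REQUIRED_COLUMNS = ("time_s", "current_A", "fluorescence_AU")


def write_recording(recording: Recording, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time_s": recording.time,
            "current_A": recording.current,
            "fluorescence_AU": recording.fluorescence,
        }
    )
    for key, value in recording.meta.items():
        if np.isscalar(value):
            df.attrs[key] = value
    with open(path, "w") as fh:
        for key, value in recording.meta.items():
            if np.isscalar(value):
                fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_recording(path: str | Path) -> Recording:
    """Read a two-channel recording table; extra columns become metadata."""
    meta: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = yaml.safe_load(value.strip())
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"recording table missing column(s): {missing}")
    t = df["time_s"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise ValueError("non-monotone time column")
    extra = [c for c in df.columns if c not in _REQUIRED_COLUMNS]
    if extra:
        meta["extra_columns"] = {c: df[c].to_numpy() for c in extra}
    return Recording(
        time=t,
        current=df["current_A"].to_numpy(),
        fluorescence=df["fluorescence_AU"].to_numpy(),
        meta=meta,
    )


def write_trajectory(traj: OccupancyTrajectory, path: str | Path) -> None:
    traj.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_trajectory(path: str | Path) -> OccupancyTrajectory:
    df = pd.read_csv(path, sep="\t")
    if "time_s" not in df.columns:
        raise ValueError("trajectory table missing time_s column")
    names = [c for c in df.columns if c != "time_s"]
    return OccupancyTrajectory(
        time=df["time_s"].to_numpy(),
        occupancies=df[names].to_numpy(),
        state_names=names,
    )
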