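"""Tables, configuration and run manifests.

Every interchange format is a delimited text table (comma-separated
with a header row): trace tables are long-format (cell_id, frame, t,
cfp, yfp), parameter ensembles are one row per set, and results carry
whatever columns the producing analysis defines.  Configuration is a
YAML mapping validated against known keys; each CLI run emits a JSON
manifest recording the command, config snapshot, seeds and outputs.
"""

from __future__ import annotations

import dataclasses
import json
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fret import FluorescenceTrace
from .kinetics import (
    ModelParameters,
    SAMPLED_FIELDS,
    VMAX_FIELDS,
)

__all__ = [
    "ConfigError",
    "TraceTableError",
    "read_trace_table",
    "write_trace_table",
    "write_results",
    "load_config",
    "DEFAULT_CONFIG",
    "RunManifest",
    "parameters_to_frame",
    "frame_to_parameters",
    "load_oscillating_fixture",
]


class ConfigError(ValueError):
    """A configuration value is missing, unknown or out of range."""


class TraceTableError(ValueError):
    """A trace table violates the long-format schema."""


TRACE_COLUMNS = ("cell_id", "frame", "t", "cfp", "yfp")


def read_trace_table(path) -> list[FluorescenceTrace]:
    """Read a long-format trace table into per-cell traces.

    Requires columns cell_id, frame, t, cfp (yfp optional for
    single-channel data); frames must be contiguous per cell, the time
    step uniform, and (cell, frame) pairs unique.  Violations raise
    :class:`TraceTableError` naming the offending cell and frame.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRACE_COLUMNS[:4] if c not in frame.columns]
    if missing:
        raise TraceTableError(f"{path}: missing columns {missing}")
    has_yfp = "yfp" in frame.columns
    dup = frame.duplicated(subset=["cell_id", "frame"])
    if dup.any():
        row = frame[dup].iloc[0]
        raise TraceTableError(
            f"{path}: duplicated (cell, frame) key ({row.cell_id}, {int(row.frame)})"
        )
    traces = []
    for cell_id, sub in frame.groupby("cell_id", sort=True):
        sub = sub.sort_values("frame")
        frames_idx = sub["frame"].to_numpy()
        gaps = np.diff(frames_idx) != 1
        if gaps.any():
            at = int(frames_idx[:-1][gaps][0])
            raise TraceTableError(
                f"{path}: cell {cell_id} has a gap in frame numbering after frame {at}"
            )
        t = sub["t"].to_numpy(dtype=float)
        steps = np.diff(t)
        if len(steps) and not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise TraceTableError(f"{path}: cell {cell_id} has a non-uniform time step")
        traces.append(FluorescenceTrace(
            cell_id=str(cell_id),
            times=t,
            cfp=sub["cfp"].to_numpy(dtype=float),
            yfp=sub["yfp"].to_numpy(dtype=float) if has_yfp else None,
        ))
    if not traces:
        raise TraceTableError(f"{path}: table contains no cells")
    return traces


def write_trace_table(traces: list[FluorescenceTrace], path) -> None:
    """Write per-cell traces as a long-format table (full float precision)."""
    parts = []
    for tr in traces:
        data = {
            "cell_id": tr.cell_id,
            "frame": np.arange(tr.times.size),
            "t": tr.times,
            "cfp": tr.cfp,
        }
        if tr.yfp is not None:
            data["yfp"] = tr.yfp
        parts.append(pd.DataFrame(data))
    # default float formatting is the shortest round-trip repr
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)


def write_results(tables: dict[str, pd.DataFrame], out_dir) -> list[Path]:
    """Write named tables as ``<out_dir>/<name>.csv``; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, table in tables.items():
        p = out_dir / f"{name}.csv"
        table.to_csv(p, index=False)
        paths.append(p)
    return paths


#: Known configuration keys, their defaults and validation ranges.
DEFAULT_CONFIG: dict = {
    "uptake_rate": 8.0,          # mmol g^-1 h^-1
    "specific_volume": 0.002,    # l g^-1
    "shift_factor": 0.95,
    "t_perturb": 50.0,           # min
    "t_end": 250.0,              # min
    "dt_out": 1.0,               # min, ensemble analysis grid
    "amplitude_threshold": 1e-3,
    "stability_threshold": -1e-5,
    "rtol": 1e-8,
    "atol": 1e-10,
    "seed": 0,
    "flux_ratio": None,          # fixed ratio instead of sampling, optional
    "dark_count": 106.0,
    "stimulus_time": 100.0,      # s
    "window_frames": 800,
    "window_offset": 50.0,       # s
    "numerator": "cfp",
    "bleach_model": None,        # exponential | linear | None (auto)
}

_RANGES = {
    "uptake_rate": (0.0, np.inf),
    "specific_volume": (0.0, np.inf),
    "shift_factor": (0.0, np.inf),
    "flux_ratio": (0.0, 0.99),
    "amplitude_threshold": (0.0, np.inf),
    "dt_out": (0.0, np.inf),
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge a YAML config file over the defaults and validate it.

    Unknown keys and out-of-range values raise :class:`ConfigError`
    citing the allowed range.
    """
    config = dict(DEFAULT_CONFIG)
    supplied = {}
    if path is not None:
        with open(path) as fh:
            supplied.update(yaml.safe_load(fh) or {})
    if overrides:
        supplied.update(overrides)
    for key, value in supplied.items():
        if key not in DEFAULT_CONFIG:
            raise ConfigError(f"unknown configuration key {key!r}")
        config[key] = value
    for key, (lo, hi) in _RANGES.items():
        value = config.get(key)
        if value is None:
            continue
        if not lo < float(value) <= hi:
            raise ConfigError(
                f"{key} = {value} outside the allowed range ({lo}, {hi}]"
            )
    if not 0.0 < config["t_perturb"] < config["t_end"]:
        raise ConfigError("require 0 < t_perturb < t_end")
    return config


@dataclasses.dataclass
class RunManifest:
    """Record of one CLI run, written next to its outputs as JSON."""

    command: str
    config: dict
    seed: int | None
    outputs: list[str]
    package_version: str = ""
    started: str = ""
    finished: str = ""

    def write(self, path) -> Path:
        from . import __version__

        self.package_version = self.package_version or __version__
        self.finished = datetime.now(timezone.utc).isoformat()
        path = Path(path)
        payload = dataclasses.asdict(self)
        payload["config"] = {k: v for k, v in payload["config"].items()}
        path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
        return path

    @classmethod
    def start(cls, command: str, config: dict, seed: int | None) -> "RunManifest":
        return cls(
            command=command, config=config, seed=seed, outputs=[],
            started=datetime.now(timezone.utc).isoformat(),
        )


PARAMETER_COLUMNS = SAMPLED_FIELDS + VMAX_FIELDS


def parameters_to_frame(sets: list[ModelParameters], seed=None) -> pd.DataFrame:
    """Flat table: one row per parameter set plus structure flags."""
    rows = []
    for p in sets:
        row = p.to_dict()
        s = p.structure
        row.update(
            pfk_inhibition=s.pfk_inhibition_active,
            fbpase_activation=s.fbpase_activation_active,
            pyk_activation=s.pyk_activation_active,
        )
        if seed is not None:
            row["seed"] = seed
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_parameters(frame: pd.DataFrame) -> list[ModelParameters]:
    """Inverse of :func:`parameters_to_frame` (structure flags implied)."""
    sets = []
    for _, row in frame.iterrows():
        kwargs = {c: float(row[c]) for c in PARAMETER_COLUMNS if c in row and pd.notna(row[c])}
        sets.append(ModelParameters(**kwargs))
    return sets


def load_oscillating_fixture() -> list[ModelParameters]:
    """Two stored calibrated parameter sets with sustained pyruvate
    oscillations (apparent periods ~2 and ~16 min on the 1-min grid),
    found by ensemble search and shipped with the package."""
    with resources.files("pyrosc.data").joinpath("oscillating_sets.csv").open() as fh:
        frame = pd.read_csv(fh)
    return frame_to_parameters(frame)
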