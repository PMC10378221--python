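"""Configuration files, trajectory writers/readers, and run manifests.

Configs are flat YAML key-value files mixing protocol keys (box, speeds,
noise, steps, seed, model, ...) with model coefficients (``alpha, beta,
gamma, delta`` for the utility-driven model; ``a, b, c`` for the boids
baseline).  Trajectories are written as a tidy summary CSV plus optional
extended-XYZ text frames (one frame per stored snapshot: N, a comment
line with the time index and box, then per-agent ``x y z vx vy vz``).
All numeric text output uses 9 significant digits, enough for round-trip
tests without bloating files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynamics import ReynoldsParams, SimConfig, run_simulation
from .geometry import BoxSpec, FlockState
from .observables import TrajectoryRecord
from .utility import GarudParams

__all__ = [
    "ConfigError",
    "ConfigFileError",
    "ConfigParseError",
    "ConfigValidationError",
    "load_config",
    "save_config",
    "RunManifest",
    "write_trajectory",
    "read_summary",
    "read_xyz_frames",
    "write_xyz_frames",
    "run_from_manifest",
]

SCHEMA_VERSION = 1
FLOAT_FMT = "%.9g"

GARUD_PARAM_KEYS = {"alpha": 0.5, "beta": 0.005, "gamma": 0.25, "delta": 1.0}
REYNOLDS_PARAM_KEYS = {"a": 0.5, "b": 0.01, "c": 0.5}
SIM_KEYS = {f.name for f in dataclasses.fields(SimConfig)}


class ConfigError(ValueError):
    """Base class for configuration problems."""


class ConfigFileError(ConfigError):
    """The config file is missing or unreadable."""


class ConfigParseError(ConfigError):
    """The config file is not valid flat YAML key-value."""


class ConfigValidationError(ConfigError):
    """The parsed config violates an invariant or has unknown keys."""


def load_config(path) -> tuple[SimConfig, GarudParams | ReynoldsParams]:
    """Read and validate a flat YAML config, filling protocol defaults.

    Unknown keys are rejected; missing keys fall back to the default
    protocol (1000 agents, 20-box, r0 = 3, speeds [0.5, 1], noise 0.01).
    """
    path = Path(path)
    if not path.is_file():
        raise ConfigFileError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigParseError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigParseError(f"config must be a flat mapping, got {type(raw).__name__}")
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> tuple[SimConfig, GarudParams | ReynoldsParams]:
    raw = dict(raw)
    model = raw.get("model", "garud")
    param_defaults = GARUD_PARAM_KEYS if model == "garud" else REYNOLDS_PARAM_KEYS
    allowed = SIM_KEYS | set(param_defaults)
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigValidationError(f"unknown config keys: {sorted(unknown)}")
    sim_kwargs = {k: v for k, v in raw.items() if k in SIM_KEYS}
    try:
        config = SimConfig(**sim_kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigValidationError(str(exc)) from exc
    par_kwargs = {k: raw.get(k, d) for k, d in param_defaults.items()}
    try:
        if model == "garud":
            params = GarudParams(r0=config.r0, **par_kwargs)
        else:
            params = ReynoldsParams(
                r0=config.r0,
                noise_level=config.noise_level,
                speed_min=config.speed_min,
                speed_max=config.speed_max,
                **par_kwargs,
            )
    except ValueError as exc:
        raise ConfigValidationError(str(exc)) from exc
    return config, params


def config_to_dict(config: SimConfig, params: GarudParams | ReynoldsParams) -> dict:
    out = dataclasses.asdict(config)
    for key in (GARUD_PARAM_KEYS if isinstance(params, GarudParams) else REYNOLDS_PARAM_KEYS):
        out[key] = getattr(params, key)
    return out


def save_config(config: SimConfig, params, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config, params), sort_keys=True))


@dataclass
class RunManifest:
    """Everything needed to reproduce a run and locate its artifacts."""

    schema_version: int
    config: dict
    seed: int
    start_time_index: int
    end_time_index: int
    files: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))


def write_xyz_frames(frames, box: BoxSpec, path) -> None:
    """Write extended-XYZ-style text frames: ``(time_index, FlockState)``."""
    L = box.edge_lengths
    with open(path, "w") as fh:
        for time_index, state in frames:
            fh.write(f"{state.n_agents}\n")
            fh.write(
                f'time_index={time_index} box="{FLOAT_FMT % L[0]} {FLOAT_FMT % L[1]} {FLOAT_FMT % L[2]}"\n'
            )
            for p, v in zip(state.positions, state.velocities):
                fh.write(" ".join(FLOAT_FMT % x for x in (*p, *v)) + "\n")


def read_xyz_frames(path) -> tuple[list[tuple[int, FlockState]], BoxSpec]:
    """Read frames written by :func:`write_xyz_frames`."""
    frames = []
    box = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        n = int(lines[i])
        comment = lines[i + 1]
        fields = dict(part.split("=", 1) for part in _split_comment(comment))
        time_index = int(fields["time_index"])
        edges = np.array([float(x) for x in fields["box"].strip('"').split()])
        box = BoxSpec(edges)
        data = np.array([[float(x) for x in lines[i + 2 + k].split()] for k in range(n)])
        frames.append((time_index, FlockState(data[:, :3], data[:, 3:], time_index)))
        i += 2 + n
    if box is None:
        raise ValueError(f"no frames found in {path}")
    return frames, box


def _split_comment(comment: str) -> list[str]:
    parts, current, quoted = [], "", False
    for ch in comment:
        if ch == '"':
            quoted = not quoted
            current += ch
        elif ch == " " and not quoted:
            if current:
                parts.append(current)
            current = ""
        else:
            current += ch
    if current:
        parts.append(current)
    return parts


def write_trajectory(record: TrajectoryRecord, out_dir, snapshot_stride: int = 0) -> RunManifest:
    """Write summary CSV, optional XYZ frames, and the manifest (last).

    ``snapshot_stride`` selects among the record's stored snapshots; 0
    writes no frame file.  On failure, partial outputs are removed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config: SimConfig = record.config
    files = {}
    written = []
    try:
        summary_path = out_dir / "summary.csv"
        record.summaries.to_csv(summary_path, index=False, float_format=FLOAT_FMT)
        written.append(summary_path)
        files["summary"] = summary_path.name
        if snapshot_stride > 0 and record.snapshots:
            frames = [
                (s.time_index, s.state)
                for s in record.snapshots
                if s.time_index % snapshot_stride == 0
            ]
            frames_path = out_dir / "frames.xyz"
            write_xyz_frames(frames, config.box, frames_path)
            written.append(frames_path)
            files["frames"] = frames_path.name
        manifest = RunManifest(
            schema_version=SCHEMA_VERSION,
            config=config_to_dict(config, record.params),
            seed=config.seed,
            start_time_index=int(record.summaries["step"].iloc[0]),
            end_time_index=int(record.summaries["step"].iloc[-1]),
            files=files,
        )
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(manifest.to_json())
        written.append(manifest_path)
        return manifest
    except OSError:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def read_summary(path) -> pd.DataFrame:
    return pd.read_csv(path)


def run_from_manifest(manifest_path) -> TrajectoryRecord:
    """Re-run the simulation described by a manifest (bit-reproducible)."""
    manifest = RunManifest.from_json(Path(manifest_path).read_text())
    config, params = config_from_dict(manifest.config)
    return run_simulation(config, params)
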