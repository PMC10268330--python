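"""Configuration files, fixed-schema CSV tables and trajectory export.

Configuration is YAML with sections mirroring the parameter dataclasses
(membrane, environment, simulation, transport, dosing, synthesis) plus
top-level output directory, seed and log level.  Unknown keys are
rejected so typos fail loudly.  All tabular interchange is CSV with
fixed, validated headers.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigError, SchemaError
from .mechanics import (
    EnvironmentParams,
    MembraneParams,
    SimulationConfig,
    Trajectory,
)

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "read_table",
    "write_table",
    "export_trajectory",
    "TABLE_SCHEMAS",
]

log = logging.getLogger("protoendo")

TABLE_SCHEMAS = {
    "counts": ["dcv_mM", "dca_mM", "replicate", "n_compartments"],
    "series": ["time_h", "ratio"],
    "release": ["time_s", "C_compartment_mM", "C_lumen_mM"],
    "diagnostics": ["time_s", "area_um2", "volume_um3", "reduced_volume",
                    "E_bend_kBT", "morphology"],
    "trajectory": ["frame", "time_s", "marker_index", "r_um", "z_um"],
    "phase_scan": ["gamma_per_s", "delta_c_mM", "label", "reduced_volume",
                   "n_invaginations"],
    "summary": ["dcv_mM", "dca_mM", "n_total", "n_replicates", "frac_any",
                "sd_any", "frac_multi", "sd_multi"],
}


@dataclass
class RunConfig:
    """Validated run configuration assembled from a YAML file."""

    membrane: MembraneParams = field(default_factory=MembraneParams)
    environment: EnvironmentParams = field(default_factory=EnvironmentParams)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    transport: dict = field(default_factory=dict)
    dosing: dict = field(default_factory=dict)
    synthesis: dict = field(default_factory=dict)
    output_dir: str = "."
    seed: int = 0
    log_level: str = "INFO"


_SECTION_TYPES = {
    "membrane": MembraneParams,
    "environment": EnvironmentParams,
    "simulation": SimulationConfig,
}
_PLAIN_SECTIONS = {"transport", "dosing", "synthesis"}
_SCALARS = {"output_dir", "seed", "log_level"}


def load_config(path) -> RunConfig:
    """Parse and validate a YAML config; defaults fill missing fields."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")

    kwargs = {}
    for key, value in raw.items():
        if key in _SECTION_TYPES:
            cls = _SECTION_TYPES[key]
            names = {f.name for f in dataclasses.fields(cls)}
            unknown = set(value) - names
            if unknown:
                raise ConfigError(
                    f"unknown keys in [{key}]: {sorted(unknown)}")
            try:
                kwargs[key] = cls(**value)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"invalid [{key}]: {exc}") from exc
        elif key in _PLAIN_SECTIONS:
            if not isinstance(value, dict):
                raise ConfigError(f"[{key}] must be a mapping")
            kwargs[key] = value
        elif key in _SCALARS:
            kwargs[key] = value
        else:
            raise ConfigError(f"unknown config section: {key!r}")
    cfg = RunConfig(**kwargs)
    log.debug("loaded config from %s: %s", path, cfg)
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    """Write a RunConfig back to YAML (normalized; round-trips with
    load_config)."""
    out = {
        "membrane": dataclasses.asdict(cfg.membrane),
        "environment": dataclasses.asdict(cfg.environment),
        "simulation": dataclasses.asdict(cfg.simulation),
        "transport": cfg.transport,
        "dosing": cfg.dosing,
        "synthesis": cfg.synthesis,
        "output_dir": cfg.output_dir,
        "seed": cfg.seed,
        "log_level": cfg.log_level,
    }
    Path(path).write_text(yaml.safe_dump(out, sort_keys=True))


def write_table(path, df: pd.DataFrame, kind: str) -> None:
    """Write a fixed-schema CSV (UTF-8, '.' decimal, comma separator)."""
    schema = TABLE_SCHEMAS.get(kind)
    if schema is None:
        raise SchemaError(f"unknown table kind {kind!r}")
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{kind} table missing columns: {missing}")
    df[schema].to_csv(path, index=False)


def read_table(path, kind: str) -> pd.DataFrame:
    """Read and validate a fixed-schema CSV."""
    schema = TABLE_SCHEMAS.get(kind)
    if schema is None:
        raise SchemaError(f"unknown table kind {kind!r}")
    df = pd.read_csv(path)
    missing = [c for c in schema if c not in df.columns]
    extra = [c for c in df.columns if c not in schema]
    if missing or extra:
        raise SchemaError(
            f"{kind} table schema mismatch: missing {missing}, extra {extra}")
    return df


def export_trajectory(traj: Trajectory, out_dir) -> tuple[Path, Path]:
    """Write marker and diagnostics CSVs for a trajectory; returns the
    two paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (t, sh) in enumerate(zip(traj.times, traj.frames)):
        m = sh.markers
        for j in range(m.shape[0]):
            rows.append((i, t, j, m[j, 0], m[j, 1]))
    markers = pd.DataFrame(rows, columns=TABLE_SCHEMAS["trajectory"])
    p1 = out / "trajectory.csv"
    p2 = out / "diagnostics.csv"
    write_table(p1, markers, "trajectory")
    write_table(p2, traj.diagnostics, "diagnostics")
    return p1, p2
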