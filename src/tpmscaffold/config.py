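"""YAML run configuration: versioned schema, strict validation, manifest echo."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .calibration import DEFAULT_CALIBRATION_SEED, DesignTarget
from .fields import Cylinder

__all__ = ["RunConfig", "ConfigError", "load_config"]

CONFIG_VERSION = 1


class ConfigError(ValueError):
    """A configuration schema violation, reported with its key path."""


# key path -> (type check, human description)
_SCHEMA: dict[str, tuple] = {
    "version": (int, "schema version (must be 1)"),
    "design.family": (str, "TPMS family, 'G' or 'D'"),
    "design.porosity": ((int, float), "target void fraction in (0,1)"),
    "design.pore_radius_mm": ((int, float), "target pore radius, mm"),
    "design.height_mm": ((int, float), "envelope height, mm"),
    "design.diameter_mm": ((int, float), "envelope diameter, mm"),
    "design.shell_thickness_mm": ((int, float), "shell thickness, mm (0 = no shell)"),
    "shell.smoothing": ((int, float), "tapered-window sharpness"),
    "shell.orientation": (str, "'shell_outside' or 'as_printed'"),
    "sampling.resolution": ((int, float, type(None)), "voxels per mm (null = auto)"),
    "estimator.method": (str, "'monte_carlo' or 'grid'"),
    "estimator.n": (int, "Monte-Carlo samples per calibration point"),
    "seed": (int, "base RNG seed"),
    "output_dir": (str, "output directory"),
}

_DEFAULTS = {
    "version": CONFIG_VERSION,
    "design.family": "G",
    "design.porosity": 0.40,
    "design.pore_radius_mm": 1.0,
    "design.height_mm": 10.0,
    "design.diameter_mm": 10.0,
    "design.shell_thickness_mm": 0.0,
    "shell.smoothing": 0.03,
    "shell.orientation": "shell_outside",
    "sampling.resolution": None,
    "estimator.method": "monte_carlo",
    "estimator.n": 200_000,
    "seed": DEFAULT_CALIBRATION_SEED,
    "output_dir": "scaffold_out",
}


def _flatten(d: dict, prefix: str = "") -> dict:
    out = {}
    for k, v in d.items():
        path = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, path + "."))
        else:
            out[path] = v
    return out


@dataclass
class RunConfig:
    """Fully resolved run configuration (defaults merged, validated)."""

    values: dict = field(default_factory=dict)

    def __getitem__(self, key: str):
        return self.values[key]

    def target(self) -> DesignTarget:
        v = self.values
        return DesignTarget(
            family=v["design.family"],
            porosity=float(v["design.porosity"]),
            pore_radius=float(v["design.pore_radius_mm"]),
            envelope=Cylinder(
                height=float(v["design.height_mm"]),
                diameter=float(v["design.diameter_mm"]),
            ),
            shell_thickness=float(v["design.shell_thickness_mm"]),
        )

    def write_manifest(self, out_dir: Path, extra: dict | None = None) -> Path:
        nested: dict = {}
        for path, val in sorted(self.values.items()):
            node = nested
            *heads, leaf = path.split(".")
            for h in heads:
                node = node.setdefault(h, {})
            node[leaf] = val
        payload = {"config": nested}
        if extra:
            payload.update(extra)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = out_dir / "manifest.json"
        manifest.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return manifest


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML config; unknown keys are rejected with their paths.

    ``overrides`` is a flat ``{"key.path": value}`` mapping (CLI flags)
    applied after the file and before validation.
    """
    raw: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config root must be a mapping, got {type(loaded).__name__}")
        raw = _flatten(loaded)
    unknown = sorted(set(raw) - set(_SCHEMA))
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
    merged = dict(_DEFAULTS)
    merged.update(raw)
    if overrides:
        bad = sorted(set(overrides) - set(_SCHEMA))
        if bad:
            raise ConfigError(f"unknown override key(s): {', '.join(bad)}")
        merged.update({k: v for k, v in overrides.items() if v is not None})

    for key, (types, desc) in _SCHEMA.items():
        val = merged[key]
        if not isinstance(val, types) or isinstance(val, bool):
            raise ConfigError(f"{key}: expected {desc}, got {val!r}")
    if merged["version"] != CONFIG_VERSION:
        raise ConfigError(f"version: unsupported schema version {merged['version']}")
    if not 0.0 < float(merged["design.porosity"]) < 1.0:
        raise ConfigError(
            f"design.porosity: target void fraction must be in (0,1), got {merged['design.porosity']}"
        )
    if merged["design.family"].upper() not in ("G", "D"):
        raise ConfigError(f"design.family: expected 'G' or 'D', got {merged['design.family']!r}")
    if merged["shell.orientation"] not in ("shell_outside", "as_printed"):
        raise ConfigError(
            f"shell.orientation: expected 'shell_outside' or 'as_printed', got {merged['shell.orientation']!r}"
        )
    cfg = RunConfig(values=merged)
    cfg.target()  # surface geometric inconsistencies now, with key-level context
    return cfg
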