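"""Configuration loading, run persistence and manifests.

Configs are YAML or JSON validated through pydantic models with unknown keys
rejected.  A run directory holds a compressed array container (``.npz``),
tabular CSVs, the validated config, and a ``manifest.json`` recording the
schema version, config hash, seeds and a checksum inventory — enough to
regenerate every artifact from scratch.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .simulator import EnvironmentParams, make_environment

__all__ = ["SCHEMA_VERSION", "SimulationConfig", "load_config", "save_config",
           "save_run", "load_run", "IntegrityError"]

SCHEMA_VERSION = 1


class IntegrityError(RuntimeError):
    """A persisted artifact failed its checksum or schema-version check."""


class SimulationConfig(BaseModel):
    """Validated environment configuration (see EnvironmentParams for units)."""

    model_config = ConfigDict(extra="forbid")

    schema_version: int = SCHEMA_VERSION
    n_fields: int = 2
    horizon: int = 12
    grid_h: int = 8
    grid_w: int = 8
    n_channels: int = 5
    n_actions: int = 2
    moisture_decay: float = 0.3
    irrigation_efficiency: float = 5e-4
    rain_efficiency: float = 0.01
    moisture_optimum: float = 0.55
    moisture_width: float = 0.30
    health_rate: float = 0.5
    growth_rate: float = 0.15
    temp_mean: float = 22.0
    temp_autocorr: float = 0.7
    humidity_mean: float = 0.6
    humidity_autocorr: float = 0.6
    precip_mean: float = 8.0
    baseline_yield: float = 330.0
    yield_gain: tuple[float, float] = (0.40, 0.25)
    saturation_dose: tuple[float, float] = (400.0, 15.0)
    response_exponent: float = 2.0
    unit_price: tuple[float, float] = (0.02, 0.5)
    env_penalty: tuple[float, float] = (1e-5, 5e-3)
    noise_scale: float = 1.0
    budget: float = 7000.0
    env_cap: float = 5.0
    dose_lower: tuple[float, float] = (0.0, 0.0)
    dose_upper: tuple[float, float] = (600.0, 25.0)

    def to_environment(self, seed: int = 0) -> EnvironmentParams:
        d = self.model_dump()
        d.pop("schema_version")
        return make_environment(d, seed=seed)


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> SimulationConfig:
    """Parse and validate a YAML/JSON environment config.

    Unknown keys (typos) and invariant violations raise a
    :class:`ConfigError` naming the offending key and the file.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        raw = (json.loads(text) if path.suffix.lower() == ".json"
               else yaml.safe_load(text))
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top-level config must be a mapping")
    if raw.get("schema_version", SCHEMA_VERSION) != SCHEMA_VERSION:
        raise ConfigError(
            f"{path}: schema version {raw.get('schema_version')} "
            f"not supported (reader is at {SCHEMA_VERSION})")
    try:
        return SimulationConfig(**raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(x) for x in first["loc"]) or "<root>"
        raise ConfigError(f"{path}: invalid config at key '{loc}': "
                          f"{first['msg']}") from exc


def save_config(config: SimulationConfig, path: str | Path) -> Path:
    path = Path(path)
    data = config.model_dump()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    return path


# ---------------------------------------------------------------------------
# run persistence
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(config: SimulationConfig) -> str:
    payload = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def save_run(out_dir: str | Path, arrays: dict[str, np.ndarray],
             config: SimulationConfig, seeds: dict[str, int],
             tables: dict[str, "object"] | None = None,
             extra: dict | None = None) -> Path:
    """Persist arrays (compressed container), config, tables and a manifest.

    Returns the manifest path.  ``tables`` values must expose ``to_csv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []

    arr_path = out / "arrays.npz"
    np.savez_compressed(arr_path, **arrays)
    files.append(arr_path)

    cfg_path = save_config(config, out / "config.yaml")
    files.append(cfg_path)

    for name, table in (tables or {}).items():
        p = out / f"{name}.csv"
        table.to_csv(p, index=False)
        files.append(p)

    manifest = {
        "schema_version": SCHEMA_VERSION,
        "config_hash": config_hash(config),
        "seeds": seeds,
        "code_version": _package_version(),
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "files": {p.name: _sha256(p) for p in files},
        "extra": extra or {},
    }
    man_path = out / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2))
    return man_path


def load_run(run_dir: str | Path) -> tuple[dict, dict[str, np.ndarray],
                                           SimulationConfig]:
    """Reload a run directory, verifying schema version and checksums.

    Raises :class:`IntegrityError` on version mismatch, missing files or
    checksum failure (truncation/corruption is never silent).
    """
    run_dir = Path(run_dir)
    man_path = run_dir / "manifest.json"
    if not man_path.exists():
        raise IntegrityError(f"no manifest.json in {run_dir}")
    manifest = json.loads(man_path.read_text())
    if manifest.get("schema_version") != SCHEMA_VERSION:
        raise IntegrityError(
            f"manifest schema version {manifest.get('schema_version')} "
            f"does not match reader version {SCHEMA_VERSION}")
    for name, digest in manifest["files"].items():
        p = run_dir / name
        if not p.exists():
            raise IntegrityError(f"missing artifact {name}")
        actual = _sha256(p)
        if actual != digest:
            raise IntegrityError(
                f"checksum mismatch for {name}: manifest {digest[:12]}..., "
                f"file {actual[:12]}...")
    config = load_config(run_dir / "config.yaml")
    if config_hash(config) != manifest["config_hash"]:
        raise IntegrityError("config hash does not match the manifest")
    with np.load(run_dir / "arrays.npz") as z:
        arrays = {k: z[k].copy() for k in z.files}
    return manifest, arrays, config


def _package_version() -> str:
    try:
        from importlib.metadata import version
        return version("agroplan")
    except Exception:  # pragma: no cover
        return "unknown"
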