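"""Configuration files, CSV output and run manifests.

Configs are YAML with a nested ``distribution`` block and flat sweep keys;
grids may be given either as explicit lists or as ``{start, stop, step}``
mappings. Every CSV written by the package is accompanied by a JSON manifest
(config echo, software version, seed, timestamps, output paths) sufficient
to reproduce it byte-for-byte.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .colony import EfficiencyMode
from .distributions import DistributionSpec
from .sweep import EfficiencyCurve, SweepConfig, SweepResult

__all__ = [
    "ConfigError",
    "load_config",
    "config_from_dict",
    "config_to_dict",
    "save_config",
    "write_curve_csv",
    "write_heatmap_csv",
    "read_curve_csv",
    "read_heatmap_csv",
    "RunManifest",
    "read_manifest",
    "reproduce_from_manifest",
]

CURVE_COLUMNS = [
    "distribution", "n_workers", "mode", "beta", "delta", "k",
    "active_fraction", "mean_normalized_efficiency",
    "sd_normalized_efficiency", "n_replicates",
]
HEATMAP_COLUMNS = [
    "distribution", "n_workers", "mode", "beta", "delta",
    "optimal_active_fraction", "efficiency_at_optimum",
]

_CONFIG_KEYS = {
    "distribution", "n_workers", "beta_grid", "delta_grid", "k_grid",
    "n_replicates", "mode", "base_seed", "production_cost",
    "common_random_numbers",
}


def _repr_float(x: float) -> str:
    # shortest representation that round-trips through text exactly
    return repr(float(x))


class ConfigError(ValueError):
    """A configuration file failed validation; the message names the key."""


def _grid_from_value(value: Any, key: str, dtype=float) -> np.ndarray | None:
    if value is None:
        return None
    if isinstance(value, dict):
        extra = set(value) - {"start", "stop", "step"}
        if extra or set(value) != {"start", "stop", "step"}:
            raise ConfigError(
                f"{key}: range form requires exactly start/stop/step keys"
            )
        start, stop, step = value["start"], value["stop"], value["step"]
        if step <= 0:
            raise ConfigError(f"{key}: step must be > 0")
        grid = np.round(np.arange(start, stop + step / 2.0, step), 10)
    else:
        try:
            grid = np.asarray(list(value), dtype=dtype)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{key}: expected a list or start/stop/step mapping") from exc
    return grid.astype(dtype)


def config_from_dict(raw: dict[str, Any]) -> SweepConfig:
    """Build a validated :class:`SweepConfig` from a plain mapping."""
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    if "distribution" not in raw:
        raise ConfigError("distribution: a distribution block is required")
    if "n_workers" not in raw:
        raise ConfigError("n_workers: a colony size is required")
    try:
        dist = DistributionSpec.from_dict(dict(raw["distribution"]))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"distribution: {exc}") from exc

    kwargs: dict[str, Any] = {"distribution": dist, "n_workers": int(raw["n_workers"])}
    for key, dtype in (("beta_grid", float), ("delta_grid", float), ("k_grid", int)):
        if key in raw:
            kwargs[key] = _grid_from_value(raw[key], key, dtype)
    for key in ("n_replicates", "base_seed"):
        if key in raw:
            kwargs[key] = int(raw[key])
    if "production_cost" in raw:
        kwargs["production_cost"] = float(raw["production_cost"])
    if "common_random_numbers" in raw:
        kwargs["common_random_numbers"] = bool(raw["common_random_numbers"])
    if "mode" in raw:
        try:
            kwargs["mode"] = EfficiencyMode(raw["mode"])
        except ValueError as exc:
            raise ConfigError(f"mode: must be 'ratio' or 'difference', got {raw['mode']!r}") from exc

    try:
        return SweepConfig(**kwargs)
    except ValueError as exc:
        # SweepConfig's message already names the offending field
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> SweepConfig:
    """Load and validate a sweep configuration from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping at top level")
    return config_from_dict(raw)


def config_to_dict(config: SweepConfig) -> dict[str, Any]:
    """Serialize a :class:`SweepConfig` to a YAML/JSON-safe mapping; the
    round trip through :func:`config_from_dict` is the identity."""
    return {
        "distribution": config.distribution.to_dict(),
        "n_workers": int(config.n_workers),
        "beta_grid": [float(b) for b in config.beta_grid],
        "delta_grid": [float(d) for d in config.delta_grid],
        "k_grid": [int(k) for k in config.k_grid],
        "n_replicates": int(config.n_replicates),
        "mode": config.mode.value,
        "base_seed": int(config.base_seed),
        "production_cost": float(config.production_cost),
        "common_random_numbers": bool(config.common_random_numbers),
    }


def save_config(config: SweepConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def write_curve_csv(curve: EfficiencyCurve, path: str | Path) -> None:
    """Write one efficiency curve as tidy CSV (one row per active count)."""
    df = pd.DataFrame(
        {
            "distribution": curve.distribution.kind.value,
            "n_workers": curve.n_workers,
            "mode": curve.mode.value,
            "beta": curve.beta,
            "delta": curve.delta,
            "k": curve.k_values,
            "active_fraction": curve.active_fractions,
            "mean_normalized_efficiency": curve.mean_normalized_efficiency,
            "sd_normalized_efficiency": curve.dispersion,
            "n_replicates": curve.n_replicates,
        }
    )[CURVE_COLUMNS]
    df.to_csv(path, index=False, float_format=_repr_float)


def write_heatmap_csv(result: SweepResult, path: str | Path) -> None:
    """Write a sweep's optimal-fraction grid as tidy CSV, beta-major order."""
    df = result.grid.sort_values(["beta", "delta"], kind="stable").copy()
    df.insert(0, "mode", result.config.mode.value)
    df.insert(0, "n_workers", result.config.n_workers)
    df.insert(0, "distribution", result.config.distribution.kind.value)
    df[HEATMAP_COLUMNS].to_csv(path, index=False, float_format=_repr_float)


def read_curve_csv(path: str | Path) -> pd.DataFrame:
    """Read a curve CSV with round-trip float parsing (bit-exact values)."""
    return pd.read_csv(path, float_precision="round_trip")


def read_heatmap_csv(path: str | Path) -> pd.DataFrame:
    """Read a heat-map CSV with round-trip float parsing."""
    return pd.read_csv(path, float_precision="round_trip")


@dataclass
class RunManifest:
    """Provenance record accompanying every set of output CSVs."""

    command: str
    config: dict[str, Any]
    version: str = __version__
    base_seed: int = 0
    started: str = ""
    finished: str = ""
    outputs: dict[str, str] = field(default_factory=dict)
    extra: dict[str, Any] = field(default_factory=dict)

    @staticmethod
    def now() -> str:
        return datetime.datetime.now(datetime.timezone.utc).isoformat()

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")


def read_manifest(path: str | Path) -> RunManifest:
    with open(path, "r", encoding="utf-8") as fh:
        return RunManifest(**json.load(fh))


def reproduce_from_manifest(manifest_path: str | Path, out_dir: str | Path) -> list[Path]:
    """Re-run the computation recorded in a manifest, writing fresh CSVs.

    Supports the ``curve`` and ``sweep`` commands; returns the paths
    written. Because every random stream is derived from the recorded
    config, the regenerated CSVs are byte-identical to the originals.
    """
    from .sweep import aggregate_curve, run_replicates, run_sweep

    manifest = read_manifest(manifest_path)
    config = config_from_dict(manifest.config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if manifest.command == "curve":
        beta = float(manifest.extra["beta"])
        delta = float(manifest.extra["delta"])
        curve = aggregate_curve(run_replicates(config), beta, delta, config)
        for name in manifest.outputs.values():
            path = out_dir / Path(name).name
            write_curve_csv(curve, path)
            written.append(path)
    elif manifest.command == "sweep":
        result = run_sweep(config)
        for name in manifest.outputs.values():
            path = out_dir / Path(name).name
            write_heatmap_csv(result, path)
            written.append(path)
    else:
        raise ValueError(f"cannot reproduce command {manifest.command!r}")
    return written
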