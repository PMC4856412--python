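"""Layered run configuration, the run manifest, and result serialization.

Resolution order is: built-in defaults, then a YAML/JSON config file, then
explicit overrides (CLI flags).  Unknown keys are rejected with the key path
(and file) named, and every value is validated by constructing the actual
domain objects, so an out-of-range trait fails at load time rather than mid
run.  A :class:`RunManifest` snapshots the fully resolved configuration next
to every output; re-running from a manifest reproduces the outputs exactly.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .environment import KIND_DEFAULTS, MAP_KINDS, MapSpec
from .model import ModelConstants, Traits

__all__ = [
    "ConfigError",
    "RunManifest",
    "default_config",
    "load_config",
    "resolve_constants",
    "resolve_map_spec",
    "resolve_traits",
    "write_results",
]


class ConfigError(ValueError):
    """A configuration file or flag set failed validation."""


def default_config() -> dict[str, Any]:
    """The built-in defaults as a plain nested dict."""
    return {
        "constants": {
            f.name: getattr(ModelConstants(), f.name)
            for f in dataclasses.fields(ModelConstants)
        },
        "traits": {
            f.name: getattr(Traits(), f.name) for f in dataclasses.fields(Traits)
        },
        "map": {
            "kind": "random_scarce",
            "grid_size": 200,
            "food_density": None,
            "units_per_site": 1,
            "patch_count": None,
            "patch_radius": None,
            "poison_fraction": 0.0,
        },
        "run": {"seed": 0, "replicates": 10},
    }


def _merge(base: dict, extra: Mapping, source: str) -> None:
    for key, value in extra.items():
        if key not in base:
            raise ConfigError(f"{source}: unknown key {key!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, Mapping):
                raise ConfigError(f"{source}: section {key!r} must be a mapping")
            _merge(base[key], value, f"{source}:{key}")
        else:
            base[key] = value


def _apply_dotted(config: dict, overrides: Mapping[str, Any], source: str) -> None:
    for dotted, value in overrides.items():
        if value is None:
            continue
        node = config
        parts = dotted.split(".")
        for part in parts[:-1]:
            if part not in node or not isinstance(node[part], dict):
                raise ConfigError(f"{source}: unknown key {dotted!r}")
            node = node[part]
        if parts[-1] not in node:
            raise ConfigError(f"{source}: unknown key {dotted!r}")
        node[parts[-1]] = value


def load_config(
    path: str | Path | None = None,
    overrides: Mapping[str, Any] | None = None,
) -> dict[str, Any]:
    """Resolve defaults <- config file <- dotted-key overrides, then validate."""
    config = default_config()
    if path is not None:
        path = Path(path)
        try:
            text = path.read_text()
            if path.suffix == ".json":
                loaded = json.loads(text)
            else:
                loaded = yaml.safe_load(text)
        except (OSError, ValueError, yaml.YAMLError) as exc:
            raise ConfigError(f"{path}: cannot parse config file: {exc}") from exc
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, Mapping):
            raise ConfigError(f"{path}: top level must be a mapping")
        _merge(config, loaded, str(path))
    if overrides:
        _apply_dotted(config, overrides, "flags")
    validate_config(config)
    return config


def resolve_traits(config: Mapping[str, Any]) -> Traits:
    return Traits(**config["traits"])


def resolve_constants(config: Mapping[str, Any]) -> ModelConstants:
    return ModelConstants(**config["constants"])


def resolve_map_spec(config: Mapping[str, Any], kind: str | None = None) -> MapSpec:
    section = dict(config["map"])
    kind = kind or section.pop("kind")
    section.pop("kind", None)
    defaults = KIND_DEFAULTS[kind] if kind in KIND_DEFAULTS else {}
    for key, default in defaults.items():
        if section.get(key) is None:
            section[key] = default
    return MapSpec(kind=kind, **section)


def validate_config(config: Mapping[str, Any]) -> None:
    """Validate by constructing the domain objects; re-raise as ConfigError."""
    try:
        resolve_traits(config)
        resolve_constants(config)
        resolve_map_spec(config)
        seed = config["run"]["seed"]
        if int(seed) != seed or seed < 0:
            raise ValueError(f"run.seed={seed!r} must be a non-negative integer")
        if config["run"]["replicates"] < 1:
            raise ValueError("run.replicates must be >= 1")
    except ConfigError:
        raise
    except (TypeError, ValueError, KeyError) as exc:
        raise ConfigError(str(exc)) from exc


@dataclasses.dataclass
class RunManifest:
    """Snapshot of a fully resolved run, written alongside every output."""

    config: dict[str, Any]
    base_seed: int
    version: str = __version__
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = _dt.datetime.now(_dt.timezone.utc).isoformat(
                timespec="seconds"
            )

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunManifest":
        data = yaml.safe_load(text)
        return cls(**data)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml())

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls.from_yaml(Path(path).read_text())


#: Fixed column orders for the result tables.
TIDY_COLUMNS = [
    "map_kind",
    "replicate",
    "generation",
    "cohort",
    "carrier_count",
    "mean_fitness",
]
SUMMARY_COLUMNS = [
    "map_kind",
    "generation",
    "cohort",
    "mean_count",
    "ci_halfwidth",
    "replicates",
]


def write_results(summary, outdir: str | Path, manifest: RunManifest) -> dict[str, Path]:
    """Write the tidy and summary CSVs plus the manifest into ``outdir``.

    Returns the paths written: ``tidy`` (one row per map kind, replicate,
    generation and cohort), ``summary`` (replicate means and 95% CI
    half-widths) and ``manifest``.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "tidy": outdir / "trajectories.csv",
            "summary": outdir / "summary.csv",
            "manifest": outdir / "manifest.yaml",
        }
        tidy = summary.to_frame()[TIDY_COLUMNS]
        tidy.to_csv(paths["tidy"], index=False)
        summ = summary.summary_frame()[SUMMARY_COLUMNS]
        summ.to_csv(paths["summary"], index=False)
        manifest.write(paths["manifest"])
    except OSError as exc:
        raise OSError(f"cannot write results under {outdir}: {exc}") from exc
    return paths


def read_tidy(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
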