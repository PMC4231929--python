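"""Packaged defaults and run configuration.

All tunable numbers in the model ship in ``data/defaults.yaml``; a user config
file (YAML) with the same structure overrides them key by key, and CLI flags
override both. A run configuration can be hashed so every output file can
carry the provenance of the exact settings that produced it.
"""
from __future__ import annotations

import copy
import hashlib
import json
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigurationError

__all__ = [
    "package_defaults",
    "load_config",
    "merge_config",
    "config_hash",
]


def _data_path(name: str):
    return resources.files("crabrisk.data").joinpath(name)


@lru_cache(maxsize=1)
def package_defaults() -> dict:
    """The packaged default parameterisation, as a nested dict."""
    with _data_path("defaults.yaml").open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def merge_config(base: Mapping[str, Any], override: Mapping[str, Any] | None) -> dict:
    """Recursively overlay ``override`` onto ``base`` (dicts merged, scalars replaced)."""
    merged = copy.deepcopy(dict(base))
    if not override:
        return merged
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(merged.get(key), Mapping):
            merged[key] = merge_config(merged[key], value)
        else:
            merged[key] = copy.deepcopy(value)
    return merged


def load_config(path: str | Path | None = None) -> dict:
    """Packaged defaults overlaid with an optional user YAML config file."""
    defaults = package_defaults()
    if path is None:
        return copy.deepcopy(defaults)
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, Mapping):
        raise ConfigurationError(f"config file must contain a mapping: {path}")
    return merge_config(defaults, user)


def config_hash(config: Mapping[str, Any]) -> str:
    """Short stable digest of a configuration (for provenance headers)."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()[:12]
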