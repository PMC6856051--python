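"""Experiment configuration: YAML/JSON loading, seed fan-out, provenance.

A run is reproducible from its config file alone.  One global seed fans out
to named sub-seeds (topology / data / split / ...) through a deterministic
splitter, so individual components can be re-seeded independently without
disturbing the others.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError

__all__ = ["load_config", "subseed", "config_hash", "provenance"]


def load_config(path) -> dict:
    """Read a YAML or JSON config file into a dict."""
    p = Path(path)
    try:
        text = p.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    try:
        doc = json.loads(text) if p.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"config root must be a mapping, got {type(doc).__name__}")
    return doc


def subseed(global_seed: int, name: str) -> np.random.SeedSequence:
    """Deterministic named sub-seed of a global seed."""
    return np.random.SeedSequence([int(global_seed), zlib.crc32(name.encode())])


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config dict (canonical JSON, sha256)."""
    canon = json.dumps(cfg, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def provenance(cfg: dict, seed: int) -> dict:
    """Provenance sidecar contents for a run."""
    from . import __version__

    return {
        "config": cfg,
        "config_hash": config_hash(cfg),
        "seed": int(seed),
        "ionliquid_version": __version__,
        "numpy_version": np.__version__,
    }


def require(cfg: dict, path: str, default=None, required: bool = False):
    """Fetch ``block.key`` style entries with config-path error messages."""
    node = cfg
    parts = path.split(".")
    for i, part in enumerate(parts):
        if not isinstance(node, dict) or part not in node:
            if required:
                raise ConfigError(f"missing config field '{'.'.join(parts[:i + 1])}'")
            return default
        node = node[part]
    return node
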