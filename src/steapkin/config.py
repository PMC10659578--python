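"""Structured run configuration (YAML) with strict key checking."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError"]

DEFAULT_SEED = 0

_KNOWN_KEYS = {
    "command", "fixture", "seed", "sigma_AU", "noise_frac", "out_dir",
    "input", "n_phases", "n_species", "direction", "window_s", "law",
    "phase", "init_rates", "nonneg_spectra", "substrate_uM", "mechanism",
}


class ConfigError(ValueError):
    """Unknown or invalid configuration key."""


@dataclass
class RunConfig:
    """Parameters of one run; unknown keys are rejected.

    Every stochastic run carries an explicit seed; if none is given the
    default is recorded so the run stays regenerable.
    """

    values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.values) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        self.values.setdefault("seed", DEFAULT_SEED)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls(data)

    def override(self, **kwargs) -> "RunConfig":
        """CLI flags override config-file keys (None values are skipped)."""
        merged = dict(self.values)
        merged.update({k: v for k, v in kwargs.items() if v is not None})
        return RunConfig(merged)

    def get(self, key: str, default=None):
        return self.values.get(key, default)

    @property
    def seed(self) -> int:
        return int(self.values["seed"])

    def digest(self) -> str:
        """Stable hash of the configuration, for run logging."""
        blob = json.dumps(self.values, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        """Per-stage seed derived from the top-level seed (documented, stable)."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)
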