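"""Run configuration: YAML loading, validation, and hashing.

A single YAML file drives the end-to-end pipeline.  Every output file embeds
the configuration hash and the seed so a result can be traced back to the
exact settings that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .io_toxdata import EndpointClass
from .population import AllometryParams

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    """Settings for one end-to-end MSAR run.

    Paths are resolved relative to the config file's directory when loaded
    from YAML.  ``chemical`` filters the input table when it covers several
    chemicals; ``variant`` selects the community curve flavour; ``hc5_on``
    chooses whether the HC5 is read off the log-logistic refit (default) or
    the raw piecewise curve.
    """

    input: str
    traits: str | None = None
    chemical: str | None = None
    outdir: str = "msar_out"
    schema: dict | None = None
    endpoint_mapping: dict | None = None
    unit_factor: float = 1.0
    strict_endpoints: bool = True
    weight_by_n: bool = False
    abbott: bool = True
    allometry: dict | None = None
    grid_n: int = 200
    variant: str = "default"
    hc5_on: str = "fit"
    n_iter: int = 1000
    n_boot: int = 1000
    seed: int = 0
    include_residual: bool = False

    def __post_init__(self):
        if self.hc5_on not in ("fit", "raw"):
            raise ConfigError("hc5_on must be 'fit' or 'raw'")
        if self.n_iter < 2 or self.n_boot < 2:
            raise ConfigError("n_iter and n_boot must be at least 2")
        if self.grid_n < 10:
            raise ConfigError("grid_n must be at least 10")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        # resolve paths relative to the config file
        base = path.parent
        cfg.input = str((base / cfg.input).resolve())
        if cfg.traits:
            cfg.traits = str((base / cfg.traits).resolve())
        return cfg

    def validate_files(self) -> None:
        if not Path(self.input).exists():
            raise ConfigError(f"input file not found: {self.input}")
        if self.traits and not Path(self.traits).exists():
            raise ConfigError(f"traits file not found: {self.traits}")

    def endpoint_table(self) -> dict[str, EndpointClass] | None:
        if self.endpoint_mapping is None:
            return None
        return {k.lower(): EndpointClass(v) for k, v in self.endpoint_mapping.items()}

    def allometry_params(self) -> AllometryParams | None:
        if self.allometry is None:
            return None
        return AllometryParams(**self.allometry)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        """Hash of the analytic settings; the output directory is excluded."""
        settings = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        canon = json.dumps(settings, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def meta(self) -> dict:
        return {"config_hash": self.config_hash, "seed": self.seed}
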