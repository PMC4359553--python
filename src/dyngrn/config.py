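"""Pipeline configuration: parsing, defaults and validation."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml


class ConfigError(ValueError):
    """Raised with the offending field path when a config value is invalid."""


@dataclass
class PipelineConfig:
    """All knobs of the two-step workflow, with the method's defaults.

    Path fields default to the standard artifact names inside ``outdir``, so
    subcommands chain without explicit wiring.
    """

    outdir: str = "dyngrn_out"
    seed: int = 0
    # synthetic dataset geometry
    n_genes: int = 12
    n_tf: int = 5
    region_len: int = 1500
    sigma: float = 0.05
    stages: List[str] = field(default_factory=lambda: ["S0", "S1", "S2", "S3"])
    # cis-regions and scanning
    cis_width: int = 40000
    scan_threshold: float = 0.90
    # expression filters
    gene_fpkm_min: float = 1.0
    tf_fpkm_min: float = 25.0
    # segments
    segment_width: int = 50
    segment_step: int = 5
    pi_default: float = 0.25
    # solver
    loss: str = "squared"
    lambda1_grid: List[float] = field(default_factory=lambda: [0.001, 0.01, 0.1])
    lambda2_grid: List[float] = field(default_factory=lambda: [0.0, 0.01, 0.1])
    lambda1: Optional[float] = None  # fixed values skip cross-validation
    lambda2: Optional[float] = None
    # bootstrap
    bootstrap_n: int = 100
    bootstrap_genes: int = 3
    # perturbation
    perturb_tf: Optional[str] = None
    perturb_fold: float = 5.0
    # optional explicit input paths (default: artifacts in outdir)
    paths: Dict[str, str] = field(default_factory=dict)

    def artifact(self, name: str) -> Path:
        if name in self.paths:
            return Path(self.paths[name])
        return Path(self.outdir) / name

    def to_dict(self) -> dict:
        return asdict(self)


_DEFAULTS = PipelineConfig()


def validate_config(raw: dict) -> PipelineConfig:
    """Fill defaults and reject conflicting or out-of-range values."""
    known = set(_DEFAULTS.to_dict())
    for key in raw:
        if key not in known:
            raise ConfigError(f"unknown config field: {key}")
    cfg = PipelineConfig(**raw)
    if cfg.seed < 0:
        raise ConfigError("seed: must be non-negative")
    if len(cfg.stages) < 2:
        raise ConfigError("stages: need at least two stage labels")
    if len(set(cfg.stages)) != len(cfg.stages):
        raise ConfigError("stages: labels must be unique")
    if cfg.cis_width <= 0 or cfg.cis_width % 2:
        raise ConfigError("cis_width: must be a positive even number")
    if not 0 < cfg.scan_threshold <= 1:
        raise ConfigError("scan_threshold: must be in (0, 1]")
    if cfg.segment_width <= 0 or cfg.segment_step <= 0:
        raise ConfigError("segment_width/segment_step: must be positive")
    if cfg.sigma < 0:
        raise ConfigError("sigma: must be non-negative")
    for name, grid in (("lambda1_grid", cfg.lambda1_grid),
                       ("lambda2_grid", cfg.lambda2_grid)):
        if not grid:
            raise ConfigError(f"{name}: must be non-empty")
        if any(l < 0 for l in grid):
            raise ConfigError(f"{name}: penalties must be non-negative")
    for name, val in (("lambda1", cfg.lambda1), ("lambda2", cfg.lambda2)):
        if val is not None and val < 0:
            raise ConfigError(f"{name}: must be non-negative")
    if cfg.loss not in ("squared", "abs"):
        raise ConfigError("loss: must be 'squared' or 'abs'")
    if cfg.bootstrap_n < 1:
        raise ConfigError("bootstrap_n: must be >= 1")
    if not 0 <= cfg.pi_default <= 1:
        raise ConfigError("pi_default: must be in [0, 1]")
    for key, path in cfg.paths.items():
        if not Path(path).exists():
            raise ConfigError(f"paths.{key}: file not found: {path}")
    return cfg


def load_config(path) -> PipelineConfig:
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        raw = yaml.safe_load(text) or {}
    else:
        raw = json.loads(text)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    return validate_config(raw)
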