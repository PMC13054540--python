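"""Pipeline configuration: defaults, validation, hashing, per-stage seeds."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .curation import DEFAULT_CLASSES, DEFAULT_PER_CLASS_CAP

STAGES = ("synth", "tile", "train-ae", "embed", "cluster", "sample", "export", "assemble")


@dataclass
class PipelineConfig:
    tile_size: int = 256
    downsample: int = 32
    tissue_threshold: float = 0.25
    m: int = 400                  # target mean cluster size
    g: int = 5                    # equal-frequency bins per cluster
    sample_fraction: float = 0.2  # per-bin sampling fraction
    per_class_cap: int = DEFAULT_PER_CLASS_CAP
    classes: tuple[str, ...] = DEFAULT_CLASSES
    master_seed: int = 0
    # autoencoder settings
    ae_width_factor: int = 8      # 1 = full width (channels up to 512)
    ae_epochs: int = 3
    ae_batch_size: int = 8
    ae_learning_rate: float = 1e-4
    # synthetic-slide stage settings
    synth_side: int = 1536
    synth_region_side: int = 512
    synth_margin: int = 256
    # embedding / clustering
    pca_components: int = 256
    n_init: int = 10
    max_iter: int = 300
    tol: float = 1e-4
    n_neighbors: int = 4

    def validate(self) -> None:
        positive = ["tile_size", "downsample", "m", "g", "per_class_cap", "ae_batch_size",
                    "ae_width_factor", "pca_components", "n_init", "max_iter",
                    "synth_side", "synth_region_side", "synth_margin", "n_neighbors"]
        for name in positive:
            if getattr(self, name) < 1:
                raise ValueError(f"config.{name}: must be a positive integer, got {getattr(self, name)}")
        if not 0.0 <= self.tissue_threshold <= 1.0:
            raise ValueError(f"config.tissue_threshold: must be in [0, 1], got {self.tissue_threshold}")
        if not 0.0 < self.sample_fraction <= 1.0:
            raise ValueError(f"config.sample_fraction: must be in (0, 1], got {self.sample_fraction}")
        if self.ae_learning_rate <= 0 or self.tol <= 0:
            raise ValueError("config.ae_learning_rate/tol: must be positive")
        if self.ae_epochs < 0:
            raise ValueError("config.ae_epochs: must be >= 0")
        if not self.classes:
            raise ValueError("config.classes: class vocabulary must not be empty")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        """Per-stage seed derived from the master seed by a fixed counter scheme."""
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; stages are {STAGES}")
        return (self.master_seed * 1_000_003 + STAGES.index(stage)) % 2 ** 31


def validate_config(raw: dict | str | Path | None) -> PipelineConfig:
    """Build a PipelineConfig from a mapping or a YAML file; inject defaults.

    An empty document yields the full defaults (256, 32, 0.25, 400, 5, 0.2,
    70,000). Unknown keys and invariant violations are reported with their
    field path.
    """
    if raw is None:
        raw = {}
    if isinstance(raw, (str, Path)):
        text = Path(raw).read_text()
        try:
            raw = yaml.safe_load(text) or {}
        except yaml.YAMLError as exc:
            raise ValueError(f"malformed config document: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValueError(f"config document must be a mapping, got {type(raw).__name__}")
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    if "classes" in raw:
        raw = {**raw, "classes": tuple(raw["classes"])}
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg
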