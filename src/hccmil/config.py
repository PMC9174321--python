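"""Pipeline configuration: nested, validated, YAML round-trippable.

Unknown keys are rejected (typos fail loudly); every default is visible in
the model definitions below.  The MIL defaults are the published operating
point of the classifier: threshold t = 0.4457, aggregation exponent p = 3,
L2 factor alpha = 0.02, initial learning rate 1e-4 halving every 10 epochs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = ["PipelineConfig", "load_config", "save_config", "config_hash"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class SimulationConfig(_Section):
    n_slides_per_class: int = Field(10, ge=1)
    n_tiles: int = Field(8, ge=1)
    tile_size: int = Field(32, ge=32)
    signal_fraction: float = Field(0.5, ge=0.0, le=1.0)
    stroma_probability: float = Field(0.6, ge=0.0, le=1.0)
    immune_density: float = Field(4.0, ge=0.0)
    n_seg_pairs: int = Field(40, ge=2)
    test_fraction: float = Field(0.25, gt=0.0, lt=1.0)
    survival_log_hr: float = 1.1
    censoring_rate: float = Field(0.25, ge=0.0, lt=1.0)


class TilingConfig(_Section):
    tile_size: int = Field(512, ge=32)
    resize: int = Field(224, ge=8)
    mpp: float = Field(0.25, gt=0)
    tissue_threshold: float = Field(0.25, ge=0.0, le=1.0)


class NormalizationConfig(_Section):
    enabled: bool = True
    sparsity: float = Field(0.1, ge=0.0)


class SegmentationConfig(_Section):
    depth: int = Field(3, ge=2)
    base_channels: int = Field(8, ge=1)
    epochs: int = Field(4, ge=0)
    learning_rate: float = Field(1e-3, gt=0)
    epsilon: float = Field(1e-8, gt=0)


class MILSection(_Section):
    aggregation_exponent: float = Field(3.0, ge=1.0)
    threshold: float = 0.4457
    l2_alpha: float = Field(0.02, ge=0.0)
    initial_lr: float = Field(0.0001, gt=0.0)
    lr_halving_epochs: int = Field(10, ge=1)
    bag_batch_size: int = Field(1, ge=1)
    backbone_variant: str = "tiny"
    epochs: int = Field(6, ge=1)

    @field_validator("threshold")
    @classmethod
    def _threshold_open_interval(cls, v):
        if not 0.0 < v < 1.0:
            raise ValueError("threshold must lie strictly between 0 and 1")
        return v

    @field_validator("backbone_variant")
    @classmethod
    def _known_variant(cls, v):
        if v not in ("tiny", "standard"):
            raise ValueError("backbone_variant must be 'tiny' or 'standard'")
        return v


class EvaluationConfig(_Section):
    horizons: list[float] = Field(
        default_factory=lambda: [6.0, 12.0, 18.0, 24.0, 30.0])
    n_bootstrap: int = Field(100, ge=10)


class PipelineConfig(_Section):
    seed: int = 0
    out_dir: str = "runs/run"
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    tiling: TilingConfig = Field(default_factory=TilingConfig)
    normalization: NormalizationConfig = Field(default_factory=NormalizationConfig)
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    mil: MILSection = Field(default_factory=MILSection)
    evaluation: EvaluationConfig = Field(default_factory=EvaluationConfig)


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML config; an empty file yields all defaults.

    Unknown keys, type mismatches and constraint violations raise a
    pydantic ``ValidationError`` naming the offending key.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return PipelineConfig.model_validate(data)


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=True))


def config_hash(config: PipelineConfig) -> str:
    """Stable hash of the full configuration (used to tag artifacts)."""
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
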