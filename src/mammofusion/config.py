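"""Run configuration: validated YAML settings for every pipeline stage."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .augment import AugmentConfig
from .preprocess import PreprocessConfig
from .train_eval import TrainConfig

__all__ = ["RunConfig", "ModelSettings", "load_config", "dump_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PreprocessSettings(_Strict):
    clahe_clip: float = 2.0
    clahe_tiles: tuple[int, int] = (8, 8)
    bilateral_diameter: int = 9
    bilateral_sigma_color: float = 75.0
    bilateral_sigma_space: float = 75.0
    target_size: int = 512

    def to_dataclass(self) -> PreprocessConfig:
        return PreprocessConfig(**self.model_dump())


class AugmentSettings(_Strict):
    n_single: int = 50
    scale_range: tuple[float, float] = (0.8, 1.0)
    translate_frac: float = 0.10
    rotation_range: tuple[float, float] = (0.0, 180.0)
    noise_sigma: float = 0.01
    contrast_gamma: tuple[float, float] = (0.8, 1.2)
    crop_frac: tuple[float, float] = (0.85, 1.0)
    include_flip_composition: bool = True
    seed: int = 0

    def to_dataclass(self) -> AugmentConfig:
        return AugmentConfig(**self.model_dump())


class TrainSettings(_Strict):
    lr: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 1e-4
    batch_size: int = 16
    epochs: int = 300
    seed: int = 0

    def to_dataclass(self) -> TrainConfig:
        return TrainConfig(**self.model_dump())


class ModelSettings(_Strict):
    image_size: int = 512
    block_sizes: tuple[int, ...] = (6, 12, 24, 32, 16)
    growth_rate: int = 32
    stem_channels: int = 64
    reduction_ratio: int = 16
    batch_norm: bool = True
    fusion_width: int = 1024


class RunConfig(_Strict):
    data_root: str = "data"
    output_root: str = "runs"
    task: str = "screening"
    seed: int = 0
    preprocess: PreprocessSettings = Field(default_factory=PreprocessSettings)
    augment: AugmentSettings = Field(default_factory=AugmentSettings)
    train: TrainSettings = Field(default_factory=TrainSettings)
    model: ModelSettings = Field(default_factory=ModelSettings)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Merged configuration: defaults <- YAML file <- keyword overrides.

    Unknown keys anywhere raise a validation error.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must contain a mapping")
        data.update(loaded)
    for key, value in overrides.items():
        if value is None:
            continue
        if isinstance(value, dict):
            data.setdefault(key, {})
            data[key] = {**data[key], **{k: v for k, v in value.items() if v is not None}}
        else:
            data[key] = value
    return RunConfig(**data)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the config echo (every run directory gets one)."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=False)
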