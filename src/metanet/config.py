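"""Experiment configuration: schema, defaults, and cross-field validation."""

from __future__ import annotations

import hashlib
import json
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import ConfigurationError
from .synthetic_data import (MODALITY_A, MODALITY_B, AudioCategoryParams,
                             SyntheticModalityConfig, VisionCategoryParams,
                             default_configs)


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class VisionCategoryConfig(_Model):
    correlation_length: float = Field(gt=0)
    orientation: float = 0.0
    anisotropy: float = Field(default=1.0, ge=1.0)


class AudioCategoryConfig(_Model):
    fundamental_row: int = Field(ge=0, le=15)
    n_harmonics: int = Field(default=3, ge=1)
    smoothness: float = Field(default=0.5, ge=0.0, lt=1.0)


def _default_vision_categories() -> list[VisionCategoryConfig]:
    cfg_a, _ = default_configs()
    return [VisionCategoryConfig(correlation_length=p.correlation_length,
                                 orientation=p.orientation, anisotropy=p.anisotropy)
            for p in cfg_a.category_params]


def _default_audio_categories() -> list[AudioCategoryConfig]:
    _, cfg_b = default_configs()
    return [AudioCategoryConfig(fundamental_row=p.fundamental_row,
                                n_harmonics=p.n_harmonics, smoothness=p.smoothness)
            for p in cfg_b.category_params]


class SuiteConfig(_Model):
    kind: Literal["synthetic"] = "synthetic"
    n_patches_per_dataset: int = Field(default=20_000, ge=1)
    noise_sd: float = Field(default=0.05, ge=0.0)
    vision_categories: list[VisionCategoryConfig] = Field(
        default_factory=_default_vision_categories, min_length=2)
    audio_categories: list[AudioCategoryConfig] = Field(
        default_factory=_default_audio_categories, min_length=2)

    @property
    def n_datasets(self) -> int:
        return len(self.vision_categories) + len(self.audio_categories)


class FirstOrderConfig(_Model):
    """Desk-scale defaults: 10 epochs over 20k patches at batch 32
    stand in for the full-scale regime's single epoch over 1M patches
    (similar optimizer step counts); lr raised accordingly."""

    n_models: int = Field(default=60, ge=2)
    n_train: int = Field(default=50, ge=1)
    epochs: int = Field(default=10, ge=1)
    batch_size: int = Field(default=32, ge=1)
    learning_rate: float = Field(default=6e-3, gt=0)


class StageConfig(_Model):
    epochs: int = Field(default=50, ge=1)
    batch_size: int = Field(default=128, ge=1)
    learning_rate: float = Field(default=3e-3, gt=0)


class KnnConfig(_Model):
    k: int = Field(default=10, ge=1)
    metric: str = "euclidean"


class TsneConfig(_Model):
    enabled: bool = False
    perplexity: float = Field(default=30.0, gt=0)


class ExperimentConfig(_Model):
    seed: int = 0
    out_dir: str = "runs/default"
    cache: bool = True
    suite: SuiteConfig = Field(default_factory=SuiteConfig)
    first_order: FirstOrderConfig = Field(default_factory=FirstOrderConfig)
    unitwise: StageConfig = Field(default_factory=StageConfig)
    interunit: StageConfig = Field(default_factory=StageConfig)
    knn: KnnConfig = Field(default_factory=KnnConfig)
    tsne: TsneConfig = Field(default_factory=TsneConfig)

    @model_validator(mode="after")
    def _cross_field(self):
        if self.first_order.n_train >= self.first_order.n_models:
            raise ValueError(
                f"first_order.n_train ({self.first_order.n_train}) must be smaller than "
                f"first_order.n_models ({self.first_order.n_models})")
        n_refs = self.suite.n_datasets * self.first_order.n_train
        if self.knn.k > n_refs:
            raise ValueError(
                f"knn.k ({self.knn.k}) exceeds the configured number of reference nets "
                f"({n_refs} = suite datasets x first_order.n_train)")
        if self.tsne.enabled:
            n_val = self.suite.n_datasets * (self.first_order.n_models - self.first_order.n_train)
            if n_val <= 3 * self.tsne.perplexity:
                raise ValueError(
                    f"tsne.perplexity ({self.tsne.perplexity}) requires more than "
                    f"{3 * self.tsne.perplexity:.0f} validation nets, configured {n_val}")
        return self

    # -- derived objects ----------------------------------------------------

    def modality_configs(self) -> tuple[SyntheticModalityConfig, SyntheticModalityConfig]:
        cfg_a = SyntheticModalityConfig(
            MODALITY_A,
            tuple(VisionCategoryParams(**c.model_dump()) for c in self.suite.vision_categories),
            noise_sd=self.suite.noise_sd, seed=self.seed)
        cfg_b = SyntheticModalityConfig(
            MODALITY_B,
            tuple(AudioCategoryParams(**c.model_dump()) for c in self.suite.audio_categories),
            noise_sd=self.suite.noise_sd, seed=self.seed + 1)
        return cfg_a, cfg_b

    def resolved_dict(self) -> dict:
        return self.model_dump(mode="json")


def validate_config(raw) -> ExperimentConfig:
    """Parse YAML text (or a mapping) into a fully defaulted ExperimentConfig.

    Every violation is reported with its field path.
    """
    if isinstance(raw, ExperimentConfig):
        return raw
    if isinstance(raw, str):
        try:
            raw = yaml.safe_load(raw)
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"config is not valid YAML: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a YAML mapping")
    try:
        return ExperimentConfig.model_validate(raw)
    except ValidationError as exc:
        lines = []
        for err in exc.errors():
            path = ".".join(str(p) for p in err["loc"]) or "<root>"
            lines.append(f"{path}: {err['msg']}")
        raise ConfigurationError("invalid experiment config:\n  " + "\n  ".join(lines)) from exc


def load_config(path) -> ExperimentConfig:
    with open(path) as f:
        return validate_config(f.read())


def subtree_hash(*subtrees) -> str:
    """Stable short hash of config subtrees, used as the stage cache key."""
    blob = json.dumps([s.model_dump(mode="json") if isinstance(s, BaseModel) else s
                       for s in subtrees], sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
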