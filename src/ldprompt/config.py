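"""Strict YAML configuration schemas (unknown keys are rejected)."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .distill import DistillConfig
from .models import ModelSpec
from .synthetic import SceneConfig
from .training import RunConfig


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SceneSection(_Strict):
    image_size: int = 64
    min_instances: int = 1
    max_instances: int = 3
    shape_family: str = "smoothed-blob"
    fg_mean: float = 0.62
    bg_mean: float = 0.38
    noise_std: float = 0.18
    blur_radius: float = 2.0
    min_radius: float = 4.0
    max_radius: float = 10.0
    seed: int

    def build(self) -> SceneConfig:
        return SceneConfig(**self.model_dump())


class DistillSection(_Strict):
    temperature: float = 10.0
    lambda_main: float = 1.0
    lambda_vlr: float = 1.0
    alpha_pos: float = Field(0.7, gt=0, le=1)
    gamma: float = Field(0.5, gt=0, le=1)
    tau_square_rescale: bool = True

    def build(self) -> DistillConfig:
        return DistillConfig(**self.model_dump())


class ModelSection(_Strict):
    image_size: int = 64
    embed_dim: int = 64
    adapter_width: int = 8
    student_width: int = 8
    teacher_width: int = 32
    fused_channels: int = 64
    num_sparse_tokens: int = 4
    bins: int = 8
    decoder_rounds: int = 2
    decoder_heads: int = 2

    def build(self) -> ModelSpec:
        return ModelSpec(**self.model_dump())


class RunSection(_Strict):
    teacher_epochs: int = 12
    phase1_epochs: int = 10
    phase1_lr: float = 3e-3
    phase2_epochs: int = 14
    phase2_lr: float = 1e-4
    cosine: bool = True
    batch_size: int = 16
    prompt_mode: str = "dense+sparse"
    distill_mode: str = "ld_main_vlr"
    seeds: list[int] = [10, 42, 123]

    def build(self) -> RunConfig:
        d = self.model_dump()
        d["seeds"] = tuple(d["seeds"])
        return RunConfig(**d)


class ExperimentConfig(_Strict):
    """Top-level config for the command-line interface."""

    scene: SceneSection
    distill: DistillSection = DistillSection()
    model: ModelSection = ModelSection()
    run: RunSection = RunSection()
    n_samples: int = 200
    test_fraction: float = 0.2
    val_fraction: float = 0.1
    split_seed: int = 2025


def load_config(path: str | Path) -> ExperimentConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path} does not contain a mapping")
    cfg = ExperimentConfig.model_validate(raw)
    # re-validate the enum fields through the dataclasses
    cfg.run.build()
    cfg.scene.build()
    cfg.distill.build()
    return cfg
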