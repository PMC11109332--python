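"""Experiment configuration: serializable description of architecture, patching
and optimization.

Every run of the pipeline is fully described by an :class:`ExperimentConfig`,
which round-trips losslessly through JSON, so an experiment can be reproduced
from its configuration file and seed alone.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Any, Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "ClassifierSpec",
    "TrainingConfig",
    "StepDecay",
    "AugmentationStep",
    "PatchConfig",
    "PathsConfig",
    "ExperimentConfig",
    "load_config",
    "save_config",
]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ClassifierSpec(_StrictModel):
    """Architecture of the minimalist CNN family.

    The network is defined by two degrees of freedom — its *depth* (number of
    convolution blocks) and *width* (filters per convolution) — for 2D or 3D
    inputs with an arbitrary number of channels.
    """

    dim: Literal[2, 3] = 2
    depth: int = Field(3, ge=1)
    width: int = Field(32, ge=1)
    in_channels: int = Field(2, ge=1)
    n_classes: int = Field(2, ge=2, le=9)
    kernel_extent: int = Field(3, ge=1)
    patch_size: Optional[tuple[int, ...]] = None

    @model_validator(mode="after")
    def _check_patch(self) -> "ClassifierSpec":
        if self.patch_size is not None:
            if len(self.patch_size) != self.dim:
                raise ValueError(
                    f"patch_size has {len(self.patch_size)} axes but dim={self.dim}"
                )
            if any(s < 1 for s in self.patch_size):
                raise ValueError("patch_size entries must be >= 1")
        return self


class StepDecay(_StrictModel):
    """Multiply the learning rate by ``factor`` every ``every_n_epochs`` epochs.

    ``every_n_epochs=None`` resolves to ``ceil(epochs / 3)`` at training time.
    """

    every_n_epochs: Optional[int] = Field(None, ge=1)
    factor: float = Field(0.5, gt=0.0, le=1.0)


class AugmentationStep(_StrictModel):
    name: str
    params: dict[str, Any] = Field(default_factory=dict)
    probability: float = Field(0.5, ge=0.0, le=1.0)


class TrainingConfig(_StrictModel):
    """Optimization settings: Adam with step decay and cross-entropy loss."""

    epochs: int = Field(600, ge=1)
    batch_size: int = Field(16, ge=1)
    learning_rate: float = Field(1e-3, gt=0.0)
    betas: tuple[float, float] = (0.9, 0.999)
    step_decay: StepDecay = Field(default_factory=StepDecay)
    loss: Literal["cross_entropy"] = "cross_entropy"
    augmentation: list[AugmentationStep] = Field(default_factory=list)
    class_weighting: Literal["none", "inverse_frequency"] = "none"
    validation_fraction: float = Field(0.0, ge=0.0, le=0.5)
    seed: int = 0

    def decay_interval(self) -> int:
        if self.step_decay.every_n_epochs is not None:
            return self.step_decay.every_n_epochs
        return max(1, math.ceil(self.epochs / 3))


class PatchConfig(_StrictModel):
    """How per-object patches are cut and normalized.

    ``patch_size=None`` resolves to 137x137 in 2D and 45x45x45 in 3D.
    ``include_mask_channel`` appends a binary silhouette of the object being
    classified as an extra input channel, disambiguating it from neighbours
    that fall inside the same crop. ``intensity_scale`` divides the intensity
    channels by a fixed global constant (e.g. 255 for 8-bit data) before
    patch extraction — useful with ``normalization="none"`` when absolute
    intensity is the class signal and per-patch min-max would erase it.
    """

    patch_size: Optional[tuple[int, ...]] = None
    include_mask_channel: bool = True
    normalization: Literal["minmax", "per_channel_minmax", "none"] = "minmax"
    intensity_scale: float = Field(1.0, gt=0.0)

    def resolved_size(self, dim: int) -> tuple[int, ...]:
        if self.patch_size is not None:
            if len(self.patch_size) != dim:
                raise ValueError(
                    f"patch_size has {len(self.patch_size)} axes but dim={dim}"
                )
            return self.patch_size
        return (137, 137) if dim == 2 else (45, 45, 45)


class PathsConfig(_StrictModel):
    input_dir: str = "."
    output_dir: str = "out"


class ExperimentConfig(_StrictModel):
    classifier: ClassifierSpec = Field(default_factory=ClassifierSpec)
    training: TrainingConfig = Field(default_factory=TrainingConfig)
    patch: PatchConfig = Field(default_factory=PatchConfig)
    paths: PathsConfig = Field(default_factory=PathsConfig)
    seed: int = 0


def load_config(path: str | Path) -> ExperimentConfig:
    """Load an :class:`ExperimentConfig` from JSON.

    Missing keys are filled with defaults; unknown keys are rejected with
    their names; invalid values name the offending field.
    """
    with open(path) as fh:
        data = json.load(fh)
    return ExperimentConfig(**data)


def save_config(config: ExperimentConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(config.model_dump(), indent=2) + "\n")
    return path
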