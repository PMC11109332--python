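"""Data augmentation registry: flips, 90-degree and free-angle rotations.

Transforms act on a single patch (C', [z,] y, x) in the trailing (y, x)
plane; the mask channel, when present, is transformed identically to the
intensity channels. New transforms can be registered by name, mirroring the
dictionary-style augmentation configuration of the original tool.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .config import AugmentationStep

__all__ = ["register_transform", "augment", "known_transforms"]

_REGISTRY: dict[str, Callable] = {}


def register_transform(name: str, fn: Callable) -> None:
    """Register `fn(patch, rng, **params) -> patch` under `name`."""
    _REGISTRY[name] = fn


def known_transforms() -> list[str]:
    return sorted(_REGISTRY)


def _hflip(patch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return patch[..., ::-1]


def _vflip(patch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return patch[..., ::-1, :]


def _rot90(patch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return np.rot90(patch, k=1, axes=(-2, -1))


def _rotate(
    patch: np.ndarray,
    rng: np.random.Generator,
    angle_range: Sequence[float] = (-180.0, 180.0),
) -> np.ndarray:
    angle = float(rng.uniform(angle_range[0], angle_range[1]))
    return ndimage.rotate(
        patch, angle, axes=(-2, -1), reshape=False, order=1, mode="constant"
    )


register_transform("hflip", _hflip)
register_transform("vflip", _vflip)
register_transform("rot90", _rot90)
register_transform("rotate", _rotate)


def augment(
    patch: np.ndarray,
    pipeline: Sequence[AugmentationStep],
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply each step of the pipeline with its probability, in order."""
    out = patch
    for step in pipeline:
        if step.name not in _REGISTRY:
            raise KeyError(
                f"unknown transform {step.name!r}; known: {known_transforms()}"
            )
        if rng.random() < step.probability:
            out = _REGISTRY[step.name](out, rng, **step.params)
    return np.ascontiguousarray(out, dtype=patch.dtype)
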