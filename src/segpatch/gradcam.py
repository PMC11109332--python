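"""Grad-CAM: gradient-weighted class activation maps for the minimalist CNN.

The map for a target class is the rectified weighted sum of the last
convolution block's output channels, each weighted by the spatial average of
the target logit's gradient with respect to that channel, upsampled to the
patch's spatial size. In this architecture everything after the last block is
global average pooling followed by an affine head, so the gradient of logit
k with respect to activation channel c is exactly W_head[k, c] / S at every
position (S = spatial size of the feature map); the spatial average equals
the same constant, which this implementation uses directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .nn import SmallConvNet

__all__ = ["Heatmap", "gradcam"]


@dataclass
class Heatmap:
    """Non-negative class activation map at the input patch's spatial shape."""

    raw: np.ndarray
    rescaled: np.ndarray  # min-max view in [0, 1]; all-zero map stays zero
    target_class_index: int

    def __post_init__(self) -> None:
        if self.raw.size and self.raw.min() < 0:
            raise ValueError("heatmap values must be non-negative")


def gradcam(
    model: SmallConvNet,
    patch: np.ndarray,
    target_class_index: int,
    interpolation: str = "nearest",
) -> Heatmap:
    """Class activation map of one patch for a 0-based target class index."""
    K = model.spec.n_classes
    if not 0 <= target_class_index < K:
        raise ValueError(f"target class index {target_class_index} not in 0..{K - 1}")
    patch = np.asarray(patch, dtype=np.float32)
    if patch.ndim != model.spec.dim + 1:
        raise ValueError(
            f"patch must be (C, {'*' * model.spec.dim}); got shape {patch.shape}"
        )
    _, feats = model.forward_with_features(patch[np.newaxis])
    A = feats[0]  # (width, *sp')
    S = int(np.prod(A.shape[1:]))
    # d logit_k / dA_c is W_head[k, c] / S everywhere; its spatial mean too.
    channel_weights = model.head.W[target_class_index] / S
    cam = np.maximum(np.tensordot(channel_weights, A, axes=(0, 0)), 0.0)
    order = {"nearest": 0, "linear": 1}.get(interpolation)
    if order is None:
        raise ValueError(f"interpolation must be 'nearest' or 'linear', got {interpolation!r}")
    raw = resize(
        cam, patch.shape[1:], order=order, preserve_range=True, anti_aliasing=False
    ).astype(np.float32)
    hi = float(raw.max())
    rescaled = raw / hi if hi > 0 else np.zeros_like(raw)
    return Heatmap(raw=raw, rescaled=rescaled, target_class_index=target_class_index)
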