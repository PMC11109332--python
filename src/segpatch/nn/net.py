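"""The minimalist CNN family: depth x width convolutional classifiers.

The architecture is `depth` blocks of [conv k^dim (same padding) -> ReLU ->
max-pool 2] at constant `width`, followed by global average pooling and an
affine map to the class logits. The GAP head makes one spec serve any patch
size. The trainable-parameter count has the closed form

    C*w*k^dim + w  +  (d-1)*(w^2*k^dim + w)  +  w*K + K.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np

from ..config import ClassifierSpec, PatchConfig
from .layers import Conv, GlobalAvgPool, Linear, MaxPool, ReLU

__all__ = [
    "SmallConvNet",
    "build_model",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]


class SmallConvNet:
    """Callable patch-batch -> logits classifier built from a ClassifierSpec."""

    def __init__(
        self,
        spec: ClassifierSpec,
        seed: int = 0,
        dtype=np.float32,
        zero_init_head: bool = True,
    ) -> None:
        if spec.patch_size is not None:
            min_size = 2**spec.depth
            bad = [s for s in spec.patch_size if s < min_size]
            if bad:
                raise ValueError(
                    f"patch size {spec.patch_size} too small for depth {spec.depth}; "
                    f"each axis must be >= {min_size}"
                )
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        d, w, k, dim = spec.depth, spec.width, spec.kernel_extent, spec.dim
        self.layers: list = []
        cin = spec.in_channels
        for _ in range(d):
            self.layers += [Conv(cin, w, k, dim, rng, dtype), ReLU(), MaxPool(dim)]
            cin = w
        self.gap = GlobalAvgPool()
        self.head = Linear(w, spec.n_classes, rng, dtype, zero_init=zero_init_head)
        self.layers += [self.gap, self.head]

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        self._check_input(x)
        for layer in self.layers:
            x = layer.forward(x)
        return x

    __call__ = forward

    def forward_with_features(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Logits plus the activations entering the global average pool
        (the last convolution block's output), for Grad-CAM."""
        x = np.asarray(x, dtype=self.dtype)
        self._check_input(x)
        for layer in self.layers[:-2]:
            x = layer.forward(x)
        feats = x
        logits = self.head.forward(self.gap.forward(x))
        return logits, feats

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        g = dlogits
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def _check_input(self, x: np.ndarray) -> None:
        expected = self.spec.in_channels
        if x.ndim != self.spec.dim + 2 or x.shape[1] != expected:
            raise ValueError(
                f"expected batch of shape (N, {expected}, {'*' * self.spec.dim}) "
                f"for dim={self.spec.dim}; got {x.shape}"
            )
        min_size = 2**self.spec.depth
        if any(s < min_size for s in x.shape[2:]):
            raise ValueError(
                f"input spatial shape {x.shape[2:]} too small for depth "
                f"{self.spec.depth} (minimum {min_size} per axis)"
            )

    # -- parameters --------------------------------------------------------
    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params)

    def set_params(self, arrays: list[np.ndarray]) -> None:
        own = self.params
        if len(arrays) != len(own):
            raise ValueError(f"expected {len(own)} arrays, got {len(arrays)}")
        for p, a in zip(own, arrays):
            if p.shape != a.shape:
                raise ValueError(f"weight shape mismatch: {p.shape} vs {a.shape}")
            p[...] = a.astype(p.dtype)


def build_model(spec: ClassifierSpec, seed: int = 0, **kwargs) -> SmallConvNet:
    return SmallConvNet(spec, seed=seed, **kwargs)


def count_parameters(spec: ClassifierSpec) -> int:
    """Closed-form trainable-weight count of the minimalist architecture."""
    kd = spec.kernel_extent**spec.dim
    w, d, C, K = spec.width, spec.depth, spec.in_channels, spec.n_classes
    return C * w * kd + w + (d - 1) * (w**2 * kd + w) + w * K + K


# -- checkpoints -----------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def save_checkpoint(
    model: SmallConvNet,
    path: str | Path,
    patch: Optional[PatchConfig] = None,
    class_names: Optional[list] = None,
) -> Path:
    """Write weights (npz) plus a JSON sidecar making the checkpoint
    self-describing (spec, patch settings, class names)."""
    path = Path(path)
    np.savez(path, **{f"p{i:03d}": p for i, p in enumerate(model.params)})
    if path.suffix != ".npz":
        path = path.with_name(path.name + ".npz")
    sidecar = {
        "spec": model.spec.model_dump(),
        "patch": (patch or PatchConfig()).model_dump(),
        "class_names": class_names,
        "n_parameters": model.n_parameters(),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2) + "\n")
    return path


def load_checkpoint(path: str | Path) -> tuple[SmallConvNet, ClassifierSpec, PatchConfig, Optional[list]]:
    """Rebuild a model from weights + sidecar; logits match the saved model
    exactly on any input."""
    path = Path(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FileNotFoundError(f"checkpoint sidecar {sidecar_file} not found")
    meta = json.loads(sidecar_file.read_text())
    spec = ClassifierSpec(**meta["spec"])
    patch = PatchConfig(**meta["patch"])
    model = SmallConvNet(spec)
    with np.load(path) as data:
        arrays = [data[f"p{i:03d}"] for i in range(len(data.files))]
    try:
        model.set_params(arrays)
    except ValueError as exc:
        raise ValueError(f"checkpoint weights do not match sidecar spec: {exc}") from exc
    return model, spec, patch, meta.get("class_names")
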