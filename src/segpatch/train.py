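"""Training loop: Adam, step-decay learning rate, cross-entropy, online
augmentation. Fully deterministic given the config seed — sampling, weight
initialization, shuffling and augmentation draws all derive from it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .augment import augment
from .config import TrainingConfig
from .nn import Adam, SmallConvNet, cross_entropy
from .patches import PatchSet

__all__ = ["TrainingHistory", "train", "make_splits", "fit_loop"]


@dataclass
class TrainingHistory:
    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    val_accuracy: Optional[float] = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"epoch": np.arange(1, len(self.loss) + 1), "loss": self.loss,
             "accuracy": self.accuracy, "lr": self.lr}
        )


def fit_loop(
    model: SmallConvNet,
    X: np.ndarray,
    y_idx: np.ndarray,
    cfg: TrainingConfig,
) -> TrainingHistory:
    """Core mini-batch loop on 0-based class indices.

    The learning rate is multiplied by the decay factor every
    ``decay_interval`` epochs; augmentation draws happen per sample per epoch
    (online), not as a pre-expanded dataset.
    """
    rng = np.random.default_rng(cfg.seed)
    n = len(X)
    K = model.spec.n_classes
    weights = None
    if cfg.class_weighting == "inverse_frequency":
        counts = np.bincount(y_idx, minlength=K).astype(np.float64)
        weights = np.where(counts > 0, n / (K * np.maximum(counts, 1)), 0.0)
    opt = Adam(model.params, lr=cfg.learning_rate, betas=cfg.betas)
    every = cfg.decay_interval()
    history = TrainingHistory()
    for epoch in range(cfg.epochs):
        opt.lr = cfg.learning_rate * cfg.step_decay.factor ** (epoch // every)
        perm = rng.permutation(n)
        epoch_loss, correct = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            xb = X[idx]
            if cfg.augmentation:
                xb = np.stack([augment(x, cfg.augmentation, rng) for x in xb])
            yb = y_idx[idx]
            logits = model.forward(xb)
            loss, dlogits = cross_entropy(logits, yb, weights)
            if not math.isfinite(loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch + 1}")
            model.backward(dlogits)
            opt.step(model.grads)
            epoch_loss += loss * len(idx)
            correct += int((logits.argmax(axis=1) == yb).sum())
        history.loss.append(epoch_loss / n)
        history.accuracy.append(correct / n)
        history.lr.append(opt.lr)
    return history


def _map_labels(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Map class labels 1..K to 0-based indices, requiring every class to
    have at least one example."""
    labels = np.asarray(labels)
    if labels.min() < 1 or labels.max() > n_classes:
        raise ValueError(
            f"labels must lie in 1..{n_classes}, got range "
            f"[{labels.min()}, {labels.max()}]"
        )
    counts = np.bincount(labels, minlength=n_classes + 1)[1:]
    empty = [c + 1 for c in range(n_classes) if counts[c] == 0]
    if empty:
        raise ValueError(f"no training examples for class(es) {empty}")
    return labels - 1


def train(
    model: SmallConvNet,
    patchset: PatchSet,
    cfg: TrainingConfig,
) -> tuple[SmallConvNet, TrainingHistory]:
    """Train a model in place on a labeled PatchSet.

    With ``validation_fraction > 0`` a stratified split is held out and the
    final validation accuracy recorded in the history.
    """
    if patchset.labels is None:
        raise ValueError("patchset has no labels; training needs supervision")
    train_set, val_set = make_splits(patchset, cfg.validation_fraction, cfg.seed)
    y_idx = _map_labels(train_set.labels, model.spec.n_classes)
    history = fit_loop(model, train_set.patches, y_idx, cfg)
    if len(val_set):
        logits = model.forward(val_set.patches)
        pred = logits.argmax(axis=1) + 1
        history.val_accuracy = float((pred == val_set.labels).mean())
    return model, history


def make_splits(
    patchset: PatchSet, validation_fraction: float, seed: int
) -> tuple[PatchSet, PatchSet]:
    """Deterministic stratified train/validation split."""
    if not 0.0 <= validation_fraction <= 0.5:
        raise ValueError("validation_fraction must lie in [0, 0.5]")
    n = len(patchset)
    if validation_fraction == 0.0 or n == 0:
        empty = PatchSet(
            patches=np.zeros((0,) + patchset.patches.shape[1:], dtype=np.float32),
            object_ids=np.zeros(0, dtype=np.int64),
            image_id=patchset.image_id,
            patch_size=patchset.patch_size,
            labels=None if patchset.labels is None else np.zeros(0, dtype=np.int64),
        )
        return patchset, empty
    if patchset.labels is None:
        raise ValueError("stratified split needs labels")
    rng = np.random.default_rng(seed)
    val_idx: list[int] = []
    for cls in np.unique(patchset.labels):
        members = np.flatnonzero(patchset.labels == cls)
        n_val = math.ceil(len(members) * validation_fraction)
        if n_val >= len(members):
            raise ValueError(
                f"validation fraction {validation_fraction} empties class {cls} "
                f"({len(members)} examples)"
            )
        val_idx.extend(rng.choice(members, size=n_val, replace=False))
    val_mask = np.zeros(n, dtype=bool)
    val_mask[val_idx] = True

    def subset(mask: np.ndarray) -> PatchSet:
        return PatchSet(
            patches=patchset.patches[mask],
            object_ids=patchset.object_ids[mask],
            image_id=patchset.image_id,
            patch_size=patchset.patch_size,
            labels=None if patchset.labels is None else patchset.labels[mask],
        )

    return subset(~val_mask), subset(val_mask)
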