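"""Scikit-learn-style estimators wrapping the minimalist CNN and the
random-forest baseline.

`PatchCNNClassifier` follows the sklearn contract — parameters stored
verbatim in ``__init__``, fitted state in trailing-underscore attributes,
``fit``/``predict``/``predict_proba``/``score`` — so it composes with
sklearn model selection. Its input X is a patch tensor (n, C, y, x) or
(n, C, z, y, x) rather than a flat feature matrix.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier

from .config import AugmentationStep, ClassifierSpec, StepDecay, TrainingConfig
from .nn import SmallConvNet, softmax
from .train import TrainingHistory, fit_loop

__all__ = ["PatchCNNClassifier", "RegionForestBaseline"]


class PatchCNNClassifier(BaseEstimator, ClassifierMixin):
    """Minimalist depth-by-width CNN on per-object patches.

    Parameters
    ----------
    depth, width : int
        Number of conv blocks and filters per conv — the architecture's only
        degrees of freedom.
    epochs, batch_size, learning_rate, betas, decay_factor, decay_every :
        Adam optimization with step-decay learning rate.
    augmentation : list of dicts ``{"name", "params", "probability"}``
        Online per-sample augmentation pipeline.
    random_state : int
        Seeds initialization, shuffling and augmentation draws.
    """

    def __init__(
        self,
        depth: int = 3,
        width: int = 32,
        kernel_extent: int = 3,
        epochs: int = 600,
        batch_size: int = 16,
        learning_rate: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        decay_factor: float = 0.5,
        decay_every: Optional[int] = None,
        augmentation: Optional[Sequence[dict]] = None,
        class_weighting: str = "none",
        random_state: int = 0,
    ) -> None:
        self.depth = depth
        self.width = width
        self.kernel_extent = kernel_extent
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.betas = betas
        self.decay_factor = decay_factor
        self.decay_every = decay_every
        self.augmentation = augmentation
        self.class_weighting = class_weighting
        self.random_state = random_state

    def _training_config(self) -> TrainingConfig:
        pipeline = [
            step if isinstance(step, AugmentationStep) else AugmentationStep(**step)
            for step in (self.augmentation or [])
        ]
        return TrainingConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            betas=self.betas,
            step_decay=StepDecay(every_n_epochs=self.decay_every, factor=self.decay_factor),
            augmentation=pipeline,
            class_weighting=self.class_weighting,
            seed=self.random_state,
        )

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PatchCNNClassifier":
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.ndim not in (4, 5):
            raise ValueError(
                f"X must be (n, C, y, x) or (n, C, z, y, x); got shape {X.shape}"
            )
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training data must contain at least two classes")
        spec = ClassifierSpec(
            dim=X.ndim - 2,
            depth=self.depth,
            width=self.width,
            in_channels=X.shape[1],
            n_classes=len(self.classes_),
            kernel_extent=self.kernel_extent,
            patch_size=tuple(int(s) for s in X.shape[2:]),
        )
        self.spec_ = spec
        self.model_ = SmallConvNet(spec, seed=self.random_state)
        y_idx = np.searchsorted(self.classes_, y)
        self.history_: TrainingHistory = fit_loop(
            self.model_, X, y_idx, self._training_config()
        )
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        self._check_fitted()
        return self.model_.forward(np.asarray(X, dtype=np.float32))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return softmax(self.decision_function(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        logits = self.decision_function(X)
        # argmax takes the first maximum: ties break toward the smallest class
        return self.classes_[np.argmax(logits, axis=1)]

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("this PatchCNNClassifier instance is not fitted yet")


class RegionForestBaseline(BaseEstimator, ClassifierMixin):
    """Random forest on pre-defined radiometric/morphometric region features.

    A thin, seeded wrapper around sklearn's RandomForestClassifier taking the
    feature matrix produced by :func:`segpatch.features.region_feature_matrix`
    (majority vote over `n_estimators` randomized trees).
    """

    def __init__(self, n_estimators: int = 100, random_state: int = 0) -> None:
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RegionForestBaseline":
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators, random_state=self.random_state
        )
        self.forest_.fit(np.asarray(X), np.asarray(y))
        self.classes_ = self.forest_.classes_
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forest_.predict(np.asarray(X))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forest_.predict_proba(np.asarray(X))
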