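"""Pre-defined radiometric and morphometric region features for the
random-forest baseline: geometry of the segmentation mask (area/volume,
equivalent diameter, optionally location) and intensity statistics inside and
just outside the segmented zone (mean, variance, quantiles, exterior-ring
mean).
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .estimators import RegionForestBaseline
from .io import ImageVolume, LabelMask

__all__ = [
    "feature_names",
    "region_features",
    "region_feature_matrix",
    "rf_baseline_train_predict",
]

_QUANTILES = (10, 25, 50, 75, 90)


def feature_names(dim: int = 2, include_spatial: bool = False) -> list[str]:
    names = ["area", "equivalent_diameter", "interior_mean", "interior_variance"]
    names += [f"interior_q{q}" for q in _QUANTILES]
    names += ["exterior_ring_mean"]
    if include_spatial:
        names += [f"centroid_{ax}" for ax in ("zyx"[-dim:])]
    return names


def _equivalent_diameter(area: float, dim: int) -> float:
    if dim == 2:
        return 2.0 * math.sqrt(area / math.pi)
    return (6.0 * area / math.pi) ** (1.0 / 3.0)


def region_features(
    image: ImageVolume,
    mask: LabelMask,
    object_id: int,
    include_spatial: bool = False,
    ring_width: int = 3,
) -> np.ndarray:
    """Feature vector of one object; intensity is the channel mean."""
    obj = mask.labels == object_id
    if not obj.any():
        raise KeyError(f"object id {object_id} not present in mask")
    intensity = image.pixels.mean(axis=0)
    interior = intensity[obj]
    area = float(obj.sum())
    dim = mask.labels.ndim
    ring = ndimage.binary_dilation(obj, iterations=ring_width) & ~obj
    ring_mean = float(intensity[ring].mean()) if ring.any() else 0.0
    feats = [
        area,
        _equivalent_diameter(area, dim),
        float(interior.mean()),
        float(interior.var()),
        *(float(np.percentile(interior, q)) for q in _QUANTILES),
        ring_mean,
    ]
    if include_spatial:
        feats.extend(float(c.mean()) for c in np.nonzero(obj))
    return np.array(feats, dtype=np.float64)


def region_feature_matrix(
    image: ImageVolume,
    mask: LabelMask,
    object_ids: Optional[Sequence[int]] = None,
    include_spatial: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack region features for the given (default: all) object ids.

    Returns (features, object_ids) with rows in ascending object id order.
    """
    ids = (
        np.asarray(sorted(int(i) for i in object_ids))
        if object_ids is not None
        else mask.object_ids().astype(int)
    )
    F = np.stack([region_features(image, mask, oid, include_spatial) for oid in ids])
    return F, ids


def rf_baseline_train_predict(
    train_features: np.ndarray,
    train_labels: Sequence[int],
    test_features: np.ndarray,
    n_estimators: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Fit the seeded random-forest baseline and predict test classes."""
    labels = np.asarray(train_labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training data must contain at least two classes")
    rf = RegionForestBaseline(n_estimators=n_estimators, random_state=seed)
    rf.fit(train_features, labels)
    return rf.predict(test_features)
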