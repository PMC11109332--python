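"""Fixed-size, normalized patch tensors centered on each object.

Patches are cut around the floor of each connected component's centroid, with
zero padding where the window leaves the canvas, and optionally carry a binary
silhouette of the target object as an extra channel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy import ndimage

from .io import ImageVolume, LabelMask

__all__ = [
    "PatchSet",
    "object_centroids",
    "extract_patch",
    "normalize_patch",
    "build_patchset",
]


@dataclass
class PatchSet:
    """A stack of per-object patches plus optional class labels.

    ``patches`` has shape (n, C', y, x) or (n, C', z, y, x) where C' includes
    the mask channel when present; ``labels``, when given, are classes 1..9.
    """

    patches: np.ndarray
    object_ids: np.ndarray
    image_id: str
    patch_size: tuple[int, ...]
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches, dtype=np.float32)
        self.object_ids = np.asarray(self.object_ids)
        if self.patches.ndim != len(self.patch_size) + 2:
            raise ValueError(
                f"patches shape {self.patches.shape} inconsistent with "
                f"patch_size {self.patch_size}"
            )
        if tuple(self.patches.shape[2:]) != tuple(self.patch_size):
            raise ValueError(
                f"patch spatial shape {self.patches.shape[2:]} != {self.patch_size}"
            )
        if len(self.object_ids) != len(self.patches):
            raise ValueError("object_ids and patches lengths differ")
        if len(np.unique(self.object_ids)) != len(self.object_ids):
            raise ValueError("object_ids must be unique within an image")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if len(self.labels) != len(self.patches):
                raise ValueError("labels and patches lengths differ")
            if self.labels.size and (self.labels.min() < 1 or self.labels.max() > 9):
                raise ValueError("labels must lie in 1..9")

    def __len__(self) -> int:
        return len(self.patches)

    @property
    def n_channels(self) -> int:
        return self.patches.shape[1]


def object_centroids(mask: LabelMask) -> dict[int, tuple[int, ...]]:
    """Per-object centers: floor of the mean voxel coordinate of each object."""
    ids = mask.object_ids()
    if ids.size == 0:
        return {}
    coms = ndimage.center_of_mass(mask.labels > 0, mask.labels, ids)
    return {
        int(oid): tuple(int(np.floor(c)) for c in com)
        for oid, com in zip(ids, coms)
    }


def extract_patch(
    image: ImageVolume,
    mask: LabelMask,
    object_id: int,
    patch_size: Sequence[int],
    include_mask_channel: bool = True,
    center: Optional[tuple[int, ...]] = None,
) -> np.ndarray:
    """Cut a fixed-size crop centered on one object's centroid.

    Per axis the window spans ``center - s//2 .. center - s//2 + s - 1``;
    voxels outside the canvas are zero. When ``include_mask_channel`` is set,
    the last channel is the binary mask of `object_id` alone.
    """
    patch_size = tuple(int(s) for s in patch_size)
    if len(patch_size) != len(mask.spatial_shape):
        raise ValueError(
            f"patch_size {patch_size} has wrong rank for spatial shape "
            f"{mask.spatial_shape}"
        )
    if center is None:
        where = mask.labels == object_id
        if not where.any():
            raise KeyError(f"object id {object_id} not present in mask")
        center = tuple(int(np.floor(c.mean())) for c in np.nonzero(where))
    C = image.n_channels
    out = np.zeros((C + int(include_mask_channel),) + patch_size, dtype=np.float32)
    src, dst = [], []
    for c, s, extent in zip(center, patch_size, mask.spatial_shape):
        start = c - s // 2
        lo, hi = max(start, 0), min(start + s, extent)
        if lo >= hi:  # window entirely outside the canvas
            return out
        src.append(slice(lo, hi))
        dst.append(slice(lo - start, hi - start))
    src_t, dst_t = tuple(src), tuple(dst)
    out[(slice(0, C),) + dst_t] = image.pixels[(slice(None),) + src_t]
    if include_mask_channel:
        out[(C,) + dst_t] = (mask.labels[src_t] == object_id).astype(np.float32)
    return out


def normalize_patch(patch: np.ndarray, mode: str = "minmax") -> np.ndarray:
    """Rescale a patch to [0, 1] by its own min and max.

    ``minmax`` uses the global extrema, ``per_channel_minmax`` normalizes each
    channel independently; a constant patch (or channel) maps to all zeros.
    ``none`` is the identity.
    """
    patch = np.asarray(patch)
    if mode == "none":
        return patch
    patch = patch.astype(np.float32)
    if mode == "minmax":
        lo, hi = float(patch.min()), float(patch.max())
        if hi == lo:
            return np.zeros_like(patch)
        return (patch - lo) / (hi - lo)
    if mode == "per_channel_minmax":
        out = np.zeros_like(patch)
        for c in range(patch.shape[0]):
            lo, hi = float(patch[c].min()), float(patch[c].max())
            if hi > lo:
                out[c] = (patch[c] - lo) / (hi - lo)
        return out
    raise ValueError(f"unknown normalization mode {mode!r}")


def build_patchset(
    image: ImageVolume,
    mask: LabelMask,
    annotations_or_all: Union[str, Mapping[int, int], "AnnotationSet"],
    patch_size: Sequence[int],
    include_mask_channel: bool = True,
    normalization: str = "minmax",
) -> PatchSet:
    """One normalized patch per requested object, in ascending object id order.

    ``annotations_or_all`` is either the string ``"all"`` (every object in the
    mask, unlabeled), a mapping object_id -> class, or an AnnotationSet (its
    records for this image are used as labels).
    """
    from .annotations import AnnotationSet  # local import to avoid a cycle

    patch_size = tuple(int(s) for s in patch_size)
    centroids = object_centroids(mask)
    if isinstance(annotations_or_all, str):
        if annotations_or_all != "all":
            raise ValueError(f"expected 'all' or annotations, got {annotations_or_all!r}")
        wanted: dict[int, Optional[int]] = {oid: None for oid in centroids}
    elif isinstance(annotations_or_all, AnnotationSet):
        wanted = {
            oid: cls
            for oid, cls in annotations_or_all.for_image(image.image_id).items()
        }
    else:
        wanted = {int(k): int(v) for k, v in annotations_or_all.items()}
    missing = sorted(set(wanted) - set(centroids))
    if missing:
        raise ValueError(f"annotations reference absent object ids: {missing[:20]}")
    ids = sorted(wanted)
    labeled = ids and all(wanted[i] is not None for i in ids)
    n_ch = image.n_channels + int(include_mask_channel)
    patches = np.zeros((len(ids), n_ch) + patch_size, dtype=np.float32)
    for i, oid in enumerate(ids):
        p = extract_patch(
            image, mask, oid, patch_size, include_mask_channel, center=centroids[oid]
        )
        patches[i] = normalize_patch(p, normalization)
    return PatchSet(
        patches=patches,
        object_ids=np.array(ids, dtype=np.int64),
        image_id=image.image_id,
        patch_size=patch_size,
        labels=np.array([wanted[i] for i in ids], dtype=np.int64) if labeled else None,
    )
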