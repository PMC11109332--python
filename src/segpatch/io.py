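"""Readers and writers for images, label masks, class masks and run manifests.

TIFF is the interchange format: multi-page files hold the Z axis, extra
samples hold channels. In memory the convention is channel-first with spatial
axes ordered (Z,)Y,X; label masks carry no channel axis.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile

from .config import ExperimentConfig

__all__ = [
    "ImageVolume",
    "LabelMask",
    "read_pair",
    "write_image",
    "write_class_mask",
    "save_run_manifest",
    "pair_stems",
]


@dataclass
class ImageVolume:
    """Intensity data with axes (C, Y, X) in 2D or (C, Z, Y, X) in 3D."""

    pixels: np.ndarray
    image_id: str = "image"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (3, 4):
            raise ValueError(
                f"ImageVolume expects (C,Y,X) or (C,Z,Y,X); got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or any(s < 1 for s in self.pixels.shape[1:]):
            raise ValueError(f"degenerate image shape {self.pixels.shape}")
        if np.issubdtype(self.pixels.dtype, np.floating) and not np.all(
            np.isfinite(self.pixels)
        ):
            raise ValueError("image contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.pixels.shape[1:]

    @property
    def dim(self) -> int:
        return self.pixels.ndim - 1


@dataclass
class LabelMask:
    """Integer instance mask; 0 is background, positive ids are objects."""

    labels: np.ndarray
    image_id: str = "image"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError(f"label mask must be integer-typed, got {self.labels.dtype}")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("label mask contains negative values")

    def object_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.labels.shape


def _normalize_channel_axis(pixels: np.ndarray, spatial: tuple[int, ...]) -> np.ndarray:
    """Move the channel axis to the front, inferring it from the mask shape."""
    if pixels.shape == spatial:
        return pixels[np.newaxis]
    if pixels.ndim == len(spatial) + 1:
        if pixels.shape[1:] == spatial:  # already channel-first
            return pixels
        if pixels.shape[:-1] == spatial:  # channel-last (e.g. RGB TIFF)
            return np.moveaxis(pixels, -1, 0)
        for ax in range(pixels.ndim):
            if pixels.shape[:ax] + pixels.shape[ax + 1 :] == spatial:
                return np.moveaxis(pixels, ax, 0)
    raise ValueError(
        f"image shape {pixels.shape} does not match mask spatial shape {spatial} "
        "under any channel-axis placement"
    )


def read_pair(image_path: str | Path, mask_path: str | Path) -> tuple[ImageVolume, LabelMask]:
    """Read an intensity image and its label mask, normalizing axes.

    The mask defines the spatial shape; the image's channel axis (if any) is
    inferred and moved to the front. A single-channel image gets C=1.
    """
    image_path, mask_path = Path(image_path), Path(mask_path)
    pixels = np.asarray(tifffile.imread(image_path))
    labels = np.asarray(tifffile.imread(mask_path))
    if not np.issubdtype(labels.dtype, np.integer):
        if np.allclose(labels, np.round(labels)):
            labels = np.round(labels).astype(np.int64)
        else:
            raise ValueError(f"mask {mask_path.name} is not integer-valued")
    spatial = labels.shape
    try:
        pixels = _normalize_channel_axis(pixels, spatial)
    except ValueError:
        raise ValueError(
            f"image {image_path.name} shape {pixels.shape} is incompatible with "
            f"mask {mask_path.name} shape {spatial}"
        ) from None
    return (
        ImageVolume(pixels, image_id=image_path.stem),
        LabelMask(labels, image_id=mask_path.stem),
    )


def write_image(pixels: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(pixels))
    return path


def write_class_mask(class_mask: np.ndarray, path: str | Path) -> Path:
    """Write a class mask (values 0..9) as a TIFF; 3D masks become multi-page."""
    class_mask = np.asarray(class_mask)
    if class_mask.size and (class_mask.min() < 0 or class_mask.max() > 9):
        raise ValueError(
            f"class mask values must lie in 0..9, got range "
            f"[{class_mask.min()}, {class_mask.max()}]"
        )
    path = Path(path)
    tifffile.imwrite(path, class_mask.astype(np.uint8))
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def save_run_manifest(
    config: ExperimentConfig,
    outputs: Mapping[str, str | Path],
    path: str | Path,
) -> Path:
    """Record a completed run: full config, seed and output file hashes.

    Re-running with the manifest's config and seed reproduces the outputs
    bit-exactly for every deterministic stage.
    """
    manifest = {
        "config": config.model_dump(),
        "seed": config.seed,
        "outputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in sorted(outputs.items())
        },
    }
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path


def pair_stems(images_dir: str | Path, masks_dir: str | Path) -> list[tuple[str, Path, Path]]:
    """Pair image and mask files by identical filename stem.

    The association must be a bijection; unmatched stems on either side abort
    the run with a listing.
    """
    images_dir, masks_dir = Path(images_dir), Path(masks_dir)
    exts = {".tif", ".tiff"}
    images = {p.stem: p for p in sorted(images_dir.iterdir()) if p.suffix.lower() in exts}
    masks = {p.stem: p for p in sorted(masks_dir.iterdir()) if p.suffix.lower() in exts}
    only_images = sorted(set(images) - set(masks))
    only_masks = sorted(set(masks) - set(images))
    if only_images or only_masks:
        raise ValueError(
            "image/mask folders do not pair up; "
            f"images without mask: {only_images}; masks without image: {only_masks}"
        )
    return [(stem, images[stem], masks[stem]) for stem in sorted(images)]
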