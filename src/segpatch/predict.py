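"""Classify every connected component of one image or a folder of images.

Predictions are pure functions of the checkpoint and inputs: no test-time
augmentation, argmax ties broken toward the smallest class index, and patches
normalized exactly as at training time (settings read from the checkpoint
sidecar).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import ClassifierSpec, PatchConfig
from .io import ImageVolume, LabelMask, pair_stems, read_pair, write_class_mask
from .nn import SmallConvNet, load_checkpoint, softmax
from .patches import build_patchset

__all__ = [
    "predict_objects",
    "render_class_mask",
    "predict_folder",
    "count_per_class",
    "save_prediction_table",
    "load_prediction_table",
]

TABLE_COLUMNS = ["image_id", "object_id", "class", "confidence"]


def predict_objects(
    model: SmallConvNet,
    image: ImageVolume,
    mask: LabelMask,
    patch: Optional[PatchConfig] = None,
    classes: Optional[Sequence[int]] = None,
    batch_size: int = 64,
) -> pd.DataFrame:
    """One row (image_id, object_id, class, confidence) per mask object.

    `classes` maps logit columns to class labels (defaults to 1..K);
    confidence is the max softmax probability.
    """
    patch = patch or PatchConfig()
    spec = model.spec
    patch_size = patch.resolved_size(spec.dim)
    expected_c = image.n_channels + int(patch.include_mask_channel)
    if expected_c != spec.in_channels:
        raise ValueError(
            f"channel mismatch: checkpoint expects {spec.in_channels} input "
            f"channels but image + patch settings provide {expected_c}"
        )
    if patch.intensity_scale != 1.0:
        image = ImageVolume(
            image.pixels / patch.intensity_scale, image_id=image.image_id
        )
    pset = build_patchset(
        image, mask, "all", patch_size, patch.include_mask_channel, patch.normalization
    )
    class_values = np.asarray(
        classes if classes is not None else np.arange(1, spec.n_classes + 1), dtype=int
    )
    rows = []
    for start in range(0, len(pset), batch_size):
        xb = pset.patches[start : start + batch_size]
        probs = softmax(model.forward(xb))
        pred_idx = probs.argmax(axis=1)  # first max: smallest class on ties
        for oid, pi, p in zip(pset.object_ids[start : start + batch_size], pred_idx, probs):
            rows.append((image.image_id, int(oid), int(class_values[pi]), float(p[pi])))
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def render_class_mask(mask: LabelMask, table: pd.DataFrame) -> np.ndarray:
    """Relabel each object's voxels by its predicted class (background 0)."""
    ids = mask.object_ids()
    table_ids = set(int(i) for i in table["object_id"])
    missing = sorted(set(int(i) for i in ids) - table_ids)
    if missing:
        raise ValueError(f"prediction table missing object ids: {missing[:20]}")
    lut = np.zeros(int(mask.labels.max()) + 1, dtype=np.uint8)
    for _, row in table.iterrows():
        oid = int(row["object_id"])
        if oid <= len(lut) - 1:
            lut[oid] = int(row["class"])
    return lut[mask.labels]


def count_per_class(table: pd.DataFrame) -> dict[int, int]:
    """Number of objects predicted in each class; counts sum to n objects."""
    if len(table) == 0:
        return {}
    counts = table["class"].value_counts().sort_index()
    return {int(c): int(n) for c, n in counts.items()}


def save_prediction_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def load_prediction_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def predict_folder(
    checkpoint: str | Path,
    images_dir: str | Path,
    masks_dir: str | Path,
    out_dir: str | Path,
) -> pd.DataFrame:
    """Run prediction on every stem-paired image/mask in two folders.

    Writes one class mask and one prediction table per pair plus a combined
    per-class counts CSV; returns the summary frame (one row per image and
    class).
    """
    model, spec, patch, class_names = load_checkpoint(checkpoint)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs = pair_stems(images_dir, masks_dir)
    summary_rows = []
    for stem, image_path, mask_path in pairs:
        image, mask = read_pair(image_path, mask_path)
        table = predict_objects(model, image, mask, patch, classes=class_names)
        save_prediction_table(table, out_dir / f"{stem}_predictions.csv")
        write_class_mask(render_class_mask(mask, table), out_dir / f"{stem}_classes.tif")
        for cls, n in count_per_class(table).items():
            summary_rows.append((stem, cls, n))
    summary = pd.DataFrame(summary_rows, columns=["image_id", "class", "count"])
    summary.to_csv(out_dir / "class_counts.csv", index=False)
    return summary
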