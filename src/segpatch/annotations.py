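"""Sparse per-object class labels and the human-in-the-loop correction cycle.

An annotation maps (image_id, object_id) to a class in 1..9 — nine being the
maximum number of classes — with at most one record per object. Records carry
a provenance tag (manual, corrected, confirmed) so a retraining set documents
where each label came from.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .io import LabelMask

__all__ = [
    "AnnotationSet",
    "sample_objects",
    "sample_stratified",
    "merge_corrections",
    "load_annotations",
    "save_annotations",
]

MAX_CLASSES = 9
_PROVENANCES = ("manual", "corrected", "confirmed")


def _check_class(cls: int) -> int:
    cls = int(cls)
    if not 1 <= cls <= MAX_CLASSES:
        raise ValueError(f"class must lie in 1..{MAX_CLASSES}, got {cls}")
    return cls


@dataclass
class AnnotationSet:
    """Keyed set of (image_id, object_id) -> (class, provenance) records."""

    records: dict[tuple[str, int], tuple[int, str]] = field(default_factory=dict)

    def assign(
        self, image_id: str, object_id: int, cls: int, provenance: str = "manual"
    ) -> "AnnotationSet":
        """Insert or overwrite one record (latest wins)."""
        if provenance not in _PROVENANCES:
            raise ValueError(f"provenance must be one of {_PROVENANCES}")
        self.records[(str(image_id), int(object_id))] = (_check_class(cls), provenance)
        return self

    def for_image(self, image_id: str) -> dict[int, int]:
        return {
            oid: cls
            for (iid, oid), (cls, _) in self.records.items()
            if iid == image_id
        }

    def classes(self) -> list[int]:
        return sorted({cls for cls, _ in self.records.values()})

    def copy(self) -> "AnnotationSet":
        return AnnotationSet(dict(self.records))

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return (key[0], int(key[1])) in self.records

    @classmethod
    def from_truth(
        cls, truth: dict[int, int], image_id: str, object_ids: Optional[Iterable[int]] = None
    ) -> "AnnotationSet":
        """Build annotations from a ground-truth mapping, optionally
        restricted to a sampled subset of objects (the headless stand-in for
        interactive labeling)."""
        out = cls()
        ids = sorted(truth) if object_ids is None else sorted(int(i) for i in object_ids)
        for oid in ids:
            out.assign(image_id, oid, truth[oid])
        return out


def sample_objects(mask: LabelMask, n: int, seed: int) -> list[int]:
    """Uniform sample of `n` distinct object ids, deterministic given seed."""
    ids = mask.object_ids()
    if n > ids.size:
        raise ValueError(f"requested {n} objects but mask only has {ids.size}")
    rng = np.random.default_rng(seed)
    return [int(i) for i in rng.choice(ids, size=n, replace=False)]


def sample_stratified(truth: dict[int, int], n_per_class: int, seed: int) -> list[int]:
    """Sample `n_per_class` object ids from each class of a truth mapping."""
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    for cls in sorted(set(truth.values())):
        ids = np.array(sorted(oid for oid, c in truth.items() if c == cls))
        if n_per_class > ids.size:
            raise ValueError(
                f"class {cls} has only {ids.size} objects, requested {n_per_class}"
            )
        chosen.extend(int(i) for i in rng.choice(ids, size=n_per_class, replace=False))
    return sorted(chosen)


def merge_corrections(
    annotations: AnnotationSet,
    predictions: pd.DataFrame,
    corrections: AnnotationSet,
    confirmed: Optional[Iterable[tuple[str, int]]] = None,
) -> AnnotationSet:
    """Fold user corrections of a prediction round back into the training set.

    The result is the manual annotations, overridden by the corrections
    (provenance ``corrected``), plus any explicitly confirmed predictions
    (provenance ``confirmed``). Unreviewed predictions are never promoted to
    training labels. Idempotent for a fixed corrections set.
    """
    predicted = {
        (str(r.image_id), int(r.object_id)): int(r["class"])
        for _, r in predictions.iterrows()
    }
    out = annotations.copy()
    for (iid, oid), (cls, _) in sorted(corrections.records.items()):
        if (iid, oid) not in predicted:
            raise ValueError(
                f"correction for ({iid!r}, {oid}) does not match any prediction"
            )
        out.assign(iid, oid, cls, provenance="corrected")
    for iid, oid in sorted(confirmed or []):
        key = (str(iid), int(oid))
        if key not in predicted:
            raise ValueError(f"confirmed object {key} does not match any prediction")
        if key not in out.records:
            out.assign(key[0], key[1], predicted[key], provenance="confirmed")
    return out


def save_annotations(annotations: AnnotationSet, path: str | Path) -> Path:
    """Write the JSON array of {image_id, object_id, class, provenance}."""
    records = [
        {"image_id": iid, "object_id": oid, "class": cls, "provenance": prov}
        for (iid, oid), (cls, prov) in sorted(annotations.records.items())
    ]
    path = Path(path)
    path.write_text(json.dumps(records, indent=1) + "\n")
    return path


def load_annotations(path: str | Path) -> AnnotationSet:
    with open(path) as fh:
        records = json.load(fh)
    out = AnnotationSet()
    for rec in records:
        if rec.get("class") is None:
            raise ValueError(
                f"annotation for object {rec.get('object_id')} has no class; "
                "fill in the skeleton file before loading"
            )
        out.assign(
            rec["image_id"],
            rec["object_id"],
            rec["class"],
            provenance=rec.get("provenance", "manual"),
        )
    return out
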