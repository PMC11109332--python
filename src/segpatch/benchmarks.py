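"""Desk-scale benchmark protocols on the synthetic scenes.

These functions wire the full annotate -> train -> predict cycle on the
synthetic generators at sizes that run in seconds to minutes on one CPU, and
are used both by the test suite and by the reproduction script. The scene
parameters are the study conditions (two gray-level classes separated by far
more than the pixel noise; matched-moment textures at 0/90 degrees; a
spatially confounded scene); the training lengths are this package's
desk-scale choices, documented in the methods note.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .annotations import sample_objects, sample_stratified
from .estimators import PatchCNNClassifier, RegionForestBaseline
from .features import region_feature_matrix
from .io import ImageVolume
from .patches import PatchSet, build_patchset
from .synth import (
    SyntheticScene,
    gen_cells,
    gen_granular_textures,
    gen_oriented_textures,
    rotate_scene_90,
)

__all__ = [
    "labeled_patches",
    "run_cells_benchmark",
    "run_textures_benchmark",
    "run_confounding_benchmark",
]

#: tile-sized patches for the texture task (the tile is the object)
TEXTURE_PATCH = (32, 32)
#: cell patches: ~1.5x the largest disk diameter, enough context without
#: pulling many neighbouring cells into the crop
CELL_PATCH = (24, 24)
#: gray levels live on the 8-bit scale; a fixed global constant maps them to
#: [0, 1] without erasing between-patch intensity differences the way
#: per-patch min-max would (the intensity IS the class signal here)
GRAY_SCALE = 255.0

ROTATION_AUGMENTATION = [
    {"name": "hflip", "probability": 0.5},
    {"name": "vflip", "probability": 0.5},
    {"name": "rot90", "probability": 0.5},
    {"name": "rotate", "params": {"angle_range": (-180.0, 180.0)}, "probability": 0.5},
]


def labeled_patches(
    scene: SyntheticScene,
    object_ids: Sequence[int],
    patch_size: tuple[int, ...] = TEXTURE_PATCH,
    normalization: str = "minmax",
    intensity_scale: float = 1.0,
) -> PatchSet:
    """Patches for the given objects with their ground-truth classes attached.

    ``intensity_scale`` divides the intensity channels by a global constant
    before patch extraction (the mask channel is untouched), for tasks where
    per-patch normalization would erase the class signal.
    """
    image = scene.image
    if intensity_scale != 1.0:
        image = ImageVolume(image.pixels / intensity_scale, image_id=image.image_id)
    wanted = {int(oid): scene.truth[int(oid)] for oid in object_ids}
    return build_patchset(
        image, scene.mask, wanted, patch_size, normalization=normalization
    )


def _split_ids(scene: SyntheticScene, train_ids: Sequence[int]) -> list[int]:
    return sorted(set(scene.truth) - set(int(i) for i in train_ids))


def run_cells_benchmark(
    seed: int,
    n_cells: int = 100,
    n_per_class: int = 5,
    epochs: int = 300,
) -> dict:
    """Gray-level cell classification from 10 labels (5 per class).

    The class means differ by 100 gray levels against pixel noise of sd 5
    (a 20x gap), so the task is solvable exactly; the question is whether the
    pipeline recovers it from 10 annotations.
    """
    scene = gen_cells(n_cells=n_cells, seed=seed)
    train_ids = sample_stratified(scene.truth, n_per_class, seed=seed)
    eval_ids = _split_ids(scene, train_ids)
    kwargs = dict(patch_size=CELL_PATCH, normalization="none", intensity_scale=GRAY_SCALE)
    train_set = labeled_patches(scene, train_ids, **kwargs)
    eval_set = labeled_patches(scene, eval_ids, **kwargs)
    clf = PatchCNNClassifier(epochs=epochs, random_state=seed)
    clf.fit(train_set.patches, train_set.labels)
    accuracy = float((clf.predict(eval_set.patches) == eval_set.labels).mean())
    return {
        "accuracy": accuracy,
        "n_train": len(train_set),
        "n_eval": len(eval_set),
        "seed": seed,
    }


def run_textures_benchmark(
    seed: int,
    n_tiles: int = 150,
    n_labels: int = 45,
    epochs: int = 300,
    with_rf_baseline: bool = False,
    rf_include_spatial: bool = False,
) -> dict:
    """Oriented-texture classification from 45 labeled tiles, no augmentation.

    The tiles share mean and variance exactly (matched by construction), so
    only the orientation of the anisotropic texture separates the classes —
    a feature absent from the random forest's pre-defined set.
    """
    scene = gen_oriented_textures(n_tiles=n_tiles, seed=seed)
    train_ids = sample_objects(scene.mask, n_labels, seed=seed)
    if len({scene.truth[i] for i in train_ids}) < 2:
        raise RuntimeError("label sample covers a single class; use another seed")
    eval_ids = _split_ids(scene, train_ids)
    train_set = labeled_patches(scene, train_ids)
    eval_set = labeled_patches(scene, eval_ids)
    clf = PatchCNNClassifier(epochs=epochs, random_state=seed)
    clf.fit(train_set.patches, train_set.labels)
    out = {
        "cnn_accuracy": float((clf.predict(eval_set.patches) == eval_set.labels).mean()),
        "n_train": len(train_set),
        "n_eval": len(eval_set),
        "seed": seed,
    }
    if with_rf_baseline:
        F_train, _ = region_feature_matrix(
            scene.image, scene.mask, train_ids, include_spatial=rf_include_spatial
        )
        F_eval, _ = region_feature_matrix(
            scene.image, scene.mask, eval_ids, include_spatial=rf_include_spatial
        )
        rf = RegionForestBaseline(random_state=seed)
        rf.fit(F_train, np.array([scene.truth[i] for i in sorted(set(map(int, train_ids)))]))
        rf_pred = rf.predict(F_eval)
        truth_eval = np.array([scene.truth[i] for i in eval_ids])
        out["rf_accuracy"] = float((rf_pred == truth_eval).mean())
    return out


def run_confounding_benchmark(
    seed: int,
    n_tiles: int = 150,
    n_labels: int = 40,
    epochs: int = 300,
) -> dict:
    """The confounding-variable demonstration on a spatially segregated scene.

    The scene is a granularity-texture grid whose left half is class 1 and
    right half class 2, with marginal pixel statistics matched across
    classes. The random forest's pre-defined features carry essentially no
    class information, so given location features it learns the spatial
    shortcut: excellent on the training scene's layout, collapsing on a
    90-degree-rotated copy. The CNN, trained with rotation augmentation,
    learns the rotation-invariant granularity feature and keeps its accuracy.
    """
    scene = gen_granular_textures(n_tiles=n_tiles, spatial_split=True, seed=seed)
    rotated = rotate_scene_90(scene)
    train_ids = sample_objects(scene.mask, n_labels, seed=seed)
    if len({scene.truth[i] for i in train_ids}) < 2:
        raise RuntimeError("label sample covers a single class; use another seed")
    eval_ids = _split_ids(scene, train_ids)
    truth_eval = np.array([scene.truth[i] for i in eval_ids])
    truth_train = np.array([scene.truth[i] for i in sorted(set(map(int, train_ids)))])

    # random forest with spatial (centroid) features
    F_train, _ = region_feature_matrix(scene.image, scene.mask, train_ids, include_spatial=True)
    F_eval, _ = region_feature_matrix(scene.image, scene.mask, eval_ids, include_spatial=True)
    F_eval_rot, _ = region_feature_matrix(
        rotated.image, rotated.mask, eval_ids, include_spatial=True
    )
    rf = RegionForestBaseline(random_state=seed)
    rf.fit(F_train, truth_train)
    rf_unrot = float((rf.predict(F_eval) == truth_eval).mean())
    rf_rot = float((rf.predict(F_eval_rot) == truth_eval).mean())

    # CNN with rotation augmentation (patches carry no location information)
    train_set = labeled_patches(scene, train_ids)
    eval_set = labeled_patches(scene, eval_ids)
    eval_set_rot = labeled_patches(rotated, eval_ids)
    clf = PatchCNNClassifier(
        epochs=epochs, augmentation=ROTATION_AUGMENTATION, random_state=seed
    )
    clf.fit(train_set.patches, train_set.labels)
    cnn_unrot = float((clf.predict(eval_set.patches) == eval_set.labels).mean())
    cnn_rot = float((clf.predict(eval_set_rot.patches) == eval_set_rot.labels).mean())
    return {
        "rf_unrotated": rf_unrot,
        "rf_rotated": rf_rot,
        "cnn_unrotated": cnn_unrot,
        "cnn_rotated": cnn_rot,
        "n_eval": len(eval_ids),
        "seed": seed,
    }
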