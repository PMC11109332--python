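"""Seeded synthetic scenes for benchmarking per-object classifiers.

Three generators cover the benchmark conditions: disks differing in average
gray level (`gen_cells`), tiled anisotropic textures with matched first and
second moments but different orientations (`gen_oriented_textures`), and 3D
ellipsoidal blobs (`gen_blobs3d`) exercising the volumetric code path. All
generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
from scipy import ndimage

from .io import ImageVolume, LabelMask, write_image

__all__ = [
    "SyntheticScene",
    "gen_cells",
    "gen_oriented_textures",
    "gen_granular_textures",
    "gen_blobs3d",
    "write_scene",
    "rotate_scene_90",
]


@dataclass
class SyntheticScene:
    """An image + mask pair with ground-truth class per object."""

    image: ImageVolume
    mask: LabelMask
    truth: dict[int, int]
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = set(int(i) for i in self.mask.object_ids())
        missing = ids - set(self.truth)
        if missing:
            raise ValueError(f"mask objects missing from truth: {sorted(missing)[:10]}")


def _place_disks(
    rng: np.random.Generator,
    n: int,
    radius_range: tuple[int, int],
    canvas: tuple[int, ...],
    max_trials_per_cell: int = 400,
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample non-overlapping disk/sphere centers and radii."""
    centers: list[np.ndarray] = []
    radii: list[int] = []
    trials = 0
    cap = max_trials_per_cell * n
    while len(centers) < n and trials < cap:
        trials += 1
        r = int(rng.integers(radius_range[0], radius_range[1] + 1))
        c = np.array([rng.integers(r, s - r) for s in canvas])
        ok = True
        for c2, r2 in zip(centers, radii):
            if np.sum((c - c2) ** 2) <= (r + r2 + 1) ** 2:
                ok = False
                break
        if ok:
            centers.append(c)
            radii.append(r)
    if len(centers) < n:
        raise RuntimeError(
            f"could not place {n} non-overlapping objects on canvas {canvas}; "
            f"achieved {len(centers)}"
        )
    return np.array(centers), np.array(radii)


def gen_cells(
    n_cells: int = 100,
    mean_a: float = 80.0,
    mean_b: float = 180.0,
    noise_sd: float = 5.0,
    radius_range: tuple[int, int] = (6, 8),
    canvas: tuple[int, int] = (256, 256),
    seed: int = 0,
    cell_sd: float = 0.0,
    spatial_split: bool = False,
) -> SyntheticScene:
    """Disks on a dark background whose two classes differ in mean gray level.

    The radius range is kept narrow by default so that average gray level is
    the sole class-discriminating factor and object scale stays a minor
    nuisance variable.

    Class-A interiors have mean `mean_a`, class-B `mean_b`, with i.i.d.
    Gaussian pixel noise of `noise_sd`. `cell_sd` additionally jitters each
    cell's own mean (between-cell variability), which weakens the radiometric
    signal relative to the class gap. With `spatial_split` the class is
    determined by image half (left = class 1, right = class 2) instead of at
    random — a deliberate spatial confound for robustness studies.
    """
    rng = np.random.default_rng(seed)
    centers, radii = _place_disks(rng, n_cells, radius_range, canvas)
    if spatial_split:
        classes = np.where(centers[:, 1] < canvas[1] // 2, 1, 2)
        if len(set(classes.tolist())) < 2:
            raise RuntimeError("spatial split produced a single class; enlarge canvas")
    else:
        classes = np.ones(n_cells, dtype=int)
        classes[n_cells // 2 :] = 2
        classes = classes[rng.permutation(n_cells)]
    image = np.zeros(canvas, dtype=np.float32)
    labels = np.zeros(canvas, dtype=np.int32)
    yy, xx = np.mgrid[0 : canvas[0], 0 : canvas[1]]
    truth: dict[int, int] = {}
    for i, (c, r, cls) in enumerate(zip(centers, radii, classes), start=1):
        interior = (yy - c[0]) ** 2 + (xx - c[1]) ** 2 <= r**2
        mean = mean_a if cls == 1 else mean_b
        if cell_sd > 0:
            mean = mean + rng.normal(0.0, cell_sd)
        values = np.full(int(interior.sum()), mean, dtype=np.float64)
        if noise_sd > 0:
            values = values + rng.normal(0.0, noise_sd, size=values.shape)
        image[interior] = values.astype(np.float32)
        labels[interior] = i
        truth[i] = int(cls)
    return SyntheticScene(
        image=ImageVolume(image[np.newaxis], image_id=f"cells_seed{seed}"),
        mask=LabelMask(labels, image_id=f"cells_seed{seed}"),
        truth=truth,
        params=dict(
            kind="cells", n_cells=n_cells, mean_a=mean_a, mean_b=mean_b,
            noise_sd=noise_sd, radius_range=radius_range, canvas=canvas,
            seed=seed, cell_sd=cell_sd, spatial_split=spatial_split,
        ),
    )


def _tile_classes(
    rng: np.random.Generator, n_tiles: int, cols: int, spatial_split: bool
) -> np.ndarray:
    """Balanced random classes, or a left/right half split of the tile grid."""
    if spatial_split:
        grid_cols = np.arange(n_tiles) % cols
        classes = np.where(grid_cols < cols / 2, 1, 2)
        if len(set(classes.tolist())) < 2:
            raise RuntimeError("spatial split produced a single class")
        return classes
    classes = np.ones(n_tiles, dtype=int)
    classes[n_tiles // 2 :] = 2
    return classes[rng.permutation(n_tiles)]


def _oriented_tile(
    rng: np.random.Generator,
    tile: tuple[int, int],
    theta_deg: float,
    sigma: tuple[float, float],
    target_mean: float,
    target_sd: float,
) -> np.ndarray:
    """One anisotropic texture tile: white noise smoothed by an elongated
    kernel at `theta_deg`, then affinely standardized to the target moments."""
    th, tw = tile
    margin = int(math.ceil(3 * max(sigma)))
    side = int(math.ceil(math.hypot(th, tw))) + 2 * margin
    noise = rng.standard_normal((side, side))
    # sigma = (short, long): smoothing strongly along x makes 0-degree
    # (horizontal) streaks; rotation then sets the class angle.
    smooth = ndimage.gaussian_filter(noise, sigma=(sigma[0], sigma[1]))
    if theta_deg % 360 != 0:
        smooth = ndimage.rotate(smooth, angle=theta_deg, reshape=False, order=1)
    y0 = (side - th) // 2
    x0 = (side - tw) // 2
    t = smooth[y0 : y0 + th, x0 : x0 + tw]
    sd = t.std()
    if sd == 0:  # pragma: no cover - smoothed noise is never constant
        raise RuntimeError("degenerate texture tile")
    return ((t - t.mean()) / sd * target_sd + target_mean).astype(np.float32)


def gen_oriented_textures(
    theta_a: float = 0.0,
    theta_b: float = 90.0,
    n_tiles: int = 150,
    tile: tuple[int, int] = (32, 32),
    seed: int = 0,
    target_mean: float = 128.0,
    target_sd: float = 30.0,
    sigma: tuple[float, float] = (0.8, 5.0),
    spatial_split: bool = False,
) -> SyntheticScene:
    """A grid of texture tiles; the two classes share mean and variance but
    differ in orientation.

    Each tile is standardized to exactly the common target mean and standard
    deviation, so no first- or second-moment feature separates the classes;
    only orientation does. With `spatial_split` the left half of the grid is
    class 1 and the right half class 2 instead of a random assignment.
    """
    if (theta_a - theta_b) % 180 == 0:
        raise ValueError(
            f"theta_a={theta_a} and theta_b={theta_b} coincide modulo 180 degrees"
        )
    th, tw = tile
    if th < 2 or tw < 2:
        raise ValueError(f"degenerate tile shape {tile}")
    rng = np.random.default_rng(seed)
    cols = int(math.ceil(math.sqrt(n_tiles)))
    rows = int(math.ceil(n_tiles / cols))
    canvas = (rows * th, cols * tw)
    classes = _tile_classes(rng, n_tiles, cols, spatial_split)
    image = np.zeros(canvas, dtype=np.float32)
    labels = np.zeros(canvas, dtype=np.int32)
    truth: dict[int, int] = {}
    for idx in range(n_tiles):
        r, c = divmod(idx, cols)
        theta = theta_a if classes[idx] == 1 else theta_b
        patch = _oriented_tile(rng, tile, theta, sigma, target_mean, target_sd)
        image[r * th : (r + 1) * th, c * tw : (c + 1) * tw] = patch
        labels[r * th : (r + 1) * th, c * tw : (c + 1) * tw] = idx + 1
        truth[idx + 1] = int(classes[idx])
    return SyntheticScene(
        image=ImageVolume(image[np.newaxis], image_id=f"textures_seed{seed}"),
        mask=LabelMask(labels, image_id=f"textures_seed{seed}"),
        truth=truth,
        params=dict(
            kind="textures", theta_a=theta_a, theta_b=theta_b, n_tiles=n_tiles,
            tile=tile, seed=seed, target_mean=target_mean, target_sd=target_sd,
            sigma=sigma,
        ),
    )


def gen_granular_textures(
    sigma_a: float = 0.8,
    sigma_b: float = 2.5,
    n_tiles: int = 150,
    tile: tuple[int, int] = (32, 32),
    seed: int = 0,
    target_mean: float = 128.0,
    target_sd: float = 30.0,
    spatial_split: bool = False,
) -> SyntheticScene:
    """Isotropic texture tiles whose classes differ only in granularity.

    Both classes are white noise smoothed by an isotropic Gaussian —
    correlation length `sigma_a` (fine) for class 1 and `sigma_b` (coarse)
    for class 2 — and standardized per tile to the common target moments.
    Marginal pixel statistics (mean, variance, quantiles) are matched across
    classes; only the spatial autocorrelation differs, a feature that is
    rotation invariant and absent from pixel-wise pre-defined feature sets.
    """
    if sigma_a == sigma_b:
        raise ValueError("sigma_a and sigma_b must differ")
    th, tw = tile
    if th < 2 or tw < 2:
        raise ValueError(f"degenerate tile shape {tile}")
    rng = np.random.default_rng(seed)
    cols = int(math.ceil(math.sqrt(n_tiles)))
    rows = int(math.ceil(n_tiles / cols))
    canvas = (rows * th, cols * tw)
    classes = _tile_classes(rng, n_tiles, cols, spatial_split)
    image = np.zeros(canvas, dtype=np.float32)
    labels = np.zeros(canvas, dtype=np.int32)
    truth: dict[int, int] = {}
    for idx in range(n_tiles):
        r, c = divmod(idx, cols)
        s = sigma_a if classes[idx] == 1 else sigma_b
        patch = _oriented_tile(rng, tile, 0.0, (s, s), target_mean, target_sd)
        image[r * th : (r + 1) * th, c * tw : (c + 1) * tw] = patch
        labels[r * th : (r + 1) * th, c * tw : (c + 1) * tw] = idx + 1
        truth[idx + 1] = int(classes[idx])
    return SyntheticScene(
        image=ImageVolume(image[np.newaxis], image_id=f"granular_seed{seed}"),
        mask=LabelMask(labels, image_id=f"granular_seed{seed}"),
        truth=truth,
        params=dict(
            kind="granular", sigma_a=sigma_a, sigma_b=sigma_b, n_tiles=n_tiles,
            tile=tile, seed=seed, target_mean=target_mean, target_sd=target_sd,
            spatial_split=spatial_split,
        ),
    )


def gen_blobs3d(
    n_blobs: int = 20,
    two_class_rule: str = "intensity",
    canvas: tuple[int, int, int] = (40, 64, 64),
    seed: int = 0,
    base_mean: float = 100.0,
    delta: float = 100.0,
    elongation_factor: float = 2.0,
    noise_sd: float = 5.0,
    radius_range: tuple[int, int] = (3, 5),
) -> SyntheticScene:
    """Ellipsoidal blobs in a 3D volume; classes differ by mean intensity or
    by axis ratio depending on `two_class_rule`."""
    if two_class_rule not in ("intensity", "elongation"):
        raise ValueError(f"unknown two_class_rule {two_class_rule!r}")
    rng = np.random.default_rng(seed)
    # bounding radius accounts for possible elongation along x
    max_r = radius_range[1] * (elongation_factor if two_class_rule == "elongation" else 1.0)
    centers: list[np.ndarray] = []
    radii: list[float] = []
    semis: list[tuple[float, float, float]] = []
    classes_list: list[int] = []
    trials, cap = 0, 400 * n_blobs
    while len(centers) < n_blobs and trials < cap:
        trials += 1
        cls = 1 if len(centers) % 2 == 0 else 2
        r = float(rng.integers(radius_range[0], radius_range[1] + 1))
        rz, ry, rx = r, r, r
        if two_class_rule == "elongation" and cls == 2:
            rx = r * elongation_factor
        bound = max(rz, ry, rx)
        c = np.array([rng.integers(int(math.ceil(b)), s - int(math.ceil(b)))
                      for b, s in zip((rz, ry, rx), canvas)])
        ok = all(
            np.sum((c - c2) ** 2) > (bound + b2 + 1) ** 2
            for c2, b2 in zip(centers, radii)
        )
        if ok:
            centers.append(c)
            radii.append(bound)
            semis.append((rz, ry, rx))
            classes_list.append(cls)
    if len(centers) < n_blobs:
        raise RuntimeError(
            f"could not place {n_blobs} blobs on canvas {canvas}; achieved {len(centers)}"
        )
    image = np.zeros(canvas, dtype=np.float32)
    labels = np.zeros(canvas, dtype=np.int32)
    zz, yy, xx = np.mgrid[0 : canvas[0], 0 : canvas[1], 0 : canvas[2]]
    truth: dict[int, int] = {}
    for i, (c, (rz, ry, rx), cls) in enumerate(zip(centers, semis, classes_list), start=1):
        interior = (
            ((zz - c[0]) / rz) ** 2 + ((yy - c[1]) / ry) ** 2 + ((xx - c[2]) / rx) ** 2
        ) <= 1.0
        mean = base_mean + (delta if (two_class_rule == "intensity" and cls == 2) else 0.0)
        n_vox = int(interior.sum())
        values = np.full(n_vox, mean)
        if noise_sd > 0:
            values = values + rng.normal(0.0, noise_sd, size=n_vox)
        image[interior] = values.astype(np.float32)
        labels[interior] = i
        truth[i] = cls
    return SyntheticScene(
        image=ImageVolume(image[np.newaxis], image_id=f"blobs3d_seed{seed}"),
        mask=LabelMask(labels, image_id=f"blobs3d_seed{seed}"),
        truth=truth,
        params=dict(
            kind="blobs3d", n_blobs=n_blobs, two_class_rule=two_class_rule,
            canvas=canvas, seed=seed, base_mean=base_mean, delta=delta,
            elongation_factor=elongation_factor, noise_sd=noise_sd,
            radius_range=radius_range,
        ),
    )


def rotate_scene_90(scene: SyntheticScene) -> SyntheticScene:
    """An exactly 90-degree-rotated copy of a 2D scene (same truth)."""
    image = np.rot90(scene.image.pixels, k=1, axes=(-2, -1)).copy()
    labels = np.rot90(scene.mask.labels, k=1, axes=(-2, -1)).copy()
    return SyntheticScene(
        image=ImageVolume(image, image_id=scene.image.image_id + "_rot90"),
        mask=LabelMask(labels, image_id=scene.mask.image_id + "_rot90"),
        truth=dict(scene.truth),
        params={**scene.params, "rotated_90": True},
    )


def write_scene(scene: SyntheticScene, out_dir: str | Path) -> dict[str, Path]:
    """Write image TIFF (images/), mask TIFF (masks/, same stem) and truth
    JSON in the annotation-file schema with every object labeled."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    stem = scene.image.image_id
    pixels = scene.image.pixels
    if pixels.shape[0] == 1:  # single channel: store as plain 2D/3D TIFF
        pixels = pixels[0]
    paths = {
        "image": write_image(pixels, out_dir / "images" / f"{stem}.tif"),
        "mask": write_image(
            scene.mask.labels.astype(np.uint16), out_dir / "masks" / f"{stem}.tif"
        ),
    }
    records = [
        {"image_id": stem, "object_id": int(oid), "class": int(cls)}
        for oid, cls in sorted(scene.truth.items())
    ]
    truth_path = out_dir / f"{stem}_truth.json"
    truth_path.write_text(json.dumps(records, indent=1) + "\n")
    paths["truth"] = truth_path
    return paths
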