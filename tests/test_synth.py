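import numpy as np
import pytest

from segpatch import (
    gen_blobs3d,
    gen_cells,
    gen_granular_textures,
    gen_oriented_textures,
    rotate_scene_90,
    write_scene,
)


def interior_values(scene, oid):
    return scene.image.pixels[0][scene.mask.labels == oid]


class TestCells:
    def test_per_class_interior_means_near_targets(self):
        scene = gen_cells(n_cells=50, mean_a=80, mean_b=180, noise_sd=5, seed=1)
        for cls, target in ((1, 80.0), (2, 180.0)):
            for oid, c in scene.truth.items():
                if c != cls:
                    continue
                vals = interior_values(scene, oid)
                tol = 3 * 5 / np.sqrt(vals.size)
                assert abs(vals.mean() - target) < tol

    def test_zero_noise_gives_exactly_constant_interiors(self):
        scene = gen_cells(n_cells=20, noise_sd=0, seed=2)
        for oid, cls in scene.truth.items():
            vals = interior_values(scene, oid)
            assert np.all(vals == (80.0 if cls == 1 else 180.0))

    def test_same_seed_is_deterministic(self):
        a, b = gen_cells(seed=5), gen_cells(seed=5)
        np.testing.assert_array_equal(a.image.pixels, b.image.pixels)
        np.testing.assert_array_equal(a.mask.labels, b.mask.labels)
        assert a.truth == b.truth

    def test_impossible_placement_reports_achieved_count(self):
        with pytest.raises(RuntimeError, match="achieved"):
            gen_cells(n_cells=500, canvas=(64, 64), seed=0)

    def test_mask_labels_cover_1_to_n(self):
        scene = gen_cells(n_cells=30, seed=3)
        np.testing.assert_array_equal(scene.mask.object_ids(), np.arange(1, 31))

    def test_spatial_split_places_classes_by_half(self):
        scene = gen_cells(n_cells=40, spatial_split=True, seed=4)
        from segpatch import object_centroids

        centers = object_centroids(scene.mask)
        for oid, cls in scene.truth.items():
            assert cls == (1 if centers[oid][1] < 128 else 2)


class TestOrientedTextures:
    def test_moments_matched_across_classes(self):
        scene = gen_oriented_textures(n_tiles=20, tile=(24, 24), seed=0)
        stats = {1: [], 2: []}
        for oid, cls in scene.truth.items():
            vals = interior_values(scene, oid)
            stats[cls].append((vals.mean(), vals.var()))
        m1, v1 = np.mean(stats[1], axis=0)
        m2, v2 = np.mean(stats[2], axis=0)
        assert abs(m1 - m2) / m1 < 0.01
        assert abs(v1 - v2) / v1 < 0.01

    def test_equal_angles_rejected(self):
        with pytest.raises(ValueError, match="180"):
            gen_oriented_textures(theta_a=45, theta_b=225)

    def test_same_seed_is_deterministic(self):
        a = gen_oriented_textures(n_tiles=9, tile=(16, 16), seed=8)
        b = gen_oriented_textures(n_tiles=9, tile=(16, 16), seed=8)
        np.testing.assert_array_equal(a.image.pixels, b.image.pixels)

    def test_gradient_energy_statistic_separates_but_moments_do_not(self):
        """Brute-force oracle: oriented gradient energy separates the classes
        while per-tile mean/variance (matched by construction) cannot."""
        scene = gen_oriented_textures(n_tiles=30, tile=(24, 24), seed=2)
        ratios, means, classes = [], [], []
        img = scene.image.pixels[0]
        for oid, cls in sorted(scene.truth.items()):
            tile = img[np.ix_(*[np.unique(ix) for ix in np.nonzero(scene.mask.labels == oid)])]
            gy, gx = np.gradient(tile)
            ratios.append((gx**2).mean() / (gy**2).mean())
            means.append(tile.mean())
            classes.append(cls)
        ratios, means, classes = map(np.array, (ratios, means, classes))
        # class 1 (0 deg, horizontal streaks): variation along y >> along x
        assert ratios[classes == 1].max() < ratios[classes == 2].min()
        assert abs(means[classes == 1].mean() - means[classes == 2].mean()) < 1e-3

    def test_degenerate_tile_rejected(self):
        with pytest.raises(ValueError, match="tile"):
            gen_oriented_textures(tile=(1, 5))


class TestGranularTextures:
    def test_marginal_quantiles_matched_but_autocorrelation_differs(self):
        scene = gen_granular_textures(n_tiles=16, tile=(24, 24), seed=1)
        img = scene.image.pixels[0]
        q, corr, classes = [], [], []
        for oid, cls in sorted(scene.truth.items()):
            tile = img[np.ix_(*[np.unique(ix) for ix in np.nonzero(scene.mask.labels == oid)])]
            q.append(np.percentile(tile, [10, 50, 90]))
            # lag-1 autocorrelation along x as a granularity statistic
            t = tile - tile.mean()
            corr.append((t[:, 1:] * t[:, :-1]).mean() / t.var())
            classes.append(cls)
        q, corr, classes = np.array(q), np.array(corr), np.array(classes)
        assert np.allclose(q[classes == 1].mean(0), q[classes == 2].mean(0), rtol=0.05)
        assert corr[classes == 1].max() < corr[classes == 2].min()

    def test_spatial_split_halves_grid(self):
        scene = gen_granular_textures(n_tiles=16, tile=(16, 16), spatial_split=True, seed=0)
        # 4x4 grid: first two columns class 1, last two class 2
        for oid, cls in scene.truth.items():
            col = (oid - 1) % 4
            assert cls == (1 if col < 2 else 2)


class TestBlobs3D:
    def test_intensity_rule_separates_interior_means(self, blob_scene):
        means = {1: [], 2: []}
        for oid, cls in blob_scene.truth.items():
            means[cls].append(interior_values(blob_scene, oid).mean())
        assert max(means[1]) < min(means[2])

    def test_single_blob(self):
        scene = gen_blobs3d(n_blobs=1, canvas=(20, 24, 24), seed=0)
        assert list(scene.truth) == [1]
        assert scene.mask.object_ids().tolist() == [1]

    def test_elongation_rule_changes_axis_ratio(self):
        scene = gen_blobs3d(
            n_blobs=8, two_class_rule="elongation", canvas=(30, 80, 80),
            elongation_factor=2.0, seed=1,
        )
        ratios = {1: [], 2: []}
        for oid, cls in scene.truth.items():
            where = np.nonzero(scene.mask.labels == oid)
            extent_x = where[2].max() - where[2].min() + 1
            extent_y = where[1].max() - where[1].min() + 1
            ratios[cls].append(extent_x / extent_y)
        assert np.mean(ratios[2]) / np.mean(ratios[1]) > 1.5

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError, match="two_class_rule"):
            gen_blobs3d(two_class_rule="color")


def test_truth_covers_every_object(cells_scene, texture_scene, blob_scene):
    for scene in (cells_scene, texture_scene, blob_scene):
        assert set(scene.truth) == set(int(i) for i in scene.mask.object_ids())
        assert set(scene.truth.values()) == {1, 2}


def test_rotate_scene_90_preserves_objects(cells_scene):
    rot = rotate_scene_90(cells_scene)
    assert rot.truth == cells_scene.truth
    assert sorted(rot.mask.object_ids()) == sorted(cells_scene.mask.object_ids())
    np.testing.assert_array_equal(
        np.rot90(cells_scene.mask.labels), rot.mask.labels
    )


def test_write_scene_emits_paired_files(tmp_path, cells_scene):
    paths = write_scene(cells_scene, tmp_path)
    assert paths["image"].exists() and paths["mask"].exists() and paths["truth"].exists()
    assert paths["image"].stem == paths["mask"].stem  # stem pairing for batch mode
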