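import numpy as np
import pytest

from segpatch import (
    ClassifierSpec,
    PatchCNNClassifier,
    SmallConvNet,
    TrainingConfig,
    make_splits,
    train,
)
from segpatch.augment import augment, known_transforms
from segpatch.benchmarks import CELL_PATCH, GRAY_SCALE, labeled_patches
from segpatch.config import AugmentationStep
from segpatch.patches import PatchSet


def step(name, p=1.0, **params):
    return AugmentationStep(name=name, params=params, probability=p)


@pytest.fixture()
def labeled_cells(cells_scene):
    return labeled_patches(
        cells_scene, sorted(cells_scene.truth), patch_size=CELL_PATCH,
        normalization="none", intensity_scale=GRAY_SCALE,
    )


class TestAugment:
    def patch(self):
        rng = np.random.default_rng(0)
        return rng.normal(size=(2, 12, 12)).astype(np.float32)

    def test_hflip_is_an_involution(self):
        rng = np.random.default_rng(0)
        p = self.patch()
        once = augment(p, [step("hflip")], rng)
        twice = augment(once, [step("hflip")], rng)
        np.testing.assert_array_equal(twice, p)

    def test_rot90_four_times_is_identity(self):
        rng = np.random.default_rng(0)
        p = self.patch()
        out = p
        for _ in range(4):
            out = augment(out, [step("rot90")], rng)
        np.testing.assert_array_equal(out, p)

    def test_zero_probability_pipeline_is_identity(self):
        rng = np.random.default_rng(0)
        p = self.patch()
        pipeline = [step(name, p=0.0) for name in ("hflip", "vflip", "rot90")]
        np.testing.assert_array_equal(augment(p, pipeline, rng), p)

    def test_unknown_transform_lists_known_names(self):
        with pytest.raises(KeyError, match="hflip"):
            augment(self.patch(), [step("warp")], np.random.default_rng(0))

    def test_mask_channel_transformed_with_intensity(self):
        p = self.patch()
        p[1] = (p[0] > 0).astype(np.float32)  # mask channel mirrors intensity sign
        out = augment(p, [step("rot90")], np.random.default_rng(0))
        np.testing.assert_array_equal(out[1], (out[0] > 0).astype(np.float32))

    def test_rotate_keeps_shape_and_channels(self):
        out = augment(
            self.patch(), [step("rotate", angle_range=(-45, 45))],
            np.random.default_rng(1),
        )
        assert out.shape == (2, 12, 12)

    def test_builtins_registered(self):
        assert {"hflip", "vflip", "rot90", "rotate"} <= set(known_transforms())


class TestTrain:
    def small_model(self, n_channels=2, n_classes=2):
        spec = ClassifierSpec(dim=2, depth=2, width=8, in_channels=n_channels,
                              n_classes=n_classes, patch_size=CELL_PATCH)
        return SmallConvNet(spec, seed=0)

    def test_first_epoch_loss_near_ln_k(self, labeled_cells):
        cfg = TrainingConfig(epochs=1, seed=0, learning_rate=1e-5)
        _, hist = train(self.small_model(), labeled_cells, cfg)
        assert hist.loss[0] == pytest.approx(np.log(2), rel=0.10)

    def test_overfits_few_patches_to_full_training_accuracy(self, labeled_cells):
        subset = PatchSet(
            patches=labeled_cells.patches[:16],
            object_ids=labeled_cells.object_ids[:16],
            image_id=labeled_cells.image_id,
            patch_size=labeled_cells.patch_size,
            labels=labeled_cells.labels[:16],
        )
        cfg = TrainingConfig(seed=0)  # default epoch budget
        _, hist = train(self.small_model(), subset, cfg)
        assert max(hist.accuracy) == 1.0

    def test_empty_class_is_named(self, labeled_cells):
        only_one = PatchSet(
            patches=labeled_cells.patches[labeled_cells.labels == 1],
            object_ids=labeled_cells.object_ids[labeled_cells.labels == 1],
            image_id=labeled_cells.image_id,
            patch_size=labeled_cells.patch_size,
            labels=labeled_cells.labels[labeled_cells.labels == 1],
        )
        with pytest.raises(ValueError, match=r"class\(es\) \[2\]"):
            train(self.small_model(), only_one, TrainingConfig(epochs=1))

    def test_training_is_bit_deterministic(self, labeled_cells):
        weights = []
        for _ in range(2):
            model = self.small_model()
            cfg = TrainingConfig(epochs=5, seed=123,
                                 augmentation=[step("hflip", p=0.5)])
            train(model, labeled_cells, cfg)
            weights.append([p.copy() for p in model.params])
        for a, b in zip(*weights):
            np.testing.assert_array_equal(a, b)

    def test_step_decay_halves_learning_rate(self, labeled_cells):
        cfg = TrainingConfig(epochs=6, seed=0)
        cfg.step_decay.every_n_epochs = 2
        _, hist = train(self.small_model(), labeled_cells, cfg)
        np.testing.assert_allclose(
            hist.lr, [1e-3, 1e-3, 5e-4, 5e-4, 2.5e-4, 2.5e-4]
        )

    def test_validation_accuracy_recorded(self, labeled_cells):
        cfg = TrainingConfig(epochs=30, seed=0, validation_fraction=0.2)
        _, hist = train(self.small_model(), labeled_cells, cfg)
        assert hist.val_accuracy is not None
        assert 0.0 <= hist.val_accuracy <= 1.0

    def test_history_lengths_equal_epochs(self, labeled_cells):
        cfg = TrainingConfig(epochs=4, seed=0)
        _, hist = train(self.small_model(), labeled_cells, cfg)
        assert len(hist.loss) == len(hist.accuracy) == len(hist.lr) == 4


class TestSplits:
    def make_patchset(self, n1, n2):
        n = n1 + n2
        return PatchSet(
            patches=np.zeros((n, 1, 8, 8), dtype=np.float32),
            object_ids=np.arange(1, n + 1),
            image_id="x",
            patch_size=(8, 8),
            labels=np.array([1] * n1 + [2] * n2),
        )

    def test_zero_fraction_gives_empty_validation(self):
        train_set, val_set = make_splits(self.make_patchset(5, 5), 0.0, seed=0)
        assert len(val_set) == 0 and len(train_set) == 10

    def test_stratified_counts(self):
        train_set, val_set = make_splits(self.make_patchset(10, 10), 0.2, seed=0)
        assert len(train_set) == 16 and len(val_set) == 4
        assert np.sum(val_set.labels == 1) == 2 and np.sum(val_set.labels == 2) == 2

    def test_same_seed_same_split(self):
        a = make_splits(self.make_patchset(10, 10), 0.3, seed=9)
        b = make_splits(self.make_patchset(10, 10), 0.3, seed=9)
        np.testing.assert_array_equal(a[1].object_ids, b[1].object_ids)

    def test_fraction_emptying_a_class_fails(self):
        with pytest.raises(ValueError, match="class"):
            make_splits(self.make_patchset(1, 10), 0.5, seed=0)


class TestEstimatorContract:
    def test_sklearn_params_round_trip(self):
        clf = PatchCNNClassifier(depth=2, width=8, epochs=3)
        params = clf.get_params()
        assert params["depth"] == 2
        clone = PatchCNNClassifier(**params)
        assert clone.get_params() == params

    def test_fit_predict_proba_and_arbitrary_class_labels(self):
        rng = np.random.default_rng(0)
        X = np.zeros((12, 1, 8, 8), dtype=np.float32)
        X[:6] = rng.normal(1.0, 0.1, size=(6, 1, 8, 8))
        X[6:] = rng.normal(-1.0, 0.1, size=(6, 1, 8, 8))
        y = np.array([2] * 6 + [5] * 6)  # labels need not be 1..K
        clf = PatchCNNClassifier(depth=1, width=4, epochs=60, random_state=0)
        clf.fit(X, y)
        assert set(clf.classes_) == {2, 5}
        proba = clf.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, rtol=1e-5)
        assert set(clf.predict(X)) <= {2, 5}
        assert clf.score(X, y) == 1.0

    def test_unfitted_predict_raises(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            PatchCNNClassifier().predict(np.zeros((1, 1, 8, 8)))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            PatchCNNClassifier(epochs=1).fit(
                np.zeros((4, 1, 8, 8), dtype=np.float32), np.ones(4)
            )
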