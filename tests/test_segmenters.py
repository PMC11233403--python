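import numpy as np
import pytest

from glycovol import EMImage, SegMask
from glycovol.segmenters import (
    SegmenterConfig,
    UNetSegmenter,
    augment,
    build_segmenter,
    pixel_accuracy,
    predict_mask,
    train,
)


def _tiny_config(**kw):
    defaults = dict(
        n_classes=2,
        depth=2,
        base_channels=4,
        input_size=64,
        epochs=2,
        learning_rate=3e-3,
        augmentation=None,
        seed=0,
    )
    defaults.update(kw)
    return SegmenterConfig(**defaults)


def _granules_data(tiny_scenes):
    return [(img, gran) for img, _, gran in tiny_scenes]


class TestBuild:
    def test_output_is_distribution_of_input_shape(self):
        model = build_segmenter(_tiny_config())
        rng = np.random.default_rng(0)
        img = EMImage(rng.integers(0, 256, (64, 64)).astype(np.uint8), 0.8)
        probs = model.predict_proba(img.pixels)
        assert probs.shape == (64, 64, 2)
        np.testing.assert_allclose(probs.sum(axis=2), 1.0, rtol=1e-5)
        mask = predict_mask(model, img)
        assert mask.shape == img.shape

    def test_locations_model_emits_permitted_labels(self):
        model = build_segmenter(_tiny_config(n_classes=6))
        img = EMImage(np.zeros((64, 64), dtype=np.uint8), 0.8)
        mask = predict_mask(model, img)
        assert mask.scheme == "locations"
        assert set(np.unique(mask.labels)) <= set(range(6))

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            SegmenterConfig(n_classes=2, depth=3, input_size=100)

    def test_bad_class_count_rejected(self):
        with pytest.raises(ValueError):
            SegmenterConfig(n_classes=3)


class TestAugment:
    def _pair(self, seed=0):
        rng = np.random.default_rng(seed)
        img = EMImage(rng.integers(0, 256, (64, 64)).astype(np.uint8), 0.8)
        msk = SegMask(rng.integers(0, 2, (64, 64)).astype(np.uint8), 0.8, "granules")
        return img, msk

    def test_geometric_transform_preserves_label_multiset(self):
        img, msk = self._pair()
        spec = {"rot90": True, "mirror": True}
        for seed in range(5):
            _, out = augment(img, msk, spec, seed=seed)
            np.testing.assert_array_equal(
                np.bincount(out.labels.ravel()), np.bincount(msk.labels.ravel())
            )

    def test_contrast_only_leaves_mask_untouched(self):
        img, msk = self._pair()
        aug_img, out = augment(img, msk, {"contrast": (0.5, 1.5)}, seed=3)
        np.testing.assert_array_equal(out.labels, msk.labels)
        assert not np.array_equal(aug_img.pixels, img.pixels)

    def test_same_seed_reproducible(self):
        img, msk = self._pair()
        spec = {"rot90": True, "mirror": True, "contrast": (0.8, 1.2)}
        a_img, a_msk = augment(img, msk, spec, seed=9)
        b_img, b_msk = augment(img, msk, spec, seed=9)
        np.testing.assert_array_equal(a_img.pixels, b_img.pixels)
        np.testing.assert_array_equal(a_msk.labels, b_msk.labels)


class TestPixelAccuracy:
    def test_identity_complement_half(self):
        a = SegMask(np.zeros((8, 8), dtype=np.uint8), 0.8, "granules")
        b = SegMask(np.ones((8, 8), dtype=np.uint8), 0.8, "granules")
        half = np.zeros((8, 8), dtype=np.uint8)
        half[:4] = 1
        h = SegMask(half, 0.8, "granules")
        assert pixel_accuracy(a, a) == 1.0
        assert pixel_accuracy(a, b) == 0.0
        assert pixel_accuracy(a, h) == 0.5

    def test_symmetry_and_shape_check(self):
        rng = np.random.default_rng(1)
        a = SegMask(rng.integers(0, 2, (8, 8)).astype(np.uint8), 0.8, "granules")
        b = SegMask(rng.integers(0, 2, (8, 8)).astype(np.uint8), 0.8, "granules")
        assert pixel_accuracy(a, b) == pixel_accuracy(b, a)
        with pytest.raises(ValueError):
            pixel_accuracy(a, SegMask(np.zeros((4, 4), dtype=np.uint8), 0.8, "granules"))


class TestTraining:
    def test_same_seed_same_first_epoch_loss(self, tiny_scenes):
        data = _granules_data(tiny_scenes)
        r1 = train(build_segmenter(_tiny_config(epochs=1)), data)
        r2 = train(build_segmenter(_tiny_config(epochs=1)), data)
        assert r1.train_loss[0] == r2.train_loss[0]

    def test_zero_learning_rate_is_a_no_op(self, tiny_scenes):
        data = _granules_data(tiny_scenes)
        cfg = _tiny_config(learning_rate=0.0, epochs=2)
        model = build_segmenter(cfg)
        before = [predict_mask(model, img).labels.copy() for img, _ in data]
        train(model, data)
        after = [predict_mask(model, img).labels for img, _ in data]
        for x, y in zip(before, after):
            np.testing.assert_array_equal(x, y)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train(build_segmenter(_tiny_config()), [])

    def test_missing_class_warns(self, tiny_scenes):
        img, _, _ = tiny_scenes[0]
        empty = SegMask(np.zeros(img.shape, dtype=np.uint8), img.pixel_nm, "granules")
        report = train(build_segmenter(_tiny_config(epochs=1)), [(img, empty)])
        assert any("absent" in w for w in report.warnings)

    def test_loss_decreases_on_tiny_overfit(self, tiny_scenes):
        data = _granules_data(tiny_scenes)
        report = train(build_segmenter(_tiny_config(epochs=15)), data)
        assert report.train_loss[-1] < report.train_loss[0]
        baseline = 1 - np.mean([m.labels.mean() for _, m in data])
        assert report.final_accuracy > 0.8 * baseline

    def test_optimizer_alternation_covers_both_rules(self, tiny_scenes):
        # epochs spanning two switch periods must not diverge or error
        data = _granules_data(tiny_scenes)
        cfg = _tiny_config(epochs=4, switch_epochs=2)
        report = train(build_segmenter(cfg), data)
        assert len(report.train_loss) == 4
        assert np.isfinite(report.train_loss).all()


class TestPredictAndPersist:
    def test_prediction_deterministic(self, tiny_scenes):
        img, _, _ = tiny_scenes[0]
        model = build_segmenter(_tiny_config())
        np.testing.assert_array_equal(
            predict_mask(model, img).labels, predict_mask(model, img).labels
        )

    def test_tiling_matches_model_on_tiles(self, tiny_scenes):
        model = build_segmenter(_tiny_config())
        rng = np.random.default_rng(2)
        big = EMImage(rng.integers(0, 256, (128, 128)).astype(np.uint8), 0.8)
        full = predict_mask(model, big)
        tile = predict_mask(model, EMImage(big.pixels[:64, :64], 0.8))
        np.testing.assert_array_equal(full.labels[:64, :64], tile.labels)

    def test_untileable_size_rejected(self):
        model = build_segmenter(_tiny_config())
        with pytest.raises(ValueError):
            predict_mask(model, EMImage(np.zeros((96, 96), dtype=np.uint8), 0.8))

    def test_save_load_round_trip(self, tiny_scenes, tmp_path):
        img, _, _ = tiny_scenes[0]
        model = build_segmenter(_tiny_config())
        model.save(tmp_path / "ckpt")
        clone = UNetSegmenter.load(tmp_path / "ckpt")
        np.testing.assert_array_equal(
            predict_mask(model, img).labels, predict_mask(clone, img).labels
        )
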