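import numpy as np
import pytest

from cardiosynth.errors import ConfigError, EmptyDatasetError, ShapeMismatchError
from cardiosynth.phantom import make_phantom_params, render_phantom
from cardiosynth.stats import dice_coefficient
from cardiosynth.unet import (AugmentationSpec, SegModel, SegTrainConfig,
                              UNet, UNetConfig, augment_pair, build_unet_spec,
                              expand_dataset, predict_segmentation, train_unet)


class TestUNetSpec:
    def test_channel_doubling_rule(self):
        spec = build_unet_spec(UNetConfig(input_resolution=128, depth=4,
                                          base_channels=64))
        enc = [b[0].out_channels for b in spec.blocks[:4]]
        assert enc == [64, 128, 256, 512]
        assert spec.blocks[4][0].out_channels == 1024     # bottleneck

    def test_output_matches_input_resolution(self):
        for res, depth in [(32, 3), (64, 3), (128, 4)]:
            cfg = UNetConfig(input_resolution=res, depth=depth, base_channels=4)
            net = UNet(cfg, np.random.default_rng(0))
            x = np.zeros((1, 1, res, res), np.float32)
            assert net.forward(x).shape == (1, cfg.n_classes, res, res)

    def test_concatenation_junction_count_equals_depth(self):
        cfg = UNetConfig(input_resolution=64, depth=3, base_channels=8)
        spec = build_unet_spec(cfg)
        concats = [d for b in spec.blocks for d in b if d.kind == "concat"]
        assert len(concats) == 3

    def test_indivisible_resolution_rejected(self):
        with pytest.raises(ConfigError):
            UNetConfig(input_resolution=100, depth=4)


class TestAugmentation:
    def _pair(self, res=64, seed=0):
        params = make_phantom_params("SAX", seed, 0.2)
        return render_phantom(params, res)

    def test_zero_limits_is_identity(self):
        image, masks = self._pair()
        spec = AugmentationSpec(rotation_limit=0, width_shift=0,
                                height_shift=0, shear_limit=0, zoom_limit=0)
        out_img, out_masks = augment_pair(image, masks, spec, rng_seed=5)
        assert np.array_equal(out_img.pixels, image.pixels)
        for k in masks:
            assert np.array_equal(out_masks[k], masks[k])

    def test_labels_preserved_subset(self):
        image, masks = self._pair()
        out_img, out_masks = augment_pair(image, masks, AugmentationSpec(), 3)
        assert set(out_masks) <= set(masks)

    def test_seeded_determinism(self):
        image, masks = self._pair()
        a = augment_pair(image, masks, AugmentationSpec(), 11)
        b = augment_pair(image, masks, AugmentationSpec(), 11)
        assert np.array_equal(a[0].pixels, b[0].pixels)
        for k in a[1]:
            assert np.array_equal(a[1][k], b[1][k])

    def test_small_rotation_preserves_disk_area(self):
        # centered disk, pure rotation: area change only from resampling
        mask = np.zeros((64, 64), bool)
        yy, xx = np.mgrid[:64, :64]
        mask[(yy - 31.5) ** 2 + (xx - 31.5) ** 2 < 15 ** 2] = True
        image = mask.astype(float)
        spec = AugmentationSpec(rotation_limit=20, width_shift=0,
                                height_shift=0, shear_limit=0, zoom_limit=0)
        _, out = augment_pair(image, {"LV": mask}, spec, rng_seed=2)
        assert out["LV"].sum() == pytest.approx(mask.sum(), rel=0.05)

    def test_flips_rejected(self):
        with pytest.raises(ConfigError):
            AugmentationSpec(flips=True)

    def test_expand_factor_and_determinism(self):
        pairs = [self._pair(seed=s) for s in range(3)]
        out = expand_dataset(pairs, AugmentationSpec(), factor=4, rng_seed=7)
        assert len(out) == 12
        again = expand_dataset(pairs, AugmentationSpec(), factor=4, rng_seed=7)
        for (i1, m1), (i2, m2) in zip(out, again):
            assert np.array_equal(i1.pixels, i2.pixels)

    def test_expand_identity_copy(self):
        pairs = [self._pair(seed=9)]
        zero = AugmentationSpec(rotation_limit=0, width_shift=0,
                                height_shift=0, shear_limit=0, zoom_limit=0)
        out = expand_dataset(pairs, zero, factor=1, rng_seed=0)
        assert np.array_equal(out[0][0].pixels, pairs[0][0].pixels)


@pytest.fixture(scope="module")
def trained(sax_pairs_64):
    cfg = UNetConfig(input_resolution=64, n_classes=3, depth=3,
                     base_channels=8)
    tcfg = SegTrainConfig(epochs=12, batch_size=8, learning_rate=1e-3,
                          rng_seed=0, validation_split=0.1)
    return train_unet(sax_pairs_64, cfg, tcfg, view="SAX")


class TestTrainPredict:

    def test_loss_decreases(self, trained):
        _, log = trained
        assert log.epoch_train_loss[-1] < log.epoch_train_loss[0]
        assert np.all(np.isfinite(log.epoch_train_loss))

    def test_prediction_beats_empty_baseline(self, trained, sax_pairs_64):
        model, _ = trained
        frame, masks = sax_pairs_64[-1]
        pred = predict_segmentation(model, frame)
        assert dice_coefficient(pred["LV"], masks["LV"]) > 0.0

    def test_predicted_masks_disjoint(self, trained, sax_pairs_64):
        model, _ = trained
        pred = predict_segmentation(model, sax_pairs_64[0][0])
        overlap = np.zeros((64, 64), int)
        for m in pred.values():
            overlap += m.astype(int)
        assert overlap.max() <= 1

    def test_prediction_deterministic(self, trained, sax_pairs_64):
        model, _ = trained
        a = predict_segmentation(model, sax_pairs_64[0][0])
        b = predict_segmentation(model, sax_pairs_64[0][0])
        for k in a:
            assert np.array_equal(a[k], b[k])

    def test_wrong_resolution_rejected(self, trained):
        model, _ = trained
        with pytest.raises(ShapeMismatchError):
            predict_segmentation(model, np.zeros((32, 32)))

    def test_training_determinism(self, sax_pairs_64):
        cfg = UNetConfig(input_resolution=64, n_classes=3, depth=2,
                         base_channels=4)
        tcfg = SegTrainConfig(epochs=2, batch_size=8, learning_rate=1e-3,
                              rng_seed=5, validation_split=0.1)
        _, log1 = train_unet(sax_pairs_64[:16], cfg, tcfg, view="SAX")
        _, log2 = train_unet(sax_pairs_64[:16], cfg, tcfg, view="SAX")
        assert log1.epoch_train_loss == log2.epoch_train_loss

    def test_empty_dataset_rejected(self):
        cfg = UNetConfig(input_resolution=64, depth=2, base_channels=4)
        with pytest.raises(EmptyDatasetError):
            train_unet([], cfg, SegTrainConfig(), view="SAX")

    def test_save_load_roundtrip(self, trained, sax_pairs_64, tmp_path):
        model, _ = trained
        model.save(tmp_path / "seg.npz")
        loaded = SegModel.load(tmp_path / "seg.npz")
        a = predict_segmentation(model, sax_pairs_64[2][0])
        b = predict_segmentation(loaded, sax_pairs_64[2][0])
        for k in a:
            assert np.array_equal(a[k], b[k])
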