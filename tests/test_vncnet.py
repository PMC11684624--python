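"""VNC-Net: normalisation, augmentation, architecture, training, inference."""

import numpy as np
import pytest

from vncct.image import CTImage
from vncct.nn import BatchNorm2d, Conv2d, ConvTranspose2d, MSELoss
from vncct.vncnet import (PairedSliceDataset, TrainConfig, UNetConfig, VNCNet,
                          augment_center_crop, build_vncnet, denormalize_hu,
                          normalize_hu, predict)


class TestNormalisation:
    @pytest.mark.parametrize("hu,expected", [
        (-1024.0, 0.0),
        (3071.0, 1.0),
        (0.0, 1024.0 / 4095.0),
    ])
    def test_fixed_points(self, hu, expected):
        assert normalize_hu(hu) == pytest.approx(expected, abs=1e-7)

    def test_roundtrip_identities(self, rng):
        hu = rng.uniform(-1024, 3071, (16, 16)).astype(np.float32)
        np.testing.assert_allclose(denormalize_hu(normalize_hu(hu)), hu, atol=1e-3)
        v = rng.random((16, 16)).astype(np.float32)
        np.testing.assert_allclose(normalize_hu(denormalize_hu(v)), v, atol=1e-6)

    def test_clamping_before_normalisation(self):
        assert normalize_hu(-5000.0) == 0.0
        assert normalize_hu(9000.0) == 1.0


class TestAugmentation:
    def test_reference_training_set_arithmetic(self):
        """6390 slices with 10% centre-crop augmentation grow to 7029."""
        ds = PairedSliceDataset(np.zeros((6390, 4, 4), dtype=np.float32),
                                np.zeros((6390, 4, 4), dtype=np.float32))
        out = augment_center_crop(ds, fraction=0.10, seed=0)
        assert len(out) == 7029
        assert out.augmented_flags.sum() == 639

    def test_zero_fraction_is_identity(self):
        ds = PairedSliceDataset(np.random.default_rng(0).random((10, 8, 8)).astype(np.float32),
                                np.random.default_rng(1).random((10, 8, 8)).astype(np.float32))
        out = augment_center_crop(ds, fraction=0.0)
        assert len(out) == 10 and not out.augmented_flags.any()

    def test_full_fraction_doubles(self):
        ds = PairedSliceDataset(np.random.default_rng(0).random((10, 8, 8)).astype(np.float32),
                                np.random.default_rng(1).random((10, 8, 8)).astype(np.float32))
        out = augment_center_crop(ds, fraction=1.0)
        assert len(out) == 20 and out.augmented_flags.sum() == 10

    def test_crop_zooms_in(self):
        # a centre bright square grows when the centre is cropped and resized
        x = np.zeros((1, 32, 32), dtype=np.float32)
        x[0, 12:20, 12:20] = 1.0
        ds = PairedSliceDataset(x, x.copy())
        out = augment_center_crop(ds, fraction=1.0, crop_ratio=0.5, seed=0)
        assert out.inputs[1].sum() > out.inputs[0].sum()

    def test_invalid_crop_ratio_rejected(self):
        ds = PairedSliceDataset(np.zeros((2, 8, 8), dtype=np.float32),
                                np.zeros((2, 8, 8), dtype=np.float32))
        with pytest.raises(ValueError):
            augment_center_crop(ds, crop_ratio=0.0)

    def test_dataset_validation(self):
        with pytest.raises(ValueError):
            PairedSliceDataset(np.zeros((2, 8, 8)), np.zeros((2, 4, 4)))
        with pytest.raises(ValueError):
            PairedSliceDataset(np.full((2, 8, 8), 2.0), np.zeros((2, 8, 8)))


def _analytic_param_count(cfg: UNetConfig) -> int:
    """Closed-form parameter sum over the stated layer list."""
    def conv(cin, cout, k):
        return cin * cout * k * k + cout  # weights + bias

    def bn(c):
        return 2 * c

    def block(cin, cout):  # two ConvBNReLU blocks
        return conv(cin, cout, 3) + bn(cout) + conv(cout, cout, 3) + bn(cout)

    total = 0
    cin = cfg.input_channels
    for cout in cfg.encoder_channels:
        total += block(cin, cout)
        cin = cout
    total += block(cin, cfg.bottleneck_channels)
    cin = cfg.bottleneck_channels
    for skip in reversed(cfg.encoder_channels):
        total += cin * skip * 2 * 2 + skip  # transposed conv 2x2
        total += block(2 * skip, skip)
        cin = skip
    total += conv(cin, cfg.output_channels, 1)
    return total


class TestArchitecture:
    def test_default_config_channels(self):
        cfg = UNetConfig()
        assert cfg.encoder_channels == (32, 64, 128, 256)
        assert cfg.depth == 4

    def test_non_increasing_channels_rejected(self):
        with pytest.raises(ValueError):
            UNetConfig(encoder_channels=(32, 32, 64, 128))

    def test_shape_preservation_default_width(self):
        net = build_vncnet(UNetConfig(), seed=0)
        out = net.forward(np.zeros((1, 1, 64, 64), dtype=np.float32), training=False)
        assert out.shape == (1, 1, 64, 64)

    def test_parameter_count_matches_closed_form(self):
        for cfg in (UNetConfig(), UNetConfig(encoder_channels=(4, 8, 16, 32),
                                             bottleneck_channels=64)):
            net = build_vncnet(cfg, seed=0)
            assert net.param_count() == _analytic_param_count(cfg)

    def test_indivisible_input_rejected(self):
        net = build_vncnet(UNetConfig(encoder_channels=(2, 4, 6, 8),
                                      bottleneck_channels=12), seed=0)
        with pytest.raises(ValueError, match="divisible"):
            net.forward(np.zeros((1, 1, 100, 100), dtype=np.float32))

    def test_gradients_match_finite_differences(self):
        """Float64 spot check of conv / transposed-conv / batch-norm
        backward passes against central differences."""
        rng = np.random.default_rng(0)
        for layer, shape in [
            (Conv2d(2, 3, 3, rng), (2, 2, 6, 6)),
            (ConvTranspose2d(3, 2, rng), (2, 3, 4, 4)),
            (BatchNorm2d(2), (3, 2, 5, 5)),
        ]:
            layer.params = {k: v.astype(np.float64) for k, v in layer.params.items()}
            x = rng.normal(size=shape)
            dout = rng.normal(size=layer.forward(x, training=True).shape)
            dx = layer.backward(dout)
            eps = 1e-6
            for _ in range(5):
                idx = tuple(rng.integers(0, s) for s in shape)
                xp, xm = x.copy(), x.copy()
                xp[idx] += eps
                xm[idx] -= eps
                num = ((layer.forward(xp, training=True) * dout).sum()
                       - (layer.forward(xm, training=True) * dout).sum()) / (2 * eps)
                assert num == pytest.approx(dx[idx], abs=1e-5, rel=1e-4)


def _toy_dataset(n=40, size=32, seed=0):
    """Smooth CT-like slices (band-limited noise) in normalised units."""
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    x = ndimage.gaussian_filter(rng.normal(0, 1, (n, size, size)), (0, 5, 5))
    x -= x.min(axis=(1, 2), keepdims=True)
    x /= np.maximum(x.max(axis=(1, 2), keepdims=True), 1e-9) / 0.4
    return PairedSliceDataset(x.astype(np.float32) + 0.1, x.astype(np.float32) + 0.1)


@pytest.fixture(scope="module")
def identity_model():
    """A network trained on identical input/target slices."""
    ds = _toy_dataset(n=60, size=32, seed=3)
    model = VNCNet(encoder_channels=(8, 16, 32, 64), bottleneck_channels=128,
                   epochs=40, batch_size=5, learning_rate=1e-2,
                   rng_seed=2, lr_schedule="cosine")
    model.fit_dataset(ds)
    return model


class TestTraining:
    @staticmethod
    def _toy_dataset(n=40, size=32, seed=0):
        return _toy_dataset(n, size, seed)

    def test_zero_epochs_leaves_weights_untouched(self):
        model = VNCNet(encoder_channels=(2, 4, 8, 16), bottleneck_channels=32,
                       epochs=0, rng_seed=1)
        model.fit_dataset(self._toy_dataset())
        ref = build_vncnet(model.config_, seed=1)
        for got, exp in zip(model.model_.param_layers(), ref.param_layers()):
            for key in got.params:
                np.testing.assert_array_equal(got.params[key], exp.params[key])
        assert model.history_["train_loss"] == []

    def test_empty_dataset_rejected(self):
        model = VNCNet()
        with pytest.raises(ValueError):
            model.fit_dataset(PairedSliceDataset(np.zeros((0, 8, 8), dtype=np.float32),
                                                 np.zeros((0, 8, 8), dtype=np.float32)))

    def test_training_is_deterministic(self):
        kw = dict(encoder_channels=(2, 4, 8, 16), bottleneck_channels=32,
                  epochs=3, batch_size=10, learning_rate=1e-3, rng_seed=5)
        a = VNCNet(**kw).fit_dataset(self._toy_dataset())
        b = VNCNet(**kw).fit_dataset(self._toy_dataset())
        assert a.history_ == b.history_
        probe = np.random.default_rng(0).uniform(-500, 500, (1, 32, 32)).astype(np.float32)
        np.testing.assert_array_equal(a.predict(probe), b.predict(probe))

    def test_identity_task_reaches_low_mse(self, identity_model):
        """Trained on identical input/target slices, the network learns the
        identity map to normalised MSE below 1e-3."""
        ds = _toy_dataset(n=60, size=32, seed=3)
        pred = identity_model.model_.forward(ds.inputs[:10, None], training=False)
        mse = float(np.mean((pred[:, 0] - ds.targets[:10]) ** 2))
        assert mse < 1e-3

    def test_loss_decreases_on_learnable_problem(self, recovery_results):
        """Across the recovery experiment's training runs the final epoch's
        loss falls well below the first epoch's."""
        for result in recovery_results[:3]:
            losses = result.train_loss
            assert losses[-1] < 0.25 * losses[0]

    def test_validation_history_and_checkpoint(self):
        ds = self._toy_dataset(n=30)
        val = self._toy_dataset(n=10, seed=9)
        model = VNCNet(encoder_channels=(2, 4, 8, 16), bottleneck_channels=32,
                       epochs=2, batch_size=10, learning_rate=1e-3, rng_seed=0)
        model.fit_dataset(ds, validation=val)
        assert len(model.history_["val_loss"]) == 2
        assert model.best_val_state_ is not None

    def test_invalid_train_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(batch_size=0)
        with pytest.raises(ValueError):
            TrainConfig(epochs=-1)
        with pytest.raises(ValueError):
            TrainConfig(augment_fraction=1.5)
        with pytest.raises(ValueError):
            TrainConfig(lr_schedule="linear")


class TestInference:
    def test_multislice_volume_preserves_slice_count(self, identity_model):
        vox = np.random.default_rng(1).uniform(-400, 400, (4, 32, 32)).astype(np.float32)
        img = CTImage(voxels=vox, spacing_mm=(1.0, 1.0, 1.0), domain_tag="pseudo_dect")
        out = predict(identity_model, img)
        assert out.voxels.shape == (4, 32, 32)
        assert out.domain_tag == "vnc"
        assert out.spacing_mm == img.spacing_mm

    def test_unfitted_model_rejected(self):
        with pytest.raises(AttributeError):
            VNCNet().predict(np.zeros((1, 32, 32)))

    def test_checkpoint_roundtrip(self, identity_model, tmp_path):
        path = tmp_path / "model.npz"
        identity_model.save(path)
        loaded = VNCNet.load(path)
        probe = np.random.default_rng(4).uniform(-500, 500, (2, 32, 32)).astype(np.float32)
        np.testing.assert_array_equal(identity_model.predict(probe), loaded.predict(probe))
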