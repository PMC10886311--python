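"""Network architecture contracts, gradients, training behavior, baseline."""

import numpy as np
import pytest

from vascusr.nn import ResUNet, mse_loss
from vascusr.srnet import (
    BilinearUpscaler,
    ModelConfig,
    ResUNetUpscaler,
    bilinear_upscale,
    bilinear_upscale_frame,
    build_model,
    load_checkpoint,
    save_checkpoint,
    subpixel_upsample,
    upscale,
    zoh_blur_kernel,
)
from vascusr.preprocess import ImageStack


class TestArchitecture:
    @pytest.mark.parametrize(
        "in_frames,scale,side",
        [(1, 4, 32), (5, 4, 16), (1, 2, 16), (5, 2, 8)],
    )
    def test_output_side_is_scale_times_input(self, in_frames, scale, side):
        net = build_model(
            ModelConfig(
                in_frames=in_frames, scale=scale, encoder_depth=2, base_channels=4
            )
        )
        x = np.random.default_rng(0).random((2, in_frames, side, side))
        out = net.forward(x)
        assert out.shape == (2, 1, side * scale, side * scale)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(in_frames=3)
        with pytest.raises(ValueError):
            ModelConfig(scale=3)
        with pytest.raises(ValueError):
            ResUNet(encoder_depth=0)

    def test_indivisible_input_side_rejected(self):
        net = build_model(ModelConfig(encoder_depth=3, base_channels=4))
        with pytest.raises(ValueError, match="divisible"):
            net.forward(np.zeros((1, 1, 12, 12)))

    def test_gradients_match_finite_differences(self):
        net = ResUNet(in_frames=1, scale=2, encoder_depth=1, base_channels=4, seed=3)
        rng = np.random.default_rng(0)
        x = rng.random((2, 1, 8, 8))
        t = rng.random((2, 1, 16, 16))
        _, grad = mse_loss(net.forward(x), t)
        net.zero_grad()
        gx = net.backward(grad)
        eps = 1e-6
        for p in net.params():
            flat, gflat = p.value.ravel(), p.grad.ravel()
            for idx in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                old = flat[idx]
                flat[idx] = old + eps
                lp = mse_loss(net.forward(x), t)[0]
                flat[idx] = old - eps
                lm = mse_loss(net.forward(x), t)[0]
                flat[idx] = old
                num = (lp - lm) / (2 * eps)
                assert gflat[idx] == pytest.approx(num, rel=1e-4, abs=1e-9)
        idx = rng.choice(x.size, size=5, replace=False)
        for i in idx:
            old = x.flat[i]
            x.flat[i] = old + eps
            lp = mse_loss(net.forward(x), t)[0]
            x.flat[i] = old - eps
            lm = mse_loss(net.forward(x), t)[0]
            x.flat[i] = old
            assert gx.flat[i] == pytest.approx((lp - lm) / (2 * eps), rel=1e-4, abs=1e-9)


class TestSubpixelUpsample:
    def test_constant_map_preserved(self):
        x = np.full((1, 4, 2, 2), 0.7)
        out = subpixel_upsample(x, factor=2, blur=True)
        assert out.shape == (1, 1, 4, 4)
        assert np.allclose(out, 0.7)

    def test_checkerboard_blurred_to_half(self):
        # channels arranged so the shuffle yields alternating 0/1 pattern
        x = np.zeros((1, 4, 4, 4))
        x[:, 0] = 1.0  # (even row, even col) positions
        x[:, 3] = 1.0  # (odd row, odd col) positions
        shuffled = subpixel_upsample(x, factor=2, blur=False)
        assert set(np.unique(shuffled)) == {0.0, 1.0}
        blurred = subpixel_upsample(x, factor=2, blur=True)
        # a box-2 kernel over any 2x2 window of a checkerboard averages to 1/2
        assert np.allclose(blurred[0, 0, 1:, 1:], 0.5)

    @pytest.mark.parametrize("factor", [2, 4])
    def test_blur_kernel_normalized(self, factor):
        assert zoh_blur_kernel(factor).sum() == pytest.approx(1.0)

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ValueError):
            subpixel_upsample(np.zeros((1, 3, 4, 4)), factor=2)


class TestTraining:
    @staticmethod
    def _toy_data(n=12, side=8, seed=0):
        rng = np.random.default_rng(seed)
        y = np.stack(
            [np.clip(np.add.outer(rng.random(32), rng.random(32)) / 2, 0, 1)
             for _ in range(n)]
        )
        X = np.stack([y[i][::4, ::4] for i in range(n)])
        return X, y

    def test_loss_decreases_on_learnable_task(self):
        # from random init (no residual shortcut) training must make progress
        X, y = self._toy_data()
        est = ResUNetUpscaler(
            encoder_depth=1, base_channels=4, epochs=4, seed=1,
            global_residual=False,
        )
        est.fit(X, y)
        hist = est.loss_history_
        assert hist[-1]["train_loss"] < hist[0]["train_loss"]

    def test_best_val_loss_monotone_nonincreasing(self):
        X, y = self._toy_data()
        est = ResUNetUpscaler(encoder_depth=1, base_channels=4, epochs=5, seed=1)
        est.fit(X, y)
        best = [h["best_val_loss"] for h in est.loss_history_]
        assert all(a >= b for a, b in zip(best, best[1:]))
        assert est.best_val_loss_ == min(h["val_loss"] for h in est.loss_history_)

    def test_same_seed_identical_histories(self):
        X, y = self._toy_data()
        h = []
        for _ in range(2):
            est = ResUNetUpscaler(encoder_depth=1, base_channels=4, epochs=3, seed=7)
            est.fit(X, y)
            h.append([e["train_loss"] for e in est.loss_history_])
        assert np.allclose(h[0], h[1], atol=1e-6)

    def test_empty_dataset_rejected(self):
        est = ResUNetUpscaler()
        with pytest.raises(ValueError):
            est.fit(np.zeros((0, 8, 8)), np.zeros((0, 32, 32)))

    def test_shape_mismatch_rejected(self):
        est = ResUNetUpscaler(scale=4)
        with pytest.raises(ValueError, match="target side"):
            est.fit(np.zeros((2, 8, 8)), np.zeros((2, 16, 16)))

    def test_sklearn_params_round_trip(self):
        est = ResUNetUpscaler(base_channels=16, epochs=2)
        params = est.get_params()
        assert params["base_channels"] == 16
        clone = ResUNetUpscaler(**params)
        assert clone.get_params() == params


class TestUpscaleStack:
    def test_single_frame_shape_contract(self, tiny_trained_upscaler):
        stack = ImageStack(
            np.random.default_rng(1).integers(0, 256, (10, 8, 8), dtype=np.uint8),
            bit_depth=8,
        )
        out = upscale(tiny_trained_upscaler, stack)
        assert out.voxels.shape == (10, 32, 32)
        assert out.bit_depth == 8
        # in-plane pixel size shrinks fourfold, axial spacing unchanged
        assert out.spacing_um[0] == stack.spacing_um[0]
        assert out.spacing_um[1] == pytest.approx(stack.spacing_um[1] / 4)

    def test_multiframe_edge_frames_via_reflection(self):
        X, y = TestTraining._toy_data(n=10)
        est = ResUNetUpscaler(
            in_frames=5, encoder_depth=1, base_channels=4, epochs=1, seed=0
        )
        # build a minimal multi-frame training set from the toy frames
        Xmf = np.stack([X[i : i + 5] for i in range(6)])
        ymf = np.stack([y[i + 2] for i in range(6)])
        est.fit(Xmf, ymf)
        stack = ImageStack(
            (X * 255).astype(np.uint8), bit_depth=8, spacing_um=(3, 1, 1)
        )
        out = upscale(est, stack)
        assert out.voxels.shape == (10, 32, 32)

    def test_checkpoint_round_trip(self, tiny_trained_upscaler, tmp_path):
        path = tmp_path / "model.npz"
        save_checkpoint(tiny_trained_upscaler, path)
        back = load_checkpoint(path)
        X = np.random.default_rng(0).random((3, 8, 8))
        assert np.allclose(back.predict(X), tiny_trained_upscaler.predict(X))
        assert back.get_params() == tiny_trained_upscaler.get_params()


class TestBilinear:
    def test_constant_frame_preserved(self):
        out = bilinear_upscale_frame(np.full((8, 8), 0.25), 4)
        assert out.shape == (32, 32)
        assert np.allclose(out, 0.25)

    def test_closed_form_columns(self):
        # half-pixel-centre convention: output col centers at input coords
        # -0.25, 0.25, 0.75, 1.25 -> values 0, 0.25, 0.75, 1 for cols [0, 1]
        frame = np.array([[0.0, 1.0], [0.0, 1.0]])
        out = bilinear_upscale_frame(frame, 2)
        expected_row = np.array([0.0, 0.25, 0.75, 1.0])
        assert np.allclose(out, np.tile(expected_row, (4, 1)))

    def test_stack_shape_and_estimator_equivalence(self, random_stack8):
        out = bilinear_upscale(random_stack8, factor=4)
        assert out.voxels.shape == (6, 128, 128)
        est = BilinearUpscaler(factor=4).fit()
        arr = est.transform(random_stack8.astype_float())
        assert np.allclose(arr, out.astype_float(), atol=1 / 255)
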