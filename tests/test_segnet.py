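"""Network structure, exact backprop, and inference contracts."""

import numpy as np
import pytest

from cherenseg.objective import LossConfig, seg_loss, seg_loss_grad
from cherenseg.segnet import (
    NetworkConfig,
    SegModel,
    _sigmoid,
    binarize,
    build_model,
)


def _analytic_param_count(cfg: NetworkConfig) -> int:
    """Independent closed-form enumeration of the trainable parameters.

    conv: cout*cin*k*k + cout;  batch norm: 2*c;  residual block: 2 BN +
    2 convs of c channels.  Layer list: stem conv, per-level encoder blocks
    with strided down-convs between levels, per-level decoder 1x1
    reduction + blocks, and the 1x1 head.
    """
    def conv(cin, cout, k):
        return cout * cin * k * k + cout

    def block(c, k):
        return 2 * (2 * c + conv(c, c, k))

    f = [cfg.init_filters * 2**i for i in range(cfg.levels)]
    k = cfg.kernel
    total = conv(cfg.in_channels, f[0], k)
    for lvl in range(cfg.levels):
        if lvl > 0:
            total += conv(f[lvl - 1], f[lvl], k)
        total += cfg.blocks_per_level[lvl] * block(f[lvl], k)
    for lvl in range(cfg.levels - 2, -1, -1):
        total += conv(f[lvl + 1], f[lvl], 1)
        total += cfg.decoder_blocks * block(f[lvl], k)
    total += conv(f[0], cfg.out_channels, 1)
    return total


class TestBuildModel:
    @pytest.mark.parametrize("cfg", [
        NetworkConfig(),
        NetworkConfig(init_filters=8, levels=2, blocks_per_level=(1, 2)),
        NetworkConfig(init_filters=4, levels=3, blocks_per_level=(1, 1, 2)),
    ])
    def test_parameter_count_matches_closed_form(self, cfg):
        model = build_model(cfg, seed=0)
        assert model.num_params() == _analytic_param_count(cfg)

    def test_deterministic_initialization(self):
        cfg = NetworkConfig(init_filters=4, levels=2, blocks_per_level=(1, 1))
        a = build_model(cfg, seed=3).state_dict()
        b = build_model(cfg, seed=3).state_dict()
        c = build_model(cfg, seed=4).state_dict()
        for key in a:
            np.testing.assert_array_equal(a[key], b[key])
        assert any(not np.array_equal(a[k], c[k]) for k in a)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(kernel=4)
        with pytest.raises(ValueError):
            NetworkConfig(levels=1, blocks_per_level=(1,))
        with pytest.raises(ValueError):
            NetworkConfig(levels=3, blocks_per_level=(1, 1))

    def test_zero_weights_predict_half_everywhere(self, tiny_net):
        state = tiny_net.state_dict()
        for key in state:
            if "running_var" not in key:
                state[key] = np.zeros_like(state[key])
        tiny_net.load_state_dict(state)
        p = tiny_net.predict(np.random.default_rng(0).random((32, 32)))
        np.testing.assert_allclose(p, 0.5, atol=1e-7)


class TestPredict:
    @pytest.mark.parametrize("size", [224, 448])
    def test_output_shape_equals_input_shape(self, tiny_net, size):
        img = np.random.default_rng(1).random((size, size))
        assert tiny_net.predict(img).shape == (size, size)

    def test_default_config_handles_standard_patch(self):
        model = build_model(NetworkConfig(init_filters=2,
                                          blocks_per_level=(1, 1, 1, 1)), seed=0)
        img = np.random.default_rng(0).random((224, 224))
        out = model.predict(img)
        assert out.shape == (224, 224)

    def test_deterministic_in_inference_mode(self, tiny_net):
        img = np.random.default_rng(2).random((64, 64))
        np.testing.assert_array_equal(tiny_net.predict(img), tiny_net.predict(img))

    def test_open_unit_interval_range(self, tiny_net):
        img = np.random.default_rng(3).random((64, 64))
        p = tiny_net.predict(img)
        assert p.min() > 0.0 and p.max() < 1.0

    def test_indivisible_size_suggests_padding(self, tiny_net):
        with pytest.raises(ValueError, match="pad"):
            tiny_net.predict(np.zeros((65, 65)))

    def test_shift_by_full_downsampling_period_shifts_interior(self):
        """Shifting the input by the total stride shifts the interior of the
        output identically (borders differ through zero padding)."""
        model = build_model(NetworkConfig(init_filters=4, levels=2,
                                          blocks_per_level=(1, 1)), seed=5,
                            dtype=np.float64)
        rng = np.random.default_rng(6)
        img = rng.random((128, 128))
        s = model.config.downsample_factor  # 2
        shifted = np.roll(img, (s, s), axis=(0, 1))
        out = model.predict(img)
        out_shifted = model.predict(shifted)
        mid = slice(40, 88)
        np.testing.assert_allclose(
            out_shifted[40 + s : 88 + s, 40 + s : 88 + s], out[mid, mid],
            atol=1e-9,
        )


class TestBackprop:
    def test_gradients_match_finite_differences(self):
        """Central-difference check on a handful of parameters of every
        layer type (float64 model, 8x8 inputs)."""
        cfg = NetworkConfig(init_filters=3, levels=2, blocks_per_level=(1, 1))
        model = build_model(cfg, seed=1, dtype=np.float64)
        rng = np.random.default_rng(0)
        x = rng.random((2, 1, 8, 8))
        y = (rng.random((2, 1, 8, 8)) > 0.6).astype(float)
        lc = LossConfig()

        def loss():
            return seg_loss(_sigmoid(model.forward(x, train=True)), y, lc)

        model.zero_grads()
        p = _sigmoid(model.forward(x, train=True))
        model.backward(seg_loss_grad(p, y, lc) * p * (1 - p))
        h = 1e-6
        checked = 0
        for name, layer, pname in model.parameters():
            arr, grad = layer.params[pname], layer.grads[pname]
            idx = tuple(rng.integers(0, s) for s in arr.shape)
            orig = arr[idx]
            arr[idx] = orig + h
            lp = loss()
            arr[idx] = orig - h
            lm = loss()
            arr[idx] = orig
            fd = (lp - lm) / (2 * h)
            assert grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-9), name
            checked += 1
        assert checked > 20

    def test_one_small_step_decreases_training_loss(self, rng):
        from cherenseg.trainer import RMSProp

        cfg = NetworkConfig(init_filters=4, levels=2, blocks_per_level=(1, 1))
        model = build_model(cfg, seed=2)
        x = rng.random((1, 1, 32, 32))
        y = (x < 0.3).astype(float)
        lc = LossConfig()
        opt = RMSProp(model, lr=1e-4)
        model.zero_grads()
        p = _sigmoid(model.forward(x, train=True))
        before = seg_loss(p, y, lc)
        model.backward(seg_loss_grad(p, y, lc) * p * (1 - p))
        opt.step()
        after = seg_loss(_sigmoid(model.forward(x, train=True)), y, lc)
        assert after < before

    def test_residual_ablation_changes_outputs(self):
        base = NetworkConfig(init_filters=4, levels=2, blocks_per_level=(1, 1))
        ablated = NetworkConfig(init_filters=4, levels=2,
                                blocks_per_level=(1, 1), use_residual=False)
        img = np.random.default_rng(7).random((32, 32))
        with_skip = build_model(base, seed=0).predict(img)
        without = build_model(ablated, seed=0).predict(img)
        assert np.abs(with_skip - without).max() > 1e-4


class TestBinarize:
    def test_all_half_map_thresholds_to_zero(self):
        assert binarize(np.full((4, 4), 0.5), 0.5).sum() == 0  # strict >

    def test_binary_map_is_fixed_point(self, rng):
        m = (rng.random((8, 8)) > 0.5).astype(float)
        np.testing.assert_array_equal(binarize(m), m.astype(np.uint8))

    def test_matches_per_pixel_oracle(self, rng):
        prob = rng.random((16, 16))
        out = binarize(prob, 0.37)
        for i in range(16):
            for j in range(16):
                assert out[i, j] == (1 if prob[i, j] > 0.37 else 0)


class TestCheckpoint:
    def test_save_load_round_trip(self, tiny_net, tmp_path):
        tiny_net.provenance = {"stage": "pretrain", "epoch": 3, "val_loss": 0.2}
        path = tmp_path / "model.ckpt"
        tiny_net.save(str(path))
        back = SegModel.load(str(path))
        img = np.random.default_rng(0).random((64, 64))
        np.testing.assert_array_equal(back.predict(img), tiny_net.predict(img))
        assert back.provenance["epoch"] == 3
        assert back.config == tiny_net.config
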