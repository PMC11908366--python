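"""Denoiser network: contracts, parameter counts, conditioning, capacity."""

import numpy as np
import pytest

import shiftsr as s
from shiftsr.nn.autodiff import Tensor
from shiftsr.nn.optim import RAdam
from shiftsr.nn.perceptual import RandomFeaturePerceptual
from shiftsr.nn.unet import ShiftUNet, count_parameters, load_checkpoint, save_checkpoint


def attention_param_total(channels: int) -> int:
    """Analytic parameter count of one windowed-attention block:
    GroupNorm (2C) + four dense maps q/k/v/proj (C^2 + C each)."""
    return 2 * channels + 4 * (channels**2 + channels)


class TestShapeContract:
    @pytest.mark.parametrize("size", [32, 64, 96])
    def test_output_shape_matches_input(self, tiny_spec, size):
        model = ShiftUNet(tiny_spec)
        x = np.random.default_rng(0).random((size, size))
        out = model.predict_x0(x, x, 3)
        assert out.shape == (size, size)

    def test_determinism(self, tiny_spec):
        model = ShiftUNet(tiny_spec)
        rng = np.random.default_rng(1)
        x_t, lr = rng.random((16, 16)), rng.random((16, 16))
        np.testing.assert_array_equal(model.predict_x0(x_t, lr, 5),
                                      model.predict_x0(x_t, lr, 5))

    def test_incompatible_shape_names_dimension(self, tiny_spec):
        model = ShiftUNet(tiny_spec)
        x = np.zeros((31, 32))  # height not divisible by the downsampling factor
        with pytest.raises(ValueError, match="height"):
            model.predict_x0(x, x, 1)
        with pytest.raises(ValueError):
            model.predict_x0(np.zeros((16, 16)), np.zeros((16, 32)), 1)

    def test_window_divisibility_enforced(self):
        spec = s.DenoiserSpec(base_channels=8, depth=1, use_windowed_attention=True,
                              window_size=5, time_embed_dim=16)
        model = ShiftUNet(spec)
        with pytest.raises(ValueError, match="window"):
            model.predict_x0(np.zeros((16, 16)), np.zeros((16, 16)), 1)


class TestParameterCount:
    def test_hand_counted_minimal_spec(self):
        """depth=1, base_channels=1, no attention: every layer enumerated."""
        te = 4
        spec = s.DenoiserSpec(base_channels=1, depth=1, use_windowed_attention=False,
                              time_embed_dim=te)
        # time MLP: two dense te->te maps
        expected = 2 * (te * te + te)
        # stem: 3x3 conv 2->1 (+bias)
        expected += 9 * 2 * 1 + 1
        # encoder ResBlock(1->1): GN(1)=2, conv 3x3 1->1 = 10, temb te->1 = te+1,
        # GN(1)=2, conv 10, no skip
        resblock_11 = 2 + 10 + (te + 1) + 2 + 10
        expected += resblock_11
        # middle: two ResBlock(1->1)
        expected += 2 * resblock_11
        # decoder ResBlock(2->1): GN(2)=4, conv 3x3 2->1 = 19, temb te+1,
        # GN(1)=2, conv 10, skip 1x1 2->1 = 3
        expected += 4 + 19 + (te + 1) + 2 + 10 + 3
        # head: GN(1)=2 + 3x3 conv 1->1 = 10
        expected += 2 + 10
        assert count_parameters(spec) == expected

    def test_ablation_toggle_differs_by_attention_total(self):
        base = 8
        on = s.DenoiserSpec(base_channels=base, depth=3, use_windowed_attention=True,
                            window_size=4, time_embed_dim=16)
        off = s.DenoiserSpec(base_channels=base, depth=3, use_windowed_attention=False,
                             time_embed_dim=16)
        # attention sits at the two coarsest levels (encoder + decoder) and in
        # the bottleneck: five blocks, all at channel width 2*base
        expected_delta = 5 * attention_param_total(2 * base)
        assert count_parameters(on) - count_parameters(off) == expected_delta

    def test_conv_weights_scale_quadratically_with_width(self):
        a = count_parameters(s.DenoiserSpec(base_channels=16, depth=2,
                                            use_windowed_attention=False,
                                            time_embed_dim=16))
        b = count_parameters(s.DenoiserSpec(base_channels=32, depth=2,
                                            use_windowed_attention=False,
                                            time_embed_dim=16))
        assert 3.4 < b / a < 4.05  # conv kernels ~4x, biases/norms/temb ~2x

    def test_positive_and_matches_introspection(self, tiny_spec):
        model = ShiftUNet(tiny_spec)
        n = count_parameters(tiny_spec)
        assert n > 0
        assert n == sum(p.data.size for p in model.parameters())


def _randomize_head(model, seed=0):
    """The output conv starts at zero (identity-on-LR init); give it random
    weights so conditioning paths reach the output."""
    rng = np.random.default_rng(seed)
    w = model.out_conv.weight
    w.data = rng.normal(0, 0.1, size=w.data.shape).astype(w.data.dtype)
    return model


class TestConditioning:
    def test_time_embedding_path_is_live(self, tiny_spec):
        model = _randomize_head(ShiftUNet(tiny_spec))
        x = np.random.default_rng(2).random((16, 16))
        assert np.abs(model.predict_x0(x, x, 1) - model.predict_x0(x, x, 15)).max() > 0

    def test_lr_conditioning_is_live(self, tiny_spec):
        model = _randomize_head(ShiftUNet(tiny_spec))
        rng = np.random.default_rng(3)
        x_t, lr = rng.random((16, 16)), rng.random((16, 16))
        out1 = model.predict_x0(x_t, lr, 4)
        out2 = model.predict_x0(x_t + 0.1, lr, 4)  # noisy-state channel
        out3 = model.predict_x0(x_t, lr + 0.1, 4)  # conditioning channel
        assert np.abs(out1 - out2).max() > 0
        assert np.abs((out3 - lr) - (out1 - lr)).max() > 0  # beyond the skip

    def test_untrained_network_is_identity_on_lr(self, tiny_spec):
        # zero-initialized head + global LR skip
        model = ShiftUNet(tiny_spec)
        rng = np.random.default_rng(4)
        x_t, lr = rng.random((16, 16)), rng.random((16, 16))
        np.testing.assert_allclose(model.predict_x0(x_t, lr, 7), lr, atol=1e-6)


def test_overfit_single_pair(tiny_pairs_16, default_schedule):
    """The network can drive the composite loss below 10% of its initial
    value on one fixed (pair, timestep) within 500 steps."""
    pair = tiny_pairs_16[0]
    model = ShiftUNet(s.DenoiserSpec(base_channels=8, depth=2, window_size=4,
                                     time_embed_dim=16, seed=0))
    perc = RandomFeaturePerceptual(seed=0)
    opt = RAdam(model.parameters(), lr=3e-3)
    t = 7
    rng = np.random.default_rng(0)
    x_t = s.forward_marginal(pair, t, default_schedule, rng=rng).x
    x = np.stack([x_t, pair.lr], axis=-1)[None].astype(np.float32)
    hr = pair.hr[None, :, :, None].astype(np.float32)
    ts = np.array([t])

    losses = []
    for _ in range(500):
        pred = model.forward(Tensor(x), ts)
        diff = pred - Tensor(hr)
        loss = (diff * diff).mean() * 10.0 + perc.distance_t(pred, Tensor(hr))
        losses.append(loss.item())
        opt.zero_grad()
        loss.backward()
        opt.step()
        if losses[-1] < 0.1 * losses[0]:
            break
    assert losses[-1] < 0.1 * losses[0]


def test_checkpoint_round_trip(tiny_spec, tmp_path, default_schedule):
    model = ShiftUNet(tiny_spec)
    # make weights non-trivial
    for p in model.parameters():
        p.data = p.data + 0.01
    path = tmp_path / "ckpt.npz"
    save_checkpoint(path, model, default_schedule.fingerprint(), extra={"step": 3})
    loaded, meta = load_checkpoint(path)
    assert meta["schedule_fingerprint"] == default_schedule.fingerprint()
    assert meta["extra"]["step"] == 3
    assert loaded.spec == model.spec
    x = np.random.default_rng(5).random((16, 16))
    np.testing.assert_array_equal(loaded.predict_x0(x, x, 2), model.predict_x0(x, x, 2))
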