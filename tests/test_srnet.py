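import numpy as np
import pytest

from srpomb import _nn as nn
from srpomb import iqa, losses, srnet


class TestAutogradCore:
    def test_conv_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        x = nn.Tensor(rng.uniform(0, 1, (2, 1, 8, 8)))
        conv = nn.Conv2d(1, 2, 3, rng)
        target = rng.uniform(0, 1, (2, 2, 8, 8))

        def loss():
            return nn.charbonnier_loss(conv(x), target, 1e-3)

        loss().backward()
        g = conv.weight.grad.copy()
        eps = 1e-6
        for idx in [(0, 0, 0, 0), (1, 0, 2, 1)]:
            w0 = conv.weight.data[idx]
            conv.weight.data[idx] = w0 + eps
            up = loss().data
            conv.weight.data[idx] = w0 - eps
            down = loss().data
            conv.weight.data[idx] = w0
            assert g[idx] == pytest.approx((up - down) / (2 * eps), rel=1e-4)

    def test_fd_loss_matches_numpy_twin_and_gradient(self):
        rng = np.random.default_rng(1)
        x = nn.Tensor(rng.uniform(0, 1, (2, 1, 8, 8)))
        t = rng.uniform(0, 1, (2, 1, 8, 8))
        val = nn.fd_loss(x, t)
        ref = losses.frequency_domain_loss(x.data[:, 0], t[:, 0])
        assert float(val.data) == pytest.approx(ref, rel=1e-12)
        # undamped backward agrees with finite differences
        x2 = nn.Tensor(x.data.copy())
        nn.fd_loss(x2, t, rel_damp=0.0).backward()
        eps = 1e-7
        for idx in [(0, 0, 3, 3), (1, 0, 0, 5)]:
            base = x.data.copy()
            base[idx] += eps
            up = losses.frequency_domain_loss(base[:, 0], t[:, 0])
            base[idx] -= 2 * eps
            down = losses.frequency_domain_loss(base[:, 0], t[:, 0])
            assert x2.grad[idx] == pytest.approx((up - down) / (2 * eps),
                                                 rel=1e-3, abs=1e-8)

    def test_grouped_conv_shapes(self):
        rng = np.random.default_rng(2)
        x = nn.Tensor(rng.uniform(0, 1, (1, 4, 8, 8)))
        conv = nn.Conv2d(4, 4, 3, rng, groups=4)   # depthwise
        assert conv(x).shape == (1, 4, 8, 8)
        assert conv.weight.data.shape == (4, 1, 3, 3)


class TestUpsampling:
    def test_nearest_conv_shape_contract(self):
        f = np.zeros((3, 16, 16))
        out = srnet.nearest_conv_upsample(f, scale=4, seed=0)
        assert out.shape == (3, 64, 64)

    def test_double_scale2_matches_scale4_dims(self):
        f = np.zeros((1, 8, 8))
        twice = srnet.nearest_conv_upsample(
            srnet.nearest_conv_upsample(f, 2, seed=0), 2, seed=0)
        once = srnet.nearest_conv_upsample(f, 4, seed=0)
        assert twice.shape == once.shape == (1, 32, 32)

    def test_nearest_stage_preserves_constants(self):
        const = np.full((1, 1, 4, 4), 0.7)
        up = nn.nearest_up(nn.Tensor(const), 2).data
        assert np.all(up == 0.7)
        assert up.shape == (1, 1, 8, 8)

    def test_unsupported_scale_rejected(self):
        with pytest.raises(ValueError):
            srnet.nearest_conv_upsample(np.zeros((1, 8, 8)), scale=3)

    def test_pixel_shuffle_generator_shape(self):
        gen = srnet.build_generator(
            srnet.GeneratorSpec(upsampler="pixel_shuffle", scale=2), seed=0)
        out = gen(nn.Tensor(np.zeros((1, 1, 16, 16))))
        assert out.shape == (1, 1, 32, 32)


class TestCritics:
    @pytest.mark.parametrize("family", sorted(srnet.CRITIC_REGISTRY))
    def test_every_family_yields_finite_scores(self, family):
        spec = srnet.CriticSpec(family=family, features=128, width=8,
                                depth=2, kernel=3, patch=4)
        critic = srnet.build_critic(spec, seed=0)
        scores = critic.scores(np.zeros((4, 1, 16, 16)))
        assert scores.shape == (4,)
        assert np.all(np.isfinite(scores))

    def test_unet_capacity_monotone_in_features(self):
        small = srnet.build_critic(srnet.CriticSpec("unet_style", features=128))
        big = srnet.build_critic(srnet.CriticSpec("unet_style", features=256))
        assert big.param_count() > small.param_count()

    def test_table_convmixer_1536_instantiates(self):
        spec = srnet.CriticSpec(family="convmixer_style", width=1536,
                                depth=20, kernel=9, patch=7)
        critic = srnet.build_critic(spec, seed=0)
        assert critic.param_count() > 10 ** 6

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            srnet.CriticSpec(family="mlp_style")

    def test_off_grid_features_rejected(self):
        with pytest.raises(ValueError):
            srnet.CriticSpec(family="vgg_style", features=64)


class TestSchedule:
    def test_cosine_endpoints_exact(self):
        cfg = srnet.TrainConfig(iterations=100, lr_start=1e-4, lr_min=1e-7)
        assert srnet.cosine_lr(cfg, 0) == 1e-4
        assert srnet.cosine_lr(cfg, 99) == pytest.approx(1e-7, abs=1e-20)

    def test_monotone_decreasing(self):
        cfg = srnet.TrainConfig(iterations=50)
        lrs = [srnet.cosine_lr(cfg, i) for i in range(50)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            srnet.TrainConfig(lr_start=1e-7, lr_min=1e-4)


@pytest.fixture(scope="module")
def short_run():
    data = srnet.make_sr_training_set(4, 32, 2, seed=11)
    cfg = srnet.toy_train_config(iterations=20, seed=5)
    ckpt, hist = srnet.train_adversarial(
        srnet.GeneratorSpec(scale=2),
        srnet.CriticSpec(family="vgg_style", features=128), cfg, data)
    return data, cfg, ckpt, hist


class TestTrainingAndInference:
    def test_all_logged_losses_finite(self, short_run):
        _, _, _, hist = short_run
        for row in hist:
            assert all(np.isfinite(v) for v in row.values())

    def test_loss_breakdown_total_is_weighted_sum(self, short_run):
        _, _, _, hist = short_run
        for row in hist[:5]:
            parts = (row["charbonnier"] + row["frequency"]
                     + row["adversarial"] + row["perceptual"])
            assert row["total"] == pytest.approx(parts, rel=1e-12)

    def test_same_seed_reproduces_identical_curves(self, short_run):
        data, cfg, _, hist = short_run
        _, hist2 = srnet.train_adversarial(
            srnet.GeneratorSpec(scale=2),
            srnet.CriticSpec(family="vgg_style", features=128), cfg, data)
        assert hist == hist2

    def test_checkpoint_round_trip_bit_identical(self, short_run, tmp_path):
        data, _, ckpt, _ = short_run
        lr = data[0][1]
        before = srnet.super_resolve(ckpt, lr)
        path = tmp_path / "ck.npz"
        ckpt.save(path)
        after = srnet.super_resolve(srnet.Checkpoint.load(path), lr)
        np.testing.assert_array_equal(before, after)

    def test_super_resolve_shape_and_determinism(self, short_run):
        _, _, ckpt, _ = short_run
        lr = np.random.default_rng(0).uniform(0, 1, (16, 16))
        a = srnet.super_resolve(ckpt, lr)
        b = srnet.super_resolve(ckpt, lr)
        assert a.shape == (32, 32)
        np.testing.assert_array_equal(a, b)
        assert a.min() >= 0 and a.max() <= 1

    def test_untrained_generator_equals_nearest_baseline(self):
        gen = srnet.build_generator(srnet.GeneratorSpec(scale=2), seed=3)
        lr = np.random.default_rng(1).uniform(0, 1, (1, 1, 8, 8))
        out = gen(nn.Tensor(lr)).data
        np.testing.assert_allclose(out, srnet.nearest_upsample(lr, 2),
                                   atol=1e-12)

    def test_scale4_checkpoint_produces_1024_from_256(self):
        gen_spec = srnet.GeneratorSpec(scale=4, width=4, n_blocks=1)
        gen = srnet.build_generator(gen_spec, seed=0)
        ckpt = srnet.Checkpoint(gen_spec=gen_spec, cfg=srnet.TrainConfig(),
                                arrays=gen.state_arrays(), seed=0)
        out = srnet.super_resolve(ckpt, np.zeros((256, 256)))
        assert out.shape == (1024, 1024)
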