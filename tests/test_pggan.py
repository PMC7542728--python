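import numpy as np
import pytest

from cardiosynth.errors import ConfigError, ShapeMismatchError, StageError
from cardiosynth.nn import (fade_in_blend, minibatch_stddev_channel,
                            pixelwise_feature_norm)
from cardiosynth.pggan import (GANConfig, Generator, GeneratorModel,
                               GrowthSchedule, GrowthState,
                               build_discriminator_spec, build_generator_spec,
                               critic_losses, default_batch_schedule,
                               sample_synthetic)

SMALL = dict(max_resolution=16, filters_per_stage=(8, 6, 4))


class TestConfig:
    def test_default_configuration(self):
        cfg = GANConfig()
        assert cfg.latent_dim == 64
        assert cfg.leakiness == 0.2
        assert cfg.output_channels == 1
        assert cfg.filters_per_stage == (48, 32, 24, 16, 16, 16, 16)
        assert cfg.stage_resolutions == (4, 8, 16, 32, 64, 128, 256)

    def test_filter_count_must_match_stages(self):
        with pytest.raises(ConfigError):
            GANConfig(max_resolution=64, filters_per_stage=(8, 8))

    def test_batch_schedule_non_increasing_enforced(self):
        with pytest.raises(ConfigError):
            GrowthSchedule(steps_per_stage=(5, 5), batch_per_stage=(16, 32))
        sizes = default_batch_schedule(7)
        assert sizes[0] == 64 and sizes[-1] == 16
        assert all(b >= c for b, c in zip(sizes, sizes[1:]))


class TestArchitectureSpecs:
    def test_generator_stage0_outputs_4x4(self):
        spec = build_generator_spec(GANConfig(), 0)
        assert spec.resolution == 4
        assert len(spec.blocks) == 1
        assert spec.tail[-1].kind == "to_image"
        assert spec.tail[-1].out_channels == 1

    def test_generator_stage6_outputs_256(self):
        spec = build_generator_spec(GANConfig(), 6)
        assert spec.resolution == 256
        assert len(spec.blocks) == 7

    def test_consecutive_stages_differ_by_one_block(self):
        cfg = GANConfig()
        for k in range(6):
            a = build_generator_spec(cfg, k)
            b = build_generator_spec(cfg, k + 1)
            assert len(b.blocks) == len(a.blocks) + 1
            assert b.blocks[:len(a.blocks)] == a.blocks

    def test_generator_blocks_contain_pixelnorm(self):
        spec = build_generator_spec(GANConfig(), 3)
        for block in spec.blocks:
            assert any(d.kind == "pixelnorm" for d in block)

    def test_discriminator_stage0_consumes_4x4(self):
        spec = build_discriminator_spec(GANConfig(), 0)
        assert spec.resolution == 4
        assert spec.head[0].kind == "from_image"
        assert spec.head[0].in_channels == 1
        assert spec.tail[-1].out_channels == 1

    def test_discriminator_mirrors_generator_channels(self):
        cfg = GANConfig()
        g = build_generator_spec(cfg, 6)
        d = build_discriminator_spec(cfg, 6)
        g_convs = [x.out_channels for b in g.blocks
                   for x in b if x.kind.startswith("conv")]
        d_convs = [x.out_channels for b in d.blocks
                   for x in b if x.kind.startswith("conv")]
        assert d.head[0].out_channels == g_convs[-1]
        # reversed filter schedule appears along the critic's blocks
        assert [b[-2].out_channels for b in d.blocks[:-1]] == \
            list(cfg.filters_per_stage[-2::-1])

    def test_exactly_one_minibatch_stddev_per_stage(self):
        for stage in range(7):
            spec = build_discriminator_spec(GANConfig(), stage)
            kinds = [x.kind for x in spec.all_descriptors()]
            assert kinds.count("minibatch_stddev") == 1

    def test_stage_out_of_range(self):
        with pytest.raises(StageError):
            build_generator_spec(GANConfig(), 7)
        with pytest.raises(StageError):
            build_discriminator_spec(GANConfig(), -1)


class TestOperators:
    def test_pixelnorm_hand_case(self):
        x = np.array([3.0, 4.0]).reshape(1, 2, 1, 1)
        y = pixelwise_feature_norm(x, 1e-12)
        # mean square = 12.5, scale = 1/sqrt(12.5)
        assert y.ravel() == pytest.approx([0.848528, 1.131371], abs=1e-5)

    def test_pixelnorm_unit_mean_square(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 8, 4, 4))
        y = pixelwise_feature_norm(x, 1e-12)
        assert np.allclose((y ** 2).mean(axis=1), 1.0, atol=1e-6)

    def test_pixelnorm_zero_input(self):
        y = pixelwise_feature_norm(np.zeros((1, 4, 2, 2)), 1e-8)
        assert np.all(y == 0)

    def test_pixelnorm_idempotent_up_to_epsilon(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(1, 6, 3, 3))
        once = pixelwise_feature_norm(x, 1e-12)
        twice = pixelwise_feature_norm(once, 1e-12)
        assert np.allclose(once, twice, atol=1e-9)

    def test_minibatch_stddev_duplicated_batch_is_zero(self):
        x = np.tile(np.random.default_rng(2).normal(size=(1, 3, 4, 4)),
                    (5, 1, 1, 1))
        out = minibatch_stddev_channel(x, epsilon=0.0)
        assert out.shape == (5, 4, 4, 4)
        assert np.allclose(out[:, -1], 0.0)

    def test_minibatch_stddev_hand_case(self):
        x = np.array([0.0, 2.0]).reshape(2, 1, 1, 1)
        out = minibatch_stddev_channel(x, epsilon=0.0)
        assert np.allclose(out[:, -1], 1.0)       # population sd of {0, 2}

    def test_fade_in_endpoints_and_midpoint(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(2, 1, 8, 8)).astype(np.float32)
        b = rng.normal(size=(2, 1, 8, 8)).astype(np.float32)
        assert np.array_equal(fade_in_blend(a, b, 0.0), a)
        assert np.array_equal(fade_in_blend(a, b, 1.0), b)
        mid = fade_in_blend(np.zeros_like(a), np.ones_like(a), 0.5)
        assert np.allclose(mid, 0.5)

    def test_fade_in_shape_mismatch(self):
        with pytest.raises(ShapeMismatchError):
            fade_in_blend(np.zeros((1, 1, 4, 4)), np.zeros((1, 1, 8, 8)), 0.5)

    def test_critic_loss_hand_case(self):
        c, g = critic_losses([1.0, 1.0], [0.0, 0.0], 0.0, 0.0)
        assert (c, g) == (-1.0, 0.0)

    def test_critic_loss_symmetry_and_antisymmetry(self):
        rng = np.random.default_rng(4)
        r, f = rng.normal(size=5), rng.normal(size=5)
        assert critic_losses(r, r)[0] == pytest.approx(0.0)
        assert critic_losses(r, f)[0] == pytest.approx(-critic_losses(f, r)[0])

    def test_gradient_penalty_weight_enters_linearly(self):
        c0, _ = critic_losses([1.0], [0.0], gradient_penalty=0.7, gp_weight=0.0)
        c1, _ = critic_losses([1.0], [0.0], gradient_penalty=0.7, gp_weight=10.0)
        assert c1 - c0 == pytest.approx(7.0)


class TestGeneratorModel:
    def test_alpha_zero_reproduces_upscaled_coarse_path(self):
        cfg = GANConfig(**SMALL)
        gen = Generator(cfg, np.random.default_rng(0))
        z = np.random.default_rng(1).standard_normal((3, cfg.latent_dim))
        coarse = gen.forward(z.astype(np.float32), 1, 1.0)
        up = coarse.repeat(2, axis=2).repeat(2, axis=3)
        blended = gen.forward(z.astype(np.float32), 2, 0.0)
        assert np.allclose(blended, up, atol=1e-6)

    def test_sampling_deterministic_and_shaped(self):
        cfg = GANConfig(**SMALL)
        gen = Generator(cfg, np.random.default_rng(0))
        model = GeneratorModel(gen, cfg, GrowthState(2, 1.0, 0))
        a = sample_synthetic(model, 5, rng_seed=9)
        b = sample_synthetic(model, 5, rng_seed=9)
        assert len(a) == 5
        assert all(f.pixels.shape == (16, 16) for f in a)
        assert all(np.array_equal(x.pixels, y.pixels) for x, y in zip(a, b))
        c = sample_synthetic(model, 5, rng_seed=10)
        assert any(not np.array_equal(x.pixels, y.pixels)
                   for x, y in zip(a, c))

    def test_save_load_roundtrip(self, tmp_path):
        cfg = GANConfig(**SMALL)
        gen = Generator(cfg, np.random.default_rng(0))
        model = GeneratorModel(gen, cfg, GrowthState(2, 1.0, 0))
        path = tmp_path / "gen.npz"
        model.save(path)
        loaded = GeneratorModel.load(path)
        a = sample_synthetic(model, 3, 1)
        b = sample_synthetic(loaded, 3, 1)
        assert all(np.array_equal(x.pixels, y.pixels) for x, y in zip(a, b))
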