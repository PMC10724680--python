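"""Network architectures: shapes, masking, receptive field, MAD-IN, gradients."""

import numpy as np
import pytest

from cycleharm import (DiscriminatorSpec, GeneratorSpec, Volume,
                       build_discriminator, build_generator, gradient_footprint,
                       mad_instance_norm, masked_generate, receptive_field)
from cycleharm import _ad as ad
from cycleharm.nets import score_map_shape


class TestGenerator:
    def test_output_shape_matches_input(self):
        gen = build_generator(GeneratorSpec(depth=2, base_channels=4), seed=0)
        x = np.random.default_rng(0).normal(size=(32, 32, 32))
        assert gen.predict(x).shape == (32, 32, 32)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_output_nonnegative_for_arbitrary_weights(self, seed):
        # activation property, not a training property
        gen = build_generator(GeneratorSpec(depth=2, base_channels=4), seed=seed)
        for p in gen.parameters():          # exaggerate the weights
            p.data = p.data * 50.0
        x = np.random.default_rng(seed).normal(size=(32, 32, 32))
        assert gen.predict(x).min() >= 0.0

    def test_indivisible_dims_rejected(self):
        gen = build_generator(GeneratorSpec(depth=3, base_channels=4), seed=0)
        with pytest.raises(ValueError):
            gen.predict(np.zeros((36, 36, 36)))

    def test_parameter_count_matches_convolution_arithmetic(self):
        spec = GeneratorSpec(depth=2, base_channels=8, kernel=4)
        gen = build_generator(spec, seed=0)
        k3 = 4 ** 3
        expected = 0
        expected += 8 * 1 * k3 + 8                 # down0 conv
        expected += 16 * 8 * k3 + 16 + 16 + 16     # down1 conv + IN gain/offset
        expected += 16 * 8 * k3 + 8 + 8 + 8        # up0 tconv (16->8) + IN
        expected += 16 * 1 * k3 + 1                # up1 tconv on concat(8+8)->1
        assert gen.parameter_count() == expected

    def test_masked_generate_support_and_identity(self, small_phantom):
        gen = build_generator(GeneratorSpec(depth=2, base_channels=4), seed=0)
        out = masked_generate(gen, small_phantom.volume)
        assert (out.data[~small_phantom.volume.mask] == 0).all()
        # missing mask rejected
        bad = Volume(small_phantom.volume.data,
                     np.zeros_like(small_phantom.volume.mask))
        with pytest.raises(ValueError):
            masked_generate(gen, bad)


class TestDiscriminator:
    def test_patch_score_grid_not_scalar(self):
        disc = build_discriminator(DiscriminatorSpec(), seed=0)
        y = disc(np.zeros((1, 1, 48, 48, 48), np.float32))
        assert y.data.shape == (1, 1, 6, 6, 6)

    @pytest.mark.parametrize("size", [32, 48, 64])
    def test_score_map_follows_conv_recurrence(self, size):
        spec = DiscriminatorSpec()
        disc = build_discriminator(spec, seed=0)
        y = disc(np.zeros((1, 1, size, size, size), np.float32))
        assert y.data.shape[2:] == score_map_shape(spec, size)

    def test_stride_two_stages_halve_dims(self):
        # 48 -> 24 -> 12 -> 6 through the three stride-2 stages, then the
        # stride-1 output stage keeps 6
        spec = DiscriminatorSpec()
        assert all(s == 2 for _k, s, _c in spec.layers[:-1])
        assert spec.layers[-1][1] == 1
        assert score_map_shape(spec, 48) == (6, 6, 6)

    def test_final_stage_single_channel_enforced(self):
        with pytest.raises(ValueError):
            DiscriminatorSpec(layers=((4, 2, 8), (3, 1, 4)))


class TestReceptiveField:
    @pytest.mark.parametrize("layers,expected", [
        (((4, 2, 8), (4, 2, 16), (4, 2, 32), (3, 1, 1)), 38),
        (((3, 1, 1),), 3),
        (((4, 2, 4), (4, 2, 1)), 10),
    ])
    def test_analytic_recurrence(self, layers, expected):
        assert receptive_field(DiscriminatorSpec(layers=layers)) == expected

    @pytest.mark.parametrize("layers,size", [
        (((4, 2, 4), (4, 2, 1)), 32),
        (((4, 2, 4), (4, 2, 8), (4, 2, 8), (3, 1, 1)), 64),
    ])
    def test_gradient_footprint_matches_analytic(self, layers, size):
        spec = DiscriminatorSpec(layers=layers)
        rf = receptive_field(spec)
        assert gradient_footprint(spec, input_size=size, seed=0) == (rf, rf, rf)


class TestMadInstanceNorm:
    def test_constant_channel_maps_to_offset(self):
        x = np.full((2, 6, 6, 6), 3.7)
        y = mad_instance_norm(x, gain=2.0, offset=0.5)
        np.testing.assert_allclose(y, 0.5, atol=1e-3)

    def test_shift_invariance(self, rng):
        x = rng.normal(size=(3, 8, 8, 8))
        np.testing.assert_allclose(mad_instance_norm(x),
                                   mad_instance_norm(x + 11.0), atol=1e-6)

    def test_gaussian_mad_ratio(self, rng):
        # E|x - mu| = sigma * sqrt(2/pi); after normalization the MAD is ~1
        x = rng.normal(5.0, 2.0, size=(1, 40, 40, 40))
        y = mad_instance_norm(x)
        mad_y = np.abs(y - y.mean()).mean()
        assert mad_y == pytest.approx(1.0, rel=0.01)
        # and the sd/mad ratio of the input matches the Gaussian constant
        mad_x = np.abs(x - x.mean()).mean()
        assert x.std() / mad_x == pytest.approx(np.sqrt(np.pi / 2.0), rel=0.01)

    def test_rescale_flag_matches_sd_normalization(self, rng):
        x = rng.normal(size=(1, 32, 32, 32))
        y = mad_instance_norm(x, rescale=True)
        assert y.std() == pytest.approx(1.0, rel=0.02)


class TestAutodiffEngine:
    """Gradients of every op check against central finite differences."""

    def _check(self, make_loss, params, rng, eps=1e-3, tol=2e-2):
        for p in params:
            p.grad = None
        make_loss().backward()
        grads = [p.grad.copy() for p in params]
        for p, g in zip(params, grads):
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in p.data.shape)
                orig = p.data[idx]
                p.data[idx] = orig + eps
                lp = make_loss().item()
                p.data[idx] = orig - eps
                lm = make_loss().item()
                p.data[idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert abs(fd - g[idx]) <= tol * max(1.0, abs(fd))

    def test_conv3d_gradients(self, rng):
        x = ad.Tensor(rng.normal(size=(2, 3, 8, 8, 8)).astype(np.float32), requires_grad=True)
        w = ad.Tensor((rng.normal(size=(4, 3, 4, 4, 4)) * 0.1).astype(np.float32), requires_grad=True)
        b = ad.Tensor(np.zeros(4, np.float32), requires_grad=True)
        self._check(lambda: ad.mean_(ad.square(ad.conv3d(x, w, b, 2, 1))), [x, w, b], rng)

    def test_conv_transpose3d_gradients(self, rng):
        x = ad.Tensor(rng.normal(size=(1, 4, 5, 5, 5)).astype(np.float32), requires_grad=True)
        w = ad.Tensor((rng.normal(size=(4, 2, 4, 4, 4)) * 0.1).astype(np.float32), requires_grad=True)
        b = ad.Tensor(np.zeros(2, np.float32), requires_grad=True)
        y = ad.conv_transpose3d(x, w, b, 2, 1)
        assert y.data.shape == (1, 2, 10, 10, 10)
        self._check(lambda: ad.mean_(ad.square(ad.conv_transpose3d(x, w, b, 2, 1))),
                    [x, w, b], rng)

    def test_mad_instance_norm_gradients(self, rng):
        x = ad.Tensor(rng.normal(size=(2, 3, 6, 6, 6)).astype(np.float32), requires_grad=True)
        g = ad.Tensor(np.full(3, 1.3, np.float32), requires_grad=True)
        o = ad.Tensor(np.full(3, 0.2, np.float32), requires_grad=True)
        self._check(lambda: ad.mean_(ad.square(ad.mad_instance_norm(x, g, o))),
                    [x, g, o], rng)

    def test_elementwise_chain_gradients(self, rng):
        x = ad.Tensor(rng.normal(size=(1, 2, 6, 6, 6)).astype(np.float32), requires_grad=True)

        def chain():
            a = ad.leaky_relu(x, 0.2)
            b = ad.clamp_min(x)
            c = ad.concat_channels(a, b)
            return ad.mean_(ad.abs_(ad.sub(c, ad.Tensor(np.float32(0.3)))))
        self._check(chain, [x], rng)
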