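"""Network building blocks: attention gate, context aggregation, wavelet
convolution, and the assembled model."""

import numpy as np
import pytest

from cryopick import nn
from cryopick.losses import LossWeights, total_loss_t
from cryopick.mfunet import (ContextAggregation, GlobalLocalECA, MFUNet,
                             ModelConfig, WTConvBlock, dwt2, eca_kernel_size,
                             idwt2, load_checkpoint, save_checkpoint,
                             wavelet_kernels)
from cryopick.nn import tensor as T


class TestECA:
    def test_kernel_size_rule(self):
        # |log2(64)/2 + 1/2| = 3.5: tie between 3 and 5 breaks downward
        assert eca_kernel_size(64, gamma=2.0, b=1.0) == 3
        assert eca_kernel_size(2, gamma=2.0, b=1.0) == 1
        assert eca_kernel_size(256, gamma=2.0, b=1.0) == 5  # |4.5| -> 5 vs 3: 4.5-3=1.5, 5-4.5=0.5

    def test_zero_input_gives_zero_output(self, rng):
        eca = GlobalLocalECA(8, rng)
        out = eca(nn.Tensor(np.zeros((2, 8, 12, 12), np.float32)))
        assert np.allclose(out.data, 0.0)

    def test_channel_weights_strictly_inside_unit_interval(self, rng):
        eca = GlobalLocalECA(16, rng)
        x = nn.Tensor(rng.standard_normal((2, 16, 8, 8)).astype(np.float32))
        w = eca.channel_weights(x).data
        assert np.all(w > 0.0) and np.all(w < 1.0)

    def test_shape_preserved(self, rng):
        eca = GlobalLocalECA(8, rng)
        x = nn.Tensor(rng.standard_normal((1, 8, 10, 14)).astype(np.float32))
        assert eca(x).shape == (1, 8, 10, 14)


class TestContextAggregation:
    def test_spatial_shape_preserved(self, rng):
        ca = ContextAggregation(8, rng)
        x = nn.Tensor(rng.standard_normal((2, 8, 9, 11)).astype(np.float32))
        assert ca(x).shape == (2, 8, 9, 11)

    def test_exactly_four_branches(self, rng):
        ca = ContextAggregation(8, rng, dilations=(1, 3, 5))
        assert len(ca.branches) + 1 == 4
        assert ca.fuse.weight.shape[1] == 4 * 8

    def test_constant_input_constant_output_bias_free(self, rng):
        # away from the zero-padded border, every branch preserves constants
        ca = ContextAggregation(4, rng)
        for conv in ca.branches + [ca.gap_conv, ca.fuse]:
            conv.bias.data = np.zeros_like(conv.bias.data)
        x = nn.Tensor(np.full((1, 4, 24, 24), 1.5, dtype=np.float32))
        interior = ca(x).data[..., 5:-5, 5:-5]
        assert np.allclose(interior, interior[..., :1, :1], atol=1e-5)

    def test_small_spatial_dims_rejected(self, rng):
        ca = ContextAggregation(4, rng)
        with pytest.raises(ValueError):
            ca(nn.Tensor(np.zeros((1, 4, 4, 4), np.float32)))


class TestWaveletTransform:
    def test_haar_constant_image_closed_form(self):
        kernels, flen = wavelet_kernels("haar")
        c = nn.Tensor(np.full((1, 1, 8, 8), 3.0, dtype=np.float32))
        d = dwt2(c, kernels, flen).data
        assert np.allclose(d[0, 0], 6.0, atol=1e-5)  # LL of constant c -> 2c
        assert np.abs(d[0, 1:]).max() < 1e-5  # LH = HL = HH = 0

    @pytest.mark.parametrize("family", ["haar", "db2"])
    def test_round_trip_perfect_reconstruction(self, rng, family):
        kernels, flen = wavelet_kernels(family)
        x = rng.standard_normal((2, 3, 32, 32)).astype(np.float64)
        d = dwt2(nn.Tensor(x), kernels, flen)
        y = idwt2(d, kernels, flen, (32, 32))
        assert np.abs(y.data - x).max() <= 1e-6

    def test_round_trip_on_50_random_images(self, rng):
        kernels, flen = wavelet_kernels("haar")
        x = rng.standard_normal((50, 1, 64, 64)).astype(np.float64)
        d = dwt2(nn.Tensor(x), kernels, flen)
        y = idwt2(d, kernels, flen, (64, 64))
        assert np.abs(y.data - x).max() <= 1e-6

    def test_matches_pywt_oracle_up_to_orthogonality(self, rng):
        """Energy is preserved exactly (Parseval), like pywt's DWT."""
        import pywt

        kernels, flen = wavelet_kernels("haar")
        x = rng.standard_normal((1, 1, 16, 16)).astype(np.float64)
        d = dwt2(nn.Tensor(x), kernels, flen).data
        assert float((d**2).sum()) == pytest.approx(float((x**2).sum()),
                                                    rel=1e-10)
        # subband energies agree with the pywt decomposition
        ll, (lh, hl, hh) = pywt.dwt2(x[0, 0], "haar")
        ours = sorted(float((d[0, s] ** 2).sum()) for s in range(4))
        theirs = sorted(float((b**2).sum()) for b in (ll, lh, hl, hh))
        assert ours == pytest.approx(theirs, rel=1e-10)


class TestWTConvBlock:
    def test_identity_configuration_reproduces_input(self, rng):
        blk = WTConvBlock(4, rng, wt_levels=2)
        blk.set_identity()
        x = rng.standard_normal((1, 4, 24, 24)).astype(np.float32)
        y = blk(nn.Tensor(x)).data
        assert np.abs(y - x).max() / np.abs(x).max() <= 1e-5

    def test_odd_input_padded_and_cropped(self, rng):
        blk = WTConvBlock(2, rng)
        x = rng.standard_normal((1, 2, 13, 17)).astype(np.float32)
        assert blk(nn.Tensor(x)).shape == (1, 2, 13, 17)


class TestMFUNet:
    @pytest.fixture(scope="class")
    def tiny(self):
        return MFUNet(ModelConfig(input_size=160, seed=3))

    def test_output_shapes_and_aux_count(self, tiny, rng):
        out = tiny.predict(rng.random((160, 160)).astype(np.float32))
        assert out.prob.shape == (160, 160)
        assert len(out.aux_probs) == 3
        assert all(a.shape == (160, 160) for a in out.aux_probs)
        assert np.allclose(out.prob, 1 / (1 + np.exp(-out.logits)), atol=1e-6)

    def test_zero_weights_give_half_probability(self, rng):
        net = MFUNet(ModelConfig(input_size=160, seed=0))
        for p in net.parameters():
            p.data = np.zeros_like(p.data)
        out = net.predict(rng.random((160, 160)).astype(np.float32))
        assert np.allclose(out.prob, 0.5, atol=1e-7)

    def test_forward_deterministic_under_fixed_weights(self, tiny, rng):
        img = rng.random((160, 160)).astype(np.float32)
        a = tiny.predict(img).prob
        b = tiny.predict(img).prob
        assert np.array_equal(a, b)

    def test_non_square_or_indivisible_input_rejected(self, tiny):
        with pytest.raises(ValueError):
            tiny.forward(nn.Tensor(np.zeros((1, 1, 160, 192), np.float32)))
        with pytest.raises(ValueError):
            tiny.forward(nn.Tensor(np.zeros((1, 1, 100, 100), np.float32)))

    @pytest.mark.parametrize("encoder", ["tiny_cnn", "pvt_like"])
    def test_loss_gradient_finite_for_every_parameter(self, rng, encoder):
        net = MFUNet(ModelConfig(encoder=encoder, input_size=160, seed=1))
        x = nn.Tensor(rng.random((1, 1, 160, 160)).astype(np.float32))
        y = nn.Tensor((rng.random((1, 1, 160, 160)) > 0.7).astype(np.float32))
        logits, aux = net.forward(x)
        loss, _ = total_loss_t(
            T.sigmoid(logits), [T.sigmoid(a) for a in aux], y, LossWeights()
        )
        loss.backward()
        params = net.parameters()
        assert len(params) > 10
        for p in params:
            assert p.grad is not None
            assert np.all(np.isfinite(p.grad))

    def test_checkpoint_round_trip(self, tiny, tmp_path, rng):
        path = tmp_path / "ck.npz"
        save_checkpoint(tiny, path)
        back = load_checkpoint(path)
        img = rng.random((160, 160)).astype(np.float32)
        assert np.array_equal(back.predict(img).prob, tiny.predict(img).prob)
        assert back.cfg == tiny.cfg

    def test_config_invariants(self):
        assert ModelConfig().dilations == (1, 3, 5)
        assert ModelConfig().input_size == 1024
        with pytest.raises(ValueError):
            ModelConfig(input_size=100)
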