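"""FiLM/CBN closed forms, fusion pipeline oracle, unit-norm contract,
prompt sensitivity and ablation structure."""

import numpy as np
import pytest

from promptseg.fusion import (ConditionalBatchNorm, FilmLayer, FusionConfig,
                              FusionModule, l2_normalize_channels, modulate)
from promptseg.nn import Tensor
from promptseg.nn.autodiff import set_default_dtype


@pytest.fixture(autouse=True)
def _double_precision():
    # closed-form identity checks are asserted to machine precision
    previous = set_default_dtype(np.float64)
    yield
    set_default_dtype(previous)


class TestFilm:
    def test_zero_gamma_beta_is_identity(self, rng):
        e4 = rng.standard_normal((2, 8, 4, 4))
        out = modulate(Tensor(e4), np.zeros((2, 8)), np.zeros((2, 8)))
        assert np.array_equal(out.data, e4)

    def test_two_channel_toy_from_direct_evaluation(self):
        e4 = np.ones((1, 2, 1, 1))
        out = modulate(Tensor(e4), np.array([[1.0, -1.0]]), np.array([[0.5, 0.0]]))
        assert out.data[0, 0, 0, 0] == pytest.approx(2.5)
        assert out.data[0, 1, 0, 0] == pytest.approx(0.0)

    def test_zero_maps_give_identity_for_any_prompt(self, rng):
        layer = FilmLayer(8, rng)      # zero-initialised generating maps
        e4 = rng.standard_normal((2, 8, 3, 3))
        v = rng.standard_normal((2, 768))
        assert np.array_equal(layer(Tensor(e4), Tensor(v)).data, e4)

    def test_channel_mismatch_rejected(self, rng):
        layer = FilmLayer(8, rng)
        with pytest.raises(ValueError, match="channels"):
            layer(Tensor(np.zeros((1, 4, 2, 2))), Tensor(np.zeros((1, 768))))


class TestCbn:
    def test_unit_gamma_zero_beta_on_whitened_batch_is_identity(self, rng):
        cbn = ConditionalBatchNorm(2, rng)     # zero W, bias -> gamma=1, beta=0
        f = rng.standard_normal((8, 2, 4, 4))
        f = (f - f.mean(axis=(0, 2, 3), keepdims=True)) \
            / f.std(axis=(0, 2, 3), keepdims=True)
        v = rng.standard_normal((8, 768))
        out = cbn(Tensor(f), Tensor(v)).data
        assert np.allclose(out, f, atol=1e-4)  # eps-perturbed denominator

    def test_zero_gamma_outputs_beta_independent_of_features(self, rng):
        cbn = ConditionalBatchNorm(3, rng)
        cbn.w_gamma.bias.data[...] = 0.0       # gamma_bn = 0
        cbn.w_beta.bias.data[...] = np.array([1.0, 2.0, 3.0])
        v = np.zeros((2, 768))
        for f in (rng.standard_normal((2, 3, 2, 2)),
                  rng.standard_normal((2, 3, 2, 2)) * 50):
            out = cbn(Tensor(f), Tensor(v)).data
            expected = np.broadcast_to(np.array([1.0, 2, 3])[None, :, None, None],
                                       out.shape)
            assert np.allclose(out, expected)

    def test_matches_elementwise_oracle(self, rng):
        cbn = ConditionalBatchNorm(2, rng, eps=1e-5)
        wg = rng.standard_normal((768, 2)) * 0.01
        wb = rng.standard_normal((768, 2)) * 0.01
        cbn.w_gamma.weight.data[...] = wg
        cbn.w_beta.weight.data[...] = wb
        f = rng.standard_normal((4, 2, 2, 2))
        v = rng.standard_normal((4, 768))
        out = cbn(Tensor(f), Tensor(v)).data
        mu = f.mean(axis=(0, 2, 3))
        var = f.var(axis=(0, 2, 3))
        gamma = v @ wg + 1.0
        beta = v @ wb
        xhat = (f - mu[None, :, None, None]) / np.sqrt(var + 1e-5)[None, :, None, None]
        expected = xhat * gamma[:, :, None, None] + beta[:, :, None, None]
        assert np.allclose(out, expected, atol=1e-10)


class TestFuse:
    def test_unit_channel_norm_at_every_location(self, rng):
        fusion = FusionModule(16, FusionConfig(), rng, se_reduction=4)
        fusion.eval()
        e4 = rng.standard_normal((2, 16, 4, 4)) + 1.0
        v = rng.standard_normal((2, 768))
        out = fusion(Tensor(e4), Tensor(v)).data
        norms = np.sqrt((out ** 2).sum(axis=1))
        assert np.allclose(norms, 1.0, atol=1e-6)

    def test_all_toggles_off_is_pure_normalization(self, rng):
        cfg = FusionConfig(use_film=False, use_cbn=False, use_se_fused=False)
        fusion = FusionModule(8, cfg, rng)
        e4 = rng.standard_normal((1, 8, 2, 2))
        out = fusion(Tensor(e4), Tensor(np.zeros((1, 768)))).data
        expected = e4 / np.sqrt((e4 ** 2).sum(axis=1, keepdims=True))
        assert np.allclose(out, expected, atol=1e-7)

    def test_zero_vector_location_is_eps_guarded(self, rng):
        cfg = FusionConfig(use_film=False, use_cbn=False, use_se_fused=False)
        fusion = FusionModule(4, cfg, rng)
        e4 = np.zeros((1, 4, 2, 2))
        out = fusion(Tensor(e4), Tensor(np.zeros((1, 768)))).data
        assert np.all(np.isfinite(out))

    def test_toy_straight_line_oracle(self, rng):
        """2-channel 1x1 bottleneck, SE disabled, hand-set FiLM/CBN params:
        sequential hand evaluation of modulate -> normalize -> residual -> L2."""
        cfg = FusionConfig(use_se_fused=False)
        fusion = FusionModule(2, cfg, rng)
        fusion.train()
        gamma, beta = np.array([0.5, -0.5]), np.array([0.1, 0.2])
        fusion.film.w_gamma.bias.data[...] = gamma
        fusion.film.w_beta.bias.data[...] = beta
        gbn, bbn = np.array([2.0, 1.0]), np.array([0.3, -0.3])
        fusion.cbn.w_gamma.bias.data[...] = gbn
        fusion.cbn.w_beta.bias.data[...] = bbn
        e4 = np.array([[[[1.0]], [[2.0]]], [[[3.0]], [[-1.0]]]])  # (2,2,1,1)
        v = np.zeros((2, 768))
        out = fusion(Tensor(e4), Tensor(v)).data
        # hand evaluation
        fused = (1 + gamma)[None, :, None, None] * e4 + beta[None, :, None, None]
        mu = fused.mean(axis=(0, 2, 3), keepdims=True)
        var = fused.var(axis=(0, 2, 3), keepdims=True)
        cbn = gbn[None, :, None, None] * (fused - mu) / np.sqrt(var + 1e-5) \
            + bbn[None, :, None, None]
        final = e4 + cbn
        expected = final / np.sqrt((final ** 2).sum(axis=1, keepdims=True) + 1e-8)
        assert np.allclose(out, expected, atol=1e-12)

    def test_distinct_prompts_give_distinct_outputs(self, rng):
        fusion = FusionModule(8, FusionConfig(), rng, se_reduction=4)
        fusion.eval()
        # give the FiLM maps nonzero weights (they are zero-initialised)
        fusion.film.w_gamma.weight.data[...] = rng.standard_normal((768, 8)) * 0.1
        e4 = rng.standard_normal((1, 8, 2, 2))
        v1 = rng.standard_normal((1, 768))
        v2 = rng.standard_normal((1, 768))
        out1 = fusion(Tensor(e4), Tensor(v1)).data
        out2 = fusion(Tensor(e4), Tensor(v2)).data
        assert not np.allclose(out1, out2)

    def test_ablation_toggles_change_parameter_sets_exactly(self, rng):
        def n_params(cfg):
            return len(FusionModule(16, cfg, np.random.default_rng(0),
                                    se_reduction=4).parameters())

        full = n_params(FusionConfig())
        no_film = n_params(FusionConfig(use_film=False))
        no_cbn = n_params(FusionConfig(use_cbn=False))
        no_se = n_params(FusionConfig(use_se_fused=False))
        assert full - no_film == 4      # FiLM: two affine maps (W, b each)
        assert full - no_cbn == 4       # CBN: two generating maps
        assert full - no_se == 4        # SE: two bottleneck layers


def test_l2_normalize_gradient_is_finite(rng):
    x = Tensor(rng.standard_normal((1, 4, 2, 2)), requires_grad=True)
    l2_normalize_channels(x).sum().backward()
    assert np.all(np.isfinite(x.grad))
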