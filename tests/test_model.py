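import numpy as np
import pytest

from boldcast.autodiff import Tensor
from boldcast.model import (DiscriminatorSpec, GeneratorSpec, cbam_attention,
                            discriminator_forward, generator_core,
                            generator_forward, init_model, load_model,
                            save_model, spatial_attention_layer,
                            temporal_attention_layer)


@pytest.fixture(scope="module")
def tiny_state():
    gs = GeneratorSpec(m=6, D=16, H=8, gru_hidden=16, fc_nodes=16,
                       cbam_reduction=2, target_index=0)
    ds = DiscriminatorSpec(H=8, gru_hidden=16)
    return init_model(gs, ds, seed=42)


def _cbam_params(state):
    return {k[len("tatt/cbam/"):]: v for k, v in state.gen_params.items()
            if k.startswith("tatt/cbam/")}


class TestCbam:
    def test_zero_input_gives_zero_output(self, tiny_state):
        F = Tensor(np.zeros((2, 6, 16)))
        out, _, _ = cbam_attention(F, _cbam_params(tiny_state), "", 7)
        np.testing.assert_array_equal(out.data, 0.0)

    def test_shape_preserved(self, tiny_state):
        F = Tensor(np.random.default_rng(0).standard_normal((3, 6, 16)))
        out, ch, sp = cbam_attention(F, _cbam_params(tiny_state), "", 7)
        assert out.shape == F.shape
        assert ch.shape == (3, 6) and sp.shape == (3, 16)

    def test_gates_in_open_unit_interval(self, tiny_state):
        F = Tensor(np.random.default_rng(1).standard_normal((2, 6, 16)))
        _, ch, sp = cbam_attention(F, _cbam_params(tiny_state), "", 7)
        for g in (ch.data, sp.data):
            assert np.all((g > 0) & (g < 1))

    def test_reduction_too_large_rejected(self):
        with pytest.raises(ValueError, match="cbam_reduction"):
            GeneratorSpec(m=4, D=8, H=4, cbam_reduction=4)


class TestAttentionLayers:
    def test_temporal_shape_and_weights(self, tiny_state):
        X = Tensor(np.random.default_rng(2).uniform(0, 1, (3, 6, 16)))
        out, tw = temporal_attention_layer(X, tiny_state.gen_params,
                                           tiny_state.gen_spec)
        assert out.shape == (3, 6, 16)
        assert tw.shape == (3, 16)  # one weight per timestep

    def test_spatial_attention_vector(self, tiny_state):
        X = Tensor(np.random.default_rng(3).uniform(0, 1, (2, 6, 16)))
        out, ra = spatial_attention_layer(X, tiny_state.gen_params,
                                          tiny_state.gen_spec)
        assert out.shape == (2, 6, 16)
        assert ra.shape == (2, 6)  # one attention value per region
        assert np.all((ra.data > 0) & (ra.data < 1))

    def test_zero_input_zero_output(self, tiny_state):
        X = Tensor(np.zeros((1, 6, 16)))
        out, _ = temporal_attention_layer(X, tiny_state.gen_params,
                                          tiny_state.gen_spec)
        np.testing.assert_array_equal(out.data, 0.0)


class TestGenerator:
    def test_forecast_shape(self, tiny_state):
        X = np.random.default_rng(4).uniform(0, 1, (5, 6, 16))
        y = generator_forward(tiny_state, X)
        assert y.shape == (5, 8)
        assert np.all(np.isfinite(y))

    def test_published_scale_shapes(self):
        # 16 regions, D=120 history, H=60 horizon (the long-scan layout)
        gs = GeneratorSpec(m=16, D=120, H=60, gru_hidden=8, fc_nodes=8,
                           cbam_reduction=8)
        ds = DiscriminatorSpec(H=60, gru_hidden=8)
        st = init_model(gs, ds, seed=0)
        y = generator_forward(st, np.zeros((1, 16, 120)))
        assert y.shape == (1, 60)

    def test_deterministic_inference(self, tiny_state):
        X = np.random.default_rng(5).uniform(0, 1, (4, 6, 16))
        np.testing.assert_array_equal(generator_forward(tiny_state, X),
                                      generator_forward(tiny_state, X))

    def test_identical_windows_identical_outputs(self, tiny_state):
        x = np.random.default_rng(6).uniform(0, 1, (6, 16))
        batch = np.stack([x, x, x])
        y = generator_forward(tiny_state, batch)
        # BLAS blocking may reassociate sums across batch rows; agreement is
        # to rounding, repeat calls are bit-identical (tested separately)
        np.testing.assert_allclose(y[0], y[1], rtol=0, atol=1e-12)
        np.testing.assert_allclose(y[1], y[2], rtol=0, atol=1e-12)

    def test_shape_mismatch_rejected(self, tiny_state):
        with pytest.raises(ValueError, match="input shape"):
            generator_forward(tiny_state, np.zeros((2, 5, 16)))

    def test_gradients_finite(self, tiny_state):
        params = {k: Tensor(v.copy(), requires_grad=True)
                  for k, v in tiny_state.gen_params.items()}
        X = Tensor(np.random.default_rng(7).uniform(0, 1, (3, 6, 16)))
        y, _ = generator_core(params, tiny_state.gen_spec, X)
        ((y ** 2.0).mean()).backward()
        for name, p in params.items():
            if p.grad is not None:
                assert np.all(np.isfinite(p.grad)), name


class TestDiscriminator:
    def test_scores_in_open_unit_interval(self, tiny_state):
        W = np.random.default_rng(8).uniform(0, 1, (10, 8))
        s = discriminator_forward(tiny_state, W)
        assert s.shape == (10,)
        assert np.all((s > 0) & (s < 1))

    def test_identical_windows_identical_scores(self, tiny_state):
        w = np.random.default_rng(9).uniform(0, 1, 8)
        s = discriminator_forward(tiny_state, np.stack([w, w]))
        assert s[0] == s[1]

    def test_wrong_length_rejected(self, tiny_state):
        with pytest.raises(ValueError, match="window length"):
            discriminator_forward(tiny_state, np.zeros((2, 5)))

    def test_three_layers_enforced(self):
        with pytest.raises(ValueError, match="3 GRU"):
            DiscriminatorSpec(H=8, gru_layers=2)


class TestSerialization:
    def test_round_trip_bit_exact(self, tiny_state, tmp_path):
        path = tmp_path / "model.h5"
        save_model(tiny_state, path)
        back = load_model(path)
        assert back.gen_spec == tiny_state.gen_spec
        assert back.disc_spec == tiny_state.disc_spec
        for k, v in tiny_state.gen_params.items():
            np.testing.assert_array_equal(back.gen_params[k], v)
        X = np.random.default_rng(10).uniform(0, 1, (2, 6, 16))
        np.testing.assert_array_equal(generator_forward(back, X),
                                      generator_forward(tiny_state, X))
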