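"""Architecture calculus, attention arithmetic, and forward/backward sanity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecgattn.model import (
    AttentionParams, ConfigurationError, INCART_CONFIG, MITBIH_CONFIG, Model,
    ModelConfig, build_model, channel_attention, refine, temporal_lengths,
)
from ecgattn import nn as ecgnn
from ecgattn.nn import AvgPool1D, ChannelAttention, Layer, pool_output_length

#: a cheap config for forward/backward tests (same topology, tiny tensors)
SMALL = ModelConfig(
    n_leads=2, window_len=40, conv_filters=(4, 4, 8, 8),
    conv_kernels=(3, 3, 5, 5), reduction_ratio=2,
)


class TestShapes:
    @pytest.mark.parametrize(
        "cfg,chain",
        [
            (MITBIH_CONFIG, [720, 360, 180, 90]),
            (INCART_CONFIG, [514, 257, 129, 65]),
        ],
    )
    def test_temporal_length_chain(self, cfg, chain):
        assert temporal_lengths(cfg) == chain
        model = build_model(cfg)
        lengths = [
            s.output_shape[0] for s in model.summarize() if "conv" in s.name
        ]
        assert lengths == chain

    @settings(max_examples=100, deadline=None)
    @given(L=st.integers(1, 2000))
    def test_pooling_recurrence_ceil(self, L):
        assert pool_output_length(L) == -(-L // 2)
        pool = AvgPool1D()
        x = np.random.default_rng(L).normal(size=(1, L, 3)).astype(np.float32)
        assert pool.forward(x).shape == (1, -(-L // 2), 3)

    def test_edge_pooling_windows_average_in_bounds_only(self):
        pool = AvgPool1D()
        x = np.ones((1, 4, 1), dtype=np.float32)
        y = pool.forward(x)
        # even length: left-aligned windows, last window has 2 in-bounds samples
        np.testing.assert_allclose(y[0, :, 0], [1.0, 1.0])
        x2 = np.arange(5, dtype=np.float32).reshape(1, 5, 1)
        y2 = pool.forward(x2)
        # odd length: windows centred at 0, 2, 4 → [mean(0,1), mean(1,2,3), mean(3,4)]
        np.testing.assert_allclose(y2[0, :, 0], [0.5, 2.0, 3.5])


class TestParameterCounts:
    def test_mitbih_per_layer_ledger(self):
        model = build_model(MITBIH_CONFIG)
        by_name = {s.name: s.n_params for s in model.summarize()}
        assert by_name["conv1"] == 688
        assert by_name["conv2"] == 11_808
        assert by_name["conv3"] == 51_264
        assert by_name["conv4"] == 221_312
        assert by_name["dense"] == 16_512
        assert by_name["output"] == 645
        assert (by_name["attention1"], by_name["attention2"],
                by_name["attention3"], by_name["attention4"]) == (64, 256, 1024, 4096)
        assert model.count_parameters() == 307_669

    def test_incart_totals(self):
        model = build_model(INCART_CONFIG)
        assert model.summarize()[0].n_params == 4048
        assert model.count_parameters() == 311_029

    def test_attention_free_total(self):
        cfg = ModelConfig(attention_mask=(False,) * 4)
        assert build_model(cfg).count_parameters() == 302_229

    def test_count_matches_enumeration_of_arrays(self):
        """Independent oracle: walk every parameter array and count entries."""
        for cfg in (MITBIH_CONFIG, INCART_CONFIG, SMALL):
            model = build_model(cfg)
            walked = sum(
                p.size for layer in model.layers for p in layer.params.values()
            )
            assert model.count_parameters() == walked

    def test_reduction_must_leave_hidden_units(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(conv_filters=(4, 32, 64, 128), reduction_ratio=8)


class TestChannelAttention:
    def test_zero_weights_give_half(self):
        p = AttentionParams(np.zeros((1, 8)), np.zeros((8, 1)))
        A = channel_attention(np.random.default_rng(0).normal(size=(30, 8)), p)
        np.testing.assert_allclose(A, 0.5)

    def test_hand_derived_all_ones_case(self):
        # C=8, r=8: W0 is 1×8 of ones, W1 is 8×1 of ones, F constant 1
        # descriptors avg = max = ones(8); hidden = relu(8) = 8 for both;
        # summed pre-sigmoid = 16 per channel
        p = AttentionParams(np.ones((1, 8)), np.ones((8, 1)))
        A = channel_attention(np.ones((12, 8)), p)
        np.testing.assert_allclose(A, 1.0 / (1.0 + np.exp(-16.0)), rtol=1e-12)

    def test_descriptors_scale_linearly_with_positive_constant(self):
        rng = np.random.default_rng(3)
        F = np.abs(rng.normal(size=(20, 4)))
        c = 3.7
        np.testing.assert_allclose((c * F).mean(axis=0), c * F.mean(axis=0))
        np.testing.assert_allclose((c * F).max(axis=0), c * F.max(axis=0))

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_attention_strictly_inside_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        F = rng.normal(size=(17, 8))
        p = AttentionParams(rng.normal(size=(2, 8)), rng.normal(size=(8, 2)))
        A = channel_attention(F, p)
        assert np.all(A > 0) and np.all(A < 1)

    def test_shape_mismatch_rejected(self):
        p = AttentionParams(np.zeros((1, 8)), np.zeros((8, 1)))
        with pytest.raises(ConfigurationError):
            channel_attention(np.zeros((10, 4)), p)
        with pytest.raises(ConfigurationError):
            AttentionParams(np.zeros((1, 8)), np.zeros((4, 1)))


class TestRefine:
    def test_identity_zero_and_single_column(self):
        rng = np.random.default_rng(5)
        F = rng.normal(size=(9, 4))
        np.testing.assert_array_equal(refine(F, np.ones(4)), F)
        assert not refine(F, np.zeros(4)).any()
        Fcol = np.zeros((9, 4))
        Fcol[:, 2] = 1.0
        out = refine(Fcol, np.array([0.1, 0.2, 0.3, 0.4]))
        assert not out[:, [0, 1, 3]].any()
        np.testing.assert_allclose(out[:, 2], 0.3)

    def test_refined_magnitude_never_exceeds_input(self):
        rng = np.random.default_rng(6)
        F = rng.normal(size=(9, 4))
        A = rng.uniform(0.01, 0.99, size=4)
        assert np.all(np.abs(refine(F, A)) <= np.abs(F))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            refine(np.zeros((5, 3)), np.zeros(4))


class _Scale(Layer):
    """Fixed per-site scaling used to emulate a σ(0)=0.5 gate."""

    def __init__(self, factor):
        self.factor = factor

    def forward(self, x):
        return x * self.factor

    def backward(self, dout):
        return dout * self.factor


class TestForward:
    def test_softmax_rows_sum_to_one(self, rng):
        model = build_model(SMALL, seed=2)
        probs = model.forward(rng.normal(size=(7, 40, 2)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_duplicated_segment_gives_identical_rows(self, rng):
        model = build_model(SMALL, seed=2)
        seg = rng.normal(size=(40, 2))
        probs = model.forward(np.stack([seg] * 8))
        np.testing.assert_array_equal(probs, np.tile(probs[0], (8, 1)))

    def test_zero_batch_is_finite(self):
        model = build_model(SMALL, seed=2)
        assert np.isfinite(model.forward(np.zeros((3, 40, 2)))).all()

    def test_wrong_shape_rejected(self):
        model = build_model(SMALL, seed=2)
        with pytest.raises(ConfigurationError):
            model.forward(np.zeros((3, 41, 2)))

    def test_zeroed_attention_equals_half_scaling(self, rng):
        """With attention weights frozen at zero every gate is σ(0)=0.5, so
        the network must equal the attention-free network with a ×0.5 scale
        at each attention site."""
        gated = build_model(SMALL, seed=7)
        for ly in gated.attention_layers():
            ly.W0[...] = 0.0
            ly.W1[...] = 0.0
        plain_layers = [
            _Scale(0.5) if isinstance(ly, ChannelAttention) else ly
            for ly in gated.layers
        ]
        plain = Model(SMALL, plain_layers)
        x = rng.normal(size=(4, 40, 2))
        np.testing.assert_allclose(gated.forward(x), plain.forward(x), atol=1e-6)

    def test_checkpoint_round_trip(self, tmp_path, rng):
        model = build_model(SMALL, seed=9)
        x = rng.normal(size=(3, 40, 2))
        before = model.forward(x)
        ckpt = model.save(tmp_path / "m")
        loaded = Model.load(ckpt)
        np.testing.assert_array_equal(loaded.forward(x), before)
        assert loaded.cfg == SMALL


class TestBackward:
    @pytest.mark.parametrize(
        "make_layer,shape",
        [
            (lambda r: ecgnn.Conv1D(2, 4, 5, rng=r), (3, 20, 2)),
            (lambda r: ecgnn.ChannelAttention(8, 2, rng=r), (3, 20, 8)),
            (lambda r: ecgnn.AvgPool1D(), (3, 21, 4)),
            (lambda r: ecgnn.AvgPool1D(), (3, 20, 4)),
            (lambda r: ecgnn.GlobalAvgPool(), (3, 20, 4)),
            (lambda r: ecgnn.Dense(6, 4, relu=True, rng=r), (3, 6)),
        ],
        ids=["conv", "attention", "avgpool-odd", "avgpool-even", "gap", "dense"],
    )
    def test_numerical_gradient_check(self, make_layer, shape, rng):
        """Each layer's backward pass agrees with central finite differences
        on the scalar objective sum(forward(x) * dout)."""
        layer = make_layer(rng)
        x = rng.normal(size=shape)
        y = layer.forward(x)
        dout = rng.normal(size=y.shape)
        dx = layer.backward(dout)

        def objective():
            return float((layer.forward(x) * dout).sum())

        eps = 1e-4
        for _ in range(15):  # input gradient at random positions
            idx = tuple(int(rng.integers(0, s)) for s in x.shape)
            orig = x[idx]
            x[idx] = orig + eps
            lp = objective()
            x[idx] = orig - eps
            lm = objective()
            x[idx] = orig
            assert (lp - lm) / (2 * eps) == pytest.approx(
                dx[idx], rel=5e-3, abs=5e-3
            )
        for key, p in layer.params.items():  # parameter gradients
            g = layer.grads[key].reshape(-1)
            flat = p.reshape(-1)
            for i in rng.choice(flat.size, size=min(8, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp = objective()
                flat[i] = orig - eps
                lm = objective()
                flat[i] = orig
                assert (lp - lm) / (2 * eps) == pytest.approx(
                    g[i], rel=5e-3, abs=5e-3
                )
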