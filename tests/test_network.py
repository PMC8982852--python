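import numpy as np
import pytest

from bindsignal import nnops
from bindsignal.network import (
    ModelConfig,
    SignalModel,
    encoder_block,
    load_checkpoint,
    model_forward,
    save_checkpoint,
)


# ---- independent oracles ---------------------------------------------------


def conv_oracle(x, W, b):
    """Direct elementwise same-padded cross-correlation, (C,L) single map."""
    O, C, k = W.shape
    L = x.shape[1]
    pad = k // 2
    xp = np.zeros((C, L + 2 * pad))
    xp[:, pad : pad + L] = x
    out = np.zeros((O, L))
    for o in range(O):
        for l in range(L):
            acc = b[o]
            for c in range(C):
                for j in range(k):
                    acc += W[o, c, j] * xp[c, l + j]
            out[o, l] = acc
    return out


def gru_oracle(x, p):
    """Hand-rolled single-direction GRU recurrence, one step at a time."""

    def sig(v):
        return 1.0 / (1.0 + np.exp(-v))

    C, T = x.shape
    H = p["W_r"].shape[0]
    h = np.zeros(H)
    out = np.zeros((H, T))
    for t in range(T):
        xt = x[:, t]
        r = sig(p["W_r"] @ xt + p["U_r"] @ h)
        z = sig(p["W_z"] @ xt + p["U_z"] @ h)
        hc = np.tanh(p["W"] @ xt + p["U"] @ (r * h))
        h = (1 - z) * h + z * hc
        out[:, t] = h
    return out


def bilinear_oracle(x, scale):
    """Independent linear-interpolation routine (align_corners=False)."""
    T = len(x)
    coords = np.clip((np.arange(T * scale) + 0.5) / scale - 0.5, 0, T - 1)
    return np.interp(coords, np.arange(T), x)


# ---- encoder block ---------------------------------------------------------


class TestEncoderBlock:
    def test_zero_input_zero_bias_gives_zero(self, rng):
        params = {"W": rng.normal(size=(3, 2, 3)), "b": np.zeros(3)}
        out = encoder_block(np.zeros((2, 10)), params, pool=2)
        assert np.all(out == 0)

    def test_shape_contract_1000_to_200(self, rng):
        params = {"W": rng.normal(size=(4, 4, 5)), "b": np.zeros(4)}
        out = encoder_block(rng.normal(size=(4, 1000)), params, pool=5)
        assert out.shape == (4, 200)

    def test_identity_kernel_matches_direct_computation(self, rng):
        # 1 channel, kernel [1] identity weight: block reduces to
        # maxpool(relu(x)), computed here elementwise
        x = rng.normal(size=(1, 12))
        params = {"W": np.ones((1, 1, 1)), "b": np.zeros(1)}
        out = encoder_block(x, params, pool=2)
        relu = np.maximum(x[0], 0)
        expected = [max(relu[2 * i], relu[2 * i + 1]) for i in range(6)]
        np.testing.assert_allclose(out[0], expected, atol=1e-6)

    def test_indivisible_length_errors(self, rng):
        params = {"W": np.ones((1, 1, 1)), "b": np.zeros(1)}
        with pytest.raises(ValueError, match="not divisible"):
            encoder_block(rng.normal(size=(1, 11)), params, pool=2)

    def test_conv_matches_brute_force(self, rng):
        x = rng.normal(size=(1, 3, 9))
        conv = nnops.Conv1d(3, 2, 5, rng=np.random.default_rng(4), dtype=np.float64)
        out = conv.forward(x)
        expected = conv_oracle(x[0], conv.params["W"], conv.params["b"])
        np.testing.assert_allclose(out[0], expected, atol=1e-9)


# ---- BiGRU -----------------------------------------------------------------


class TestBiGRU:
    def test_zero_parameters_zero_output(self):
        gru = nnops.BiGRU(2, 3, dtype=np.float64)
        for p in gru.params.values():
            p[...] = 0.0
        out = gru.forward(np.ones((1, 2, 4)))
        assert np.all(out == 0)

    def test_single_step_symmetry(self, rng):
        # T=1: forward and backward see the same input from zero state,
        # and with shared weights the output is 2x the single-step state
        gru = nnops.BiGRU(2, 3, rng=np.random.default_rng(7), dtype=np.float64)
        for name in nnops.GRUDirection.WEIGHT_NAMES:
            gru.bwd.params[name][...] = gru.fwd.params[name]
        x = rng.normal(size=(1, 2, 1))
        out = gru.forward(x)
        single = gru_oracle(x[0], gru.fwd.params)
        np.testing.assert_allclose(out[0], 2 * single, atol=1e-10)

    def test_matches_recurrence_oracle(self, rng):
        gru = nnops.BiGRU(2, 3, rng=np.random.default_rng(3), dtype=np.float64)
        x = rng.normal(size=(1, 2, 5)) * 0.5
        out = gru.forward(x)
        fwd = gru_oracle(x[0], gru.fwd.params)
        bwd = gru_oracle(x[0, :, ::-1], gru.bwd.params)[:, ::-1]
        np.testing.assert_allclose(out[0], fwd + bwd, atol=1e-6)

    def test_oracle_equivalence_many_small_instances(self):
        # >= 50 random instances, <= 3 channels, <= 5 steps, 1e-6 tolerance
        for i in range(60):
            rng = np.random.default_rng(1000 + i)
            C = int(rng.integers(1, 4))
            H = int(rng.integers(1, 4))
            T = int(rng.integers(1, 6))
            gru = nnops.BiGRU(C, H, rng=np.random.default_rng(i), dtype=np.float64)
            x = rng.normal(size=(1, C, T))
            out = gru.forward(x)
            fwd = gru_oracle(x[0], gru.fwd.params)
            bwd = gru_oracle(x[0, :, ::-1], gru.bwd.params)[:, ::-1]
            np.testing.assert_allclose(out[0], fwd + bwd, atol=1e-6)

    def test_empty_time_axis_errors(self):
        gru = nnops.BiGRU(2, 3)
        with pytest.raises(ValueError):
            gru.forward(np.zeros((1, 2, 0)))

    def test_reversal_symmetry(self, rng):
        # reversing input and swapping direction parameters reverses output
        gru = nnops.BiGRU(2, 3, rng=np.random.default_rng(11), dtype=np.float64)
        x = rng.normal(size=(2, 2, 6))
        out = gru.forward(x)
        swapped = nnops.BiGRU(2, 3, dtype=np.float64)
        for name in nnops.GRUDirection.WEIGHT_NAMES:
            swapped.fwd.params[name][...] = gru.bwd.params[name]
            swapped.bwd.params[name][...] = gru.fwd.params[name]
        out_rev = swapped.forward(x[:, :, ::-1])
        np.testing.assert_allclose(out_rev[:, :, ::-1], out, atol=1e-10)


# ---- global average pooling ------------------------------------------------


class TestGlobalAverageContext:
    def test_constant_map(self):
        h = np.full((3, 7), 2.5)
        np.testing.assert_allclose(nnops.global_average_context(h), [2.5] * 3)

    def test_simple_channel(self):
        h = np.array([[1.0, 2.0, 3.0]])
        assert nnops.global_average_context(h)[0] == 2.0

    def test_matches_brute_force(self, rng):
        for _ in range(50):
            h = rng.normal(size=(4, 9))
            expected = [sum(h[c]) / 9 for c in range(4)]
            np.testing.assert_allclose(
                nnops.global_average_context(h), expected, atol=1e-12
            )

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            nnops.global_average_context(np.zeros((3, 0)))


# ---- bilinear upsampling ---------------------------------------------------


class TestBilinearUpsample:
    @pytest.mark.parametrize("scale", [1, 2, 3, 5])
    def test_constant_preserved(self, scale):
        up = nnops.BilinearUpsample1d(scale)
        out = up.forward(np.full((1, 2, 6), 3.3))
        np.testing.assert_allclose(out, 3.3)

    def test_matches_interp_oracle(self, rng):
        up = nnops.BilinearUpsample1d(5)
        x = rng.normal(size=(1, 1, 8))
        out = up.forward(x)
        assert out.shape == (1, 1, 40)
        np.testing.assert_allclose(out[0, 0], bilinear_oracle(x[0, 0], 5), atol=1e-12)

    def test_oracle_many_instances(self):
        for i in range(50):
            rng = np.random.default_rng(2000 + i)
            scale = int(rng.integers(1, 7))
            T = int(rng.integers(2, 12))
            x = rng.normal(size=(1, 1, T))
            out = nnops.BilinearUpsample1d(scale).forward(x)
            np.testing.assert_allclose(
                out[0, 0], bilinear_oracle(x[0, 0], scale), atol=1e-9
            )


# ---- decoder stage ---------------------------------------------------------


class TestDecoderStage:
    def test_skip_cancellation(self, rng):
        # s=1, skip=-y: the post-add map is zero; with BN disabled
        # (identity) and an identity blend the output is ReLU(0) = 0
        from bindsignal.network import DecoderStage

        stage = DecoderStage(1, 1, 1, 1, None, np.float64)
        stage.conv.params["W"][...] = 1.0
        stage.conv.params["b"][...] = 0.0
        y = rng.normal(size=(1, 1, 6))
        out = stage.forward(y, skip=-y)  # inference: BN uses mean 0 var 1
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_skip_shape_mismatch_errors(self, rng):
        from bindsignal.network import DecoderStage

        stage = DecoderStage(2, 1, 1, 1, None, np.float64)
        with pytest.raises(ValueError, match="skip"):
            stage.forward(rng.normal(size=(1, 1, 4)), skip=rng.normal(size=(1, 1, 4)))


# ---- full model ------------------------------------------------------------


class TestModelForward:
    @pytest.mark.parametrize("L", [125, 250, 1000])
    def test_length_preserved(self, tiny_model, L, rng):
        x = rng.random((4, L)).astype(np.float32)
        out = model_forward(x, tiny_model)
        assert out.shape == (L,)

    def test_length_preserved_8000(self, tiny_model, rng):
        x = rng.random((4, 8000)).astype(np.float32)
        assert model_forward(x, tiny_model).shape == (8000,)

    def test_indivisible_length_errors(self, tiny_model, rng):
        with pytest.raises(ValueError, match="divisible"):
            model_forward(rng.random((4, 1001)).astype(np.float32), tiny_model)

    def test_inference_bitwise_deterministic(self, tiny_model, rng):
        x = rng.random((4, 1000)).astype(np.float32)
        a = model_forward(x, tiny_model)
        b = model_forward(x, tiny_model)
        np.testing.assert_array_equal(a, b)

    def test_dropout_active_only_in_training(self, tiny_config, rng):
        model = SignalModel(tiny_config, seed=0)
        # the output head is zero-initialized; give it weight so dropout
        # noise reaches the output
        model.dec[3].conv.params["W"][...] = rng.normal(
            size=model.dec[3].conv.params["W"].shape
        ).astype(np.float32)
        x = rng.random((4, 1000)).astype(np.float32)
        t1 = model.forward(x[None], training=True)
        t2 = model.forward(x[None], training=True)
        assert not np.array_equal(t1, t2)  # fresh dropout masks differ
        i1 = model.forward(x[None])
        i2 = model.forward(x[None])
        np.testing.assert_array_equal(i1, i2)


class TestModelConfig:
    def test_input_len_multiple(self):
        assert ModelConfig().input_len_multiple == 125

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(kernel_sizes=(4, 5, 3))

    def test_skip_channel_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(blend_channels=(99, 64, 64, 1))

    def test_final_channel_must_be_one(self):
        with pytest.raises(ValueError):
            ModelConfig(blend_channels=(96, 64, 64, 2))


class TestCheckpoint:
    def test_roundtrip(self, tiny_config, tmp_path, rng):
        model = SignalModel(tiny_config, seed=4)
        path = tmp_path / "model.ckpt"
        save_checkpoint(model, path, {"note": "test"})
        loaded, meta = load_checkpoint(path)
        assert meta == {"note": "test"}
        x = rng.random((4, 500)).astype(np.float32)
        np.testing.assert_array_equal(
            model.forward(x[None]), loaded.forward(x[None])
        )
        assert model.param_digest() == loaded.param_digest()


class TestGradients:
    """Finite-difference checks of the hand-written backward passes."""

    def _check(self, layer, x, n_checks=10, eps=1e-6, tol=1e-5):
        rng = np.random.default_rng(0)
        dout_shape = layer.forward(x).shape
        dout = rng.normal(size=dout_shape)

        def loss():
            return float(np.sum(layer.forward(x) * dout))

        layer.zero_grad()
        layer.forward(x)
        dx = layer.backward(dout)
        for name, p in layer.params.items():
            flat = p.ravel()
            for i in rng.choice(flat.size, size=min(n_checks, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp = loss()
                flat[i] = orig - eps
                lm = loss()
                flat[i] = orig
                assert layer.grads[name].ravel()[i] == pytest.approx(
                    (lp - lm) / (2 * eps), abs=tol, rel=tol
                ), name
        # input gradient
        xf = x.ravel()
        for i in rng.choice(xf.size, size=min(n_checks, xf.size), replace=False):
            orig = xf[i]
            xf[i] = orig + eps
            lp = loss()
            xf[i] = orig - eps
            lm = loss()
            xf[i] = orig
            assert dx.ravel()[i] == pytest.approx((lp - lm) / (2 * eps), abs=tol, rel=tol)

    def test_conv(self, rng):
        conv = nnops.Conv1d(3, 4, 5, rng=np.random.default_rng(1), dtype=np.float64)
        self._check(conv, rng.normal(size=(2, 3, 8)))

    def test_gru(self, rng):
        gru = nnops.BiGRU(3, 4, rng=np.random.default_rng(2), dtype=np.float64)
        self._check(gru, rng.normal(size=(2, 3, 5)))

    def test_full_model_end_to_end(self, rng):
        cfg = ModelConfig(
            conv_channels=(3, 4, 5),
            kernel_sizes=(5, 3, 3),
            pool_sizes=(2, 2, 2),
            gru_hidden=5,
            blend_channels=(4, 3, 2, 1),
            dropout_rate=0.0,
            dtype="float64",
        )
        model = SignalModel(cfg, seed=3)
        x = rng.random((2, 4, 16))
        target = rng.random((2, 16))

        def loss():
            pred = model.forward(x, training=True)
            return float(np.mean((pred - target) ** 2))

        model.zero_grad()
        pred = model.forward(x, training=True)
        model.backward(2.0 / pred.size * (pred - target))
        grads = {k: v.copy() for k, v in model.grads().items()}
        eps = 1e-6
        check_rng = np.random.default_rng(9)
        for name, p in model.params().items():
            flat = p.ravel()
            for i in check_rng.choice(flat.size, size=min(3, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp = loss()
                flat[i] = orig - eps
                lm = loss()
                flat[i] = orig
                assert grads[name].ravel()[i] == pytest.approx(
                    (lp - lm) / (2 * eps), abs=1e-6, rel=1e-4
                ), name
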