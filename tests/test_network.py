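"""Conv/BiGRU/Wav-KAN layers and the assembled window classifier."""

import numpy as np
import pytest

from phoskan.errors import ContractError, PhosKANError
from phoskan.nn import (
    Adam,
    BatchNorm1d,
    BiGRU,
    Conv2dValid,
    ModelConfig,
    PhosKANModel,
    Tensor,
    WavKANLayer,
    count_parameters,
    wavelet_eval,
)
from phoskan.nn.autograd import bce_with_logits

RNG = np.random.default_rng(5)


def conv_oracle(x, w, b):
    """Naive 4-loop valid cross-correlation, ReLU applied."""
    B, H, W = x.shape
    K, kh, kw = w.shape
    out = np.zeros((B, K, H - kh + 1, W - kw + 1))
    for n in range(B):
        for k in range(K):
            for i in range(H - kh + 1):
                for j in range(W - kw + 1):
                    out[n, k, i, j] = (
                        x[n, i : i + kh, j : j + kw] * w[k]
                    ).sum() + b[k]
    return np.maximum(out, 0.0)


class TestConv:
    def test_printed_shape_chain(self):
        conv = Conv2dValid(16, 5, np.random.default_rng(0))
        out = conv.forward(Tensor(RNG.standard_normal((2, 9, 1792))))
        assert out.shape == (2, 16, 5, 1788)

    def test_matches_loop_oracle_on_toy_widths(self):
        conv = Conv2dValid(4, 5, np.random.default_rng(1))
        x = RNG.standard_normal((3, 9, 12))
        ours = conv.forward(Tensor(x)).data
        oracle = conv_oracle(x, conv.weight.data, conv.bias.data)
        np.testing.assert_allclose(ours, oracle, rtol=1e-10, atol=1e-12)

    def test_zero_input_zero_bias_gives_zeros(self):
        conv = Conv2dValid(4, 3, np.random.default_rng(2))
        conv.bias.data = np.zeros_like(conv.bias.data)
        out = conv.forward(Tensor(np.zeros((2, 9, 10))))
        assert np.all(out.data == 0)

    def test_delta_kernel_extracts_central_block(self):
        conv = Conv2dValid(1, 5, np.random.default_rng(3))
        conv.weight.data = np.zeros((1, 5, 5))
        conv.weight.data[0, 2, 2] = 1.0  # delta at the kernel center
        conv.bias.data = np.zeros(1)
        x = RNG.standard_normal((1, 9, 30))
        out = conv.forward(Tensor(x)).data
        np.testing.assert_allclose(out[0, 0], np.maximum(x[0, 2:7, 2:28], 0))

    def test_wrong_rank_rejected(self):
        conv = Conv2dValid(2, 3)
        with pytest.raises(ContractError):
            conv.forward(Tensor(np.zeros((9, 12))))


class TestBiGRU:
    def test_output_shape(self):
        gru = BiGRU(d_in=20, hidden=8, rng=np.random.default_rng(0))
        out = gru.forward(Tensor(RNG.standard_normal((3, 5, 20))))
        assert out.shape == (3, 5, 16)

    def test_zero_input_zero_bias_fixed_point(self):
        gru = BiGRU(d_in=6, hidden=4, rng=np.random.default_rng(1))
        # with zero input, zero biases and zero initial state the update
        # gate halves a zero candidate: the hidden state stays zero
        out = gru.forward(Tensor(np.zeros((2, 5, 6))))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-15)

    def test_time_reversal_swaps_directions(self):
        gru = BiGRU(d_in=6, hidden=4, rng=np.random.default_rng(2))
        # share the per-gate weights between directions
        for k, v in gru.fwd.named_parameters().items():
            gru.bwd.named_parameters()[k].data = v.data.copy()
        x = RNG.standard_normal((2, 5, 6))
        out = gru.forward(Tensor(x)).data
        rev = gru.forward(Tensor(x[:, ::-1].copy())).data
        # forward track of the reversed input = reversed backward track
        np.testing.assert_allclose(rev[:, :, :4], out[:, ::-1, 4:],
                                   rtol=1e-12)
        np.testing.assert_allclose(rev[:, :, 4:], out[:, ::-1, :4],
                                   rtol=1e-12)


class TestWavKANLayer:
    def wavkan_oracle(self, x, layer):
        """Per-edge scalar-loop evaluation of the layer."""
        omega = layer.omega.data
        s = np.exp(layer.log_s.data)
        tau = layer.tau.data
        wb = layer.w_base.data
        bias = layer.bias.data
        B = x.shape[0]
        out = np.zeros((B, layer.d_out))
        for n in range(B):
            for j in range(layer.d_out):
                acc = bias[j]
                for i in range(layer.d_in):
                    t = (x[n, i] - tau[j, i]) / s[j, i]
                    acc += omega[j, i] * wavelet_eval(layer.wavelet, t)
                    acc += wb[i, j] * x[n, i]
                out[n, j] = acc
        return out

    def test_zero_wavelet_zero_base_returns_bias(self):
        layer = WavKANLayer(4, 3, rng=np.random.default_rng(0))
        layer.omega.data = np.zeros_like(layer.omega.data)
        layer.w_base.data = np.zeros_like(layer.w_base.data)
        layer.bias.data = np.array([1.0, -2.0, 0.5])
        out = layer.forward(Tensor(RNG.standard_normal((6, 4))))
        np.testing.assert_allclose(out.data,
                                   np.tile([1.0, -2.0, 0.5], (6, 1)))

    def test_single_edge_is_omega_times_psi(self):
        layer = WavKANLayer(1, 1, wavelet="dog",
                            rng=np.random.default_rng(1))
        layer.w_base.data = np.zeros((1, 1))
        layer.bias.data = np.zeros(1)
        omega = float(layer.omega.data[0, 0])
        x = np.array([[0.7], [-1.3]])
        out = layer.forward(Tensor(x)).data
        expected = omega * np.array(
            [[wavelet_eval("dog", 0.7)], [wavelet_eval("dog", -1.3)]]
        )
        np.testing.assert_allclose(out, expected, rtol=1e-12)

    @pytest.mark.parametrize("wavelet", ["dog", "mexican_hat", "morlet"])
    def test_matches_scalar_oracle(self, wavelet):
        rng = np.random.default_rng(8)
        for trial in range(12):
            d_in, d_out = int(rng.integers(1, 5)), int(rng.integers(1, 4))
            layer = WavKANLayer(d_in, d_out, wavelet=wavelet, rng=rng)
            layer.log_s.data = rng.uniform(-0.3, 0.3, (d_out, d_in))
            layer.tau.data = rng.standard_normal((d_out, d_in)) * 0.5
            x = rng.standard_normal((3, d_in))
            ours = layer.forward(Tensor(x)).data
            np.testing.assert_allclose(ours, self.wavkan_oracle(x, layer),
                                       rtol=1e-9, atol=1e-11)

    def test_strict_mode_freezes_scale_and_translation(self):
        layer = WavKANLayer(3, 2, strict_mode=True)
        trainable = {id(p) for p in layer.parameters()}
        assert id(layer.log_s) not in trainable
        assert id(layer.tau) not in trainable
        assert id(layer.omega) in trainable

    def test_edge_count_proportional_to_width(self):
        small = WavKANLayer(10, 8).n_parameters()
        double = WavKANLayer(10, 16).n_parameters()
        assert double == 2 * small


class TestBatchNorm:
    def test_eval_mode_is_batch_composition_invariant(self):
        bn = BatchNorm1d(4)
        x = RNG.standard_normal((32, 4))
        bn.forward(Tensor(x))  # accumulate running stats
        bn.eval()
        full = bn.forward(Tensor(x)).data
        single = np.vstack([bn.forward(Tensor(x[i : i + 1])).data
                            for i in range(8)])
        np.testing.assert_allclose(full[:8], single, rtol=1e-12)

    def test_train_mode_normalizes_batch(self):
        bn = BatchNorm1d(3)
        x = RNG.standard_normal((200, 3)) * 5 + 2
        out = bn.forward(Tensor(x)).data
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.std(axis=0), 1.0, atol=1e-2)


class TestModel:
    @pytest.fixture(scope="class")
    def tiny_model(self):
        return PhosKANModel(ModelConfig(variant="Y", embed_dim=16, seed=4))

    def test_full_size_shape_contract(self):
        cfg = ModelConfig(variant="ST")
        assert cfg.conv_out_shape == (5, 1788)
        assert cfg.flatten_dim == 80
        model = PhosKANModel(cfg)
        z = model.forward(RNG.standard_normal((2, 9, 1792)))
        assert z.shape == (2,)

    def test_probabilities_in_unit_interval(self, tiny_model):
        p = tiny_model.predict_proba(RNG.standard_normal((10, 9, 16)))
        assert np.all((p >= 0) & (p <= 1))

    def test_sigmoid_of_zero_logit(self):
        assert 1 / (1 + np.exp(-0.0)) == 0.5  # head convention
        # and predict_proba is exactly the sigmoid of forward()
        model = PhosKANModel(ModelConfig(variant="Y", embed_dim=16, seed=1))
        model.eval()
        x = RNG.standard_normal((4, 9, 16))
        z = model.forward(x).data
        np.testing.assert_allclose(model.predict_proba(x),
                                   1 / (1 + np.exp(-z)), rtol=1e-12)

    def test_wrong_input_shape(self, tiny_model):
        with pytest.raises(ContractError):
            tiny_model.forward(RNG.standard_normal((2, 9, 20)))

    def test_inference_invariant_to_batch_composition(self, tiny_model):
        x = RNG.standard_normal((6, 9, 16))
        together = tiny_model.predict_proba(x)
        alone = np.concatenate(
            [tiny_model.predict_proba(x[i : i + 1]) for i in range(6)]
        )
        np.testing.assert_allclose(together, alone, rtol=1e-10)

    def test_variant_layouts(self):
        st = ModelConfig(variant="ST")
        y = ModelConfig(variant="Y")
        assert st.hidden_layout == (128, 32)
        assert y.hidden_layout == (24,)

    def test_parameter_counts(self):
        st = count_parameters(ModelConfig(variant="ST"))
        y = count_parameters(ModelConfig(variant="Y"))
        assert st["conv"] == 16 * (5 * 5 + 1) == 416
        assert st["total"] > y["total"]

    def test_invalid_variant(self):
        with pytest.raises(PhosKANError):
            ModelConfig(variant="STY")

    def test_checkpoint_round_trip(self, tmp_path, tiny_model):
        x = RNG.standard_normal((5, 9, 16))
        before = tiny_model.predict_proba(x)
        tiny_model.save(tmp_path / "ckpt", history={"val_loss": [0.5]})
        loaded = PhosKANModel.load(tmp_path / "ckpt")
        np.testing.assert_array_equal(loaded.predict_proba(x), before)

    def test_meanpool_input_mode_runs(self):
        cfg = ModelConfig(variant="Y", embed_dim=16, seed=2,
                          bigru_input_mode="meanpool")
        model = PhosKANModel(cfg)
        assert model.forward(RNG.standard_normal((3, 9, 16))).shape == (3,)


class TestEndToEndGradients:
    def test_finite_difference_check_on_sampled_parameters(self):
        """Analytic gradients of the full model match central differences
        within 1e-3 relative error on a tiny instance."""
        model = PhosKANModel(ModelConfig(variant="Y", embed_dim=12, seed=3))
        model.eval()  # freeze batch statistics so loss is a pure function
        x = np.random.default_rng(1).standard_normal((6, 9, 12))
        y = np.array([0, 1, 0, 1, 1, 0])

        def loss_value():
            return bce_with_logits(model.forward(x), y)

        loss = loss_value()
        loss.backward()
        params = model.named_parameters()
        rng = np.random.default_rng(2)
        checked = 0
        for name in ["conv.weight", "conv.bias", "bigru.fwd.w_x",
                     "bigru.fwd.w_h", "bigru.bwd.b_x", "hidden0.omega",
                     "hidden0.log_s", "hidden0.tau", "hidden0.w_base",
                     "norm0.gamma", "norm0.beta", "head.omega", "head.bias"]:
            p = params[name]
            for _ in range(3):
                idx = tuple(int(rng.integers(0, s)) for s in p.data.shape)
                eps = 1e-6
                old = p.data[idx]
                p.data[idx] = old + eps
                lp = loss_value().item()
                p.data[idx] = old - eps
                lm = loss_value().item()
                p.data[idx] = old
                fd = (lp - lm) / (2 * eps)
                an = p.grad[idx]
                denom = max(abs(fd), abs(an), 1e-6)
                assert abs(fd - an) / denom < 1e-3, (name, idx, fd, an)
                checked += 1
        assert checked >= 30


class TestAdam:
    def test_minimizes_quadratic(self):
        p = Tensor(np.array([5.0, -3.0]), requires_grad=True)
        opt = Adam([p], lr=0.1)
        for _ in range(300):
            opt.zero_grad()
            loss = (p * p).sum()
            loss.backward()
            opt.step()
        np.testing.assert_allclose(p.data, 0.0, atol=1e-3)

    def test_invalid_hyperparameters(self):
        with pytest.raises(ValueError):
            Adam([], lr=-1)
        with pytest.raises(ValueError):
            Adam([], beta1=1.5)
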