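"""Network components against brute-force oracles; training mechanics."""

import hashlib

import numpy as np
import pytest

from uesdist import io as uio
from uesdist import model as M
from tests.conftest import make_planted_samples


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# naive reference implementations (independent of the vectorized code paths)
# ---------------------------------------------------------------------------

def naive_cnn(chunk, params, cfg):
    p = params.arrays
    C, F, K = cfg.channels_in, cfg.conv1_filters_per_channel, cfg.kernel_len
    L1 = cfg.conv1_out_len
    a1 = np.zeros((L1, C, F))
    for w in range(L1):
        for c in range(C):
            for f in range(F):
                acc = p["conv1_b"].reshape(C, F)[c, f]
                for k in range(K):
                    acc += chunk[w + k, c] * p["conv1_w"][c, f, k]
                a1[w, c, f] = max(acc, 0.0)
    Lp = cfg.pool_out_len
    pooled = np.zeros((Lp, C * F))
    for w in range(Lp):
        for c in range(C):
            for f in range(F):
                pooled[w, c * F + f] = max(a1[2 * w, c, f], a1[2 * w + 1, c, f])
    L2 = cfg.conv2_out_len
    out = np.zeros((L2, C * F))
    for w in range(L2):
        for ch in range(C * F):
            acc = p["conv2_b"][ch]
            for k in range(K):
                acc += pooled[w + k, ch] * p["conv2_w"][ch, k]
            out[w, ch] = max(acc, 0.0)
    return out.reshape(-1)


def naive_gru_cell(x, h, params, cfg, layer):
    p, H = params.arrays, cfg.gru_units
    wx, b = p[f"gru{layer}_wx"], p[f"gru{layer}_b"]
    wh_zr, wh_n = p[f"gru{layer}_wh_zr"], p[f"gru{layer}_wh_n"]
    pre = x @ wx + b
    z = sigmoid(pre[:H] + h @ wh_zr[:, :H])
    r = sigmoid(pre[H : 2 * H] + h @ wh_zr[:, H:])
    n = np.tanh(pre[2 * H :] + (r * h) @ wh_n)
    return (1.0 - z) * n + z * h


def naive_head(y_flat, params, cfg):
    p = params.arrays
    h = y_flat
    for layer in range(cfg.fc_layers):
        h = np.maximum(h @ p[f"fc{layer}_w"] + p[f"fc{layer}_b"], 0.0)
    return sigmoid((h @ p["out_w"] + p["out_b"])[0])


# ---------------------------------------------------------------------------
# architecture audit
# ---------------------------------------------------------------------------

class TestArchitecture:
    def test_printed_dimensions(self):
        cfg = M.ModelConfig()
        assert cfg.cnn_channels == 48
        assert cfg.conv1_out_len == 62
        assert cfg.pool_out_len == 31
        assert cfg.conv2_out_len == 27
        assert cfg.cnn_feature_dim == 1296
        assert cfg.rnn_flat_dim == 90 * 64

    def test_parameter_shapes(self):
        cfg = M.ModelConfig()
        params = M.init_params(cfg, seed=0)
        a = params.arrays
        assert a["attn_cnn_w1"].shape == (90, 2048)
        assert a["attn_cnn_w2"].shape == (2048, 90 * 1296)
        assert a["attn_rnn_w2"].shape == (2048, 90 * 64)
        assert a["gru0_wx"].shape == (1296, 3 * 64)
        assert a["fc0_w"].shape == (90 * 64, 128)
        assert a["fc1_w"].shape == (128, 128)
        assert a["out_w"].shape == (128, 1)
        del params


# ---------------------------------------------------------------------------
# forward-path oracles (scaled-down config keeps the loops fast)
# ---------------------------------------------------------------------------

class TestForwardOracles:
    def test_cnn_matches_naive(self, tiny_config, rng):
        params = M.init_params(tiny_config, seed=1, dtype=np.float64)
        chunk = rng.standard_normal((tiny_config.chunk_len,
                                     tiny_config.channels_in))
        fast = M.cnn_forward(chunk, params, tiny_config)
        slow = naive_cnn(chunk, params, tiny_config)
        assert np.allclose(fast, slow, atol=1e-6)

    def test_cnn_zero_params_zero_output(self, tiny_config, rng):
        params = M.init_params(tiny_config, seed=0, dtype=np.float64)
        for k in ("conv1_w", "conv1_b", "conv2_w", "conv2_b"):
            params.arrays[k][:] = 0
        chunk = rng.standard_normal((tiny_config.chunk_len,
                                     tiny_config.channels_in))
        assert np.all(M.cnn_forward(chunk, params, tiny_config) == 0)

    def test_cnn_shape_contract(self, tiny_config):
        params = M.init_params(tiny_config, seed=0)
        with pytest.raises(ValueError):
            M.cnn_forward(np.zeros((tiny_config.chunk_len + 1, 3)), params,
                          tiny_config)

    def test_gru_single_step_matches_cell_equations(self, tiny_config, rng):
        params = M.init_params(tiny_config, seed=2, dtype=np.float64)
        x = rng.standard_normal(tiny_config.cnn_feature_dim)
        seq = np.zeros((tiny_config.T, tiny_config.cnn_feature_dim))
        seq[0] = x
        out = M.rnn_forward(seq, params, tiny_config)
        h = np.zeros(tiny_config.gru_units)
        h = naive_gru_cell(x, h, params, tiny_config, layer=0)
        for layer in range(1, tiny_config.gru_layers):
            h = naive_gru_cell(h, np.zeros(tiny_config.gru_units), params,
                               tiny_config, layer)
        assert np.allclose(out[0], h, atol=1e-6)

    def test_gru_zero_params_zero_output(self, tiny_config, rng):
        params = M.init_params(tiny_config, seed=0, dtype=np.float64)
        for k in list(params.arrays):
            if k.startswith("gru"):
                params.arrays[k][:] = 0
        seq = rng.standard_normal((tiny_config.T, tiny_config.cnn_feature_dim))
        assert np.all(M.rnn_forward(seq, params, tiny_config) == 0)

    def test_head_matches_naive(self, tiny_config, rng):
        params = M.init_params(tiny_config, seed=3, dtype=np.float64)
        y = rng.standard_normal(tiny_config.rnn_flat_dim)
        assert M.head_forward(y, params, tiny_config) == pytest.approx(
            naive_head(y, params, tiny_config), abs=1e-6)

    def test_head_output_range_and_determinism(self, tiny_config, rng):
        params = M.init_params(tiny_config, seed=4)
        y = rng.standard_normal(tiny_config.rnn_flat_dim).astype(np.float32)
        a = M.head_forward(y, params, tiny_config)
        b = M.head_forward(y, params, tiny_config)
        assert 0.0 < a < 1.0
        assert a == b  # dropout inactive at inference

    def test_attention_shapes_range_and_sensitivity(self, tiny_config, rng):
        cfg = tiny_config
        params = M.init_params(cfg, seed=5)
        mask = np.zeros(cfg.T, dtype=np.float32)
        mask[2:5] = 1
        a_cnn, a_rnn = M.attention_forward(mask, params, cfg)
        assert a_cnn.shape == (cfg.T, cfg.cnn_feature_dim)
        assert a_rnn.shape == (cfg.T, cfg.gru_units)
        assert np.all((a_cnn > 0) & (a_cnn < 1))
        other = np.zeros(cfg.T, dtype=np.float32)
        other[6:8] = 1
        b_cnn, _ = M.attention_forward(other, params, cfg)
        assert not np.allclose(a_cnn, b_cnn)

    def test_attention_zero_weights_give_half(self, tiny_config):
        cfg = tiny_config
        params = M.init_params(cfg, seed=0)
        for k in list(params.arrays):
            if k.startswith("attn"):
                params.arrays[k][:] = 0
        a_cnn, a_rnn = M.attention_forward(np.ones(cfg.T, dtype=np.float32),
                                           params, cfg)
        assert np.allclose(a_cnn, 0.5) and np.allclose(a_rnn, 0.5)

    def test_mse_matches_bruteforce(self, rng):
        p, t = rng.random(50), rng.random(50)
        assert M.mse_loss(p, t) == pytest.approx(sum((a - b) ** 2 for a, b
                                                     in zip(p, t)) / 50)
        assert M.mse_loss(t, t) == 0
        assert M.mse_loss([0.5], [0.0]) == 0.25

    def test_ape_values(self):
        assert M.ape(0.35, 0.45) == pytest.approx(22.2, abs=0.05)
        assert M.ape(0.5, 0.5) == 0
        assert M.ape(0.0, 0.3) == 100
        with pytest.raises(ValueError):
            M.ape(0.5, 0.0)


class TestFullForward:
    def test_prediction_in_unit_interval_and_finite(self, tiny_config):
        cfg = tiny_config
        for seed in range(100):
            r = np.random.default_rng(seed)
            params = M.init_params(cfg, seed=seed)
            chunks = r.standard_normal(
                (1, cfg.T, cfg.chunk_len, cfg.channels_in)).astype(np.float32)
            mask = (r.random((1, cfg.T)) < 0.5).astype(np.float32)
            pred = M._forward_batch(chunks, mask, params, cfg)
            assert np.isfinite(pred).all() and 0 < pred[0] < 1

    def test_order_sensitivity_inside_window(self, tiny_config, rng):
        cfg = tiny_config
        params = M.init_params(cfg, seed=8)
        sample = make_planted_samples(cfg, 1, seed=3)[0]
        base = M.forward(sample, params, cfg)
        idx = np.where(sample.mask > 0)[0][:2]
        chunks = sample.chunks.copy()
        chunks[[idx[0], idx[1]]] = chunks[[idx[1], idx[0]]]
        swapped = type(sample)(chunks=chunks, mask=sample.mask,
                               target_ratio=sample.target_ratio,
                               valid_chunks=sample.valid_chunks)
        assert M.forward(swapped, params, cfg) != base

    def test_identical_samples_identical_predictions(self, tiny_config):
        cfg = tiny_config
        params = M.init_params(cfg, seed=9)
        s = make_planted_samples(cfg, 1, seed=4)[0]
        preds = M.predict([s, s, s], params, cfg)
        assert np.all(preds == preds[0])


# ---------------------------------------------------------------------------
# gradients
# ---------------------------------------------------------------------------

class TestGradients:
    def test_backprop_matches_directional_derivatives(self, tiny_config):
        # central differences along random parameter directions; this
        # averages over the isolated ReLU kinks that make elementwise
        # finite differences unreliable near zero pre-activations
        cfg = tiny_config
        params = M.init_params(cfg, seed=3, dtype=np.float64)
        rng = np.random.default_rng(0)
        for w in params.arrays.values():
            # zero-initialized biases put dead ReLU units exactly at the
            # kink, where the subgradient convention and finite
            # differences legitimately disagree; move off that set
            w += 0.05 * rng.standard_normal(w.shape)
        B = 3
        X = rng.standard_normal((B, cfg.T, cfg.chunk_len, cfg.channels_in))
        Mk = (rng.random((B, cfg.T)) < 0.5).astype(float)
        y = rng.uniform(0.2, 0.8, B)
        _, _, grads = M.loss_and_gradients(X, Mk, y, params, cfg)
        eps = 1e-6
        for trial in range(5):
            direction = {k: rng.standard_normal(w.shape)
                         for k, w in params.arrays.items()}
            for k, w in params.arrays.items():
                w += eps * direction[k]
            lp, _, _ = M.loss_and_gradients(X, Mk, y, params, cfg)
            for k, w in params.arrays.items():
                w -= 2 * eps * direction[k]
            lm, _, _ = M.loss_and_gradients(X, Mk, y, params, cfg)
            for k, w in params.arrays.items():
                w += eps * direction[k]
            numeric = (lp - lm) / (2 * eps)
            analytic = sum(float(np.sum(grads[k] * direction[k]))
                           for k in grads)
            assert numeric == pytest.approx(analytic, rel=1e-5, abs=1e-9)


# ---------------------------------------------------------------------------
# training mechanics
# ---------------------------------------------------------------------------

def params_digest(params):
    h = hashlib.sha256()
    for k in sorted(params.arrays):
        h.update(k.encode())
        h.update(np.ascontiguousarray(params.arrays[k]).tobytes())
    return h.hexdigest()


class TestTraining:
    def test_loss_decreases_on_planted_data(self, tiny_config, planted_samples):
        _, history = M.train(planted_samples, tiny_config, seed=0)
        assert history[-1]["mse"] < history[0]["mse"]

    def test_same_seed_reproduces_parameters_bitwise(self, tiny_config,
                                                     planted_samples):
        pa, _ = M.train(planted_samples, tiny_config, seed=42)
        pb, _ = M.train(planted_samples, tiny_config, seed=42)
        assert params_digest(pa) == params_digest(pb)

    def test_different_seed_differs(self, tiny_config, planted_samples):
        pa, _ = M.train(planted_samples, tiny_config, seed=1)
        pb, _ = M.train(planted_samples, tiny_config, seed=2)
        assert params_digest(pa) != params_digest(pb)

    def test_heldout_recovery_small_model(self, tiny_config):
        cfg = type(tiny_config)(**{**tiny_config.__dict__, "epochs": 60})
        train_set = make_planted_samples(cfg, 48, seed=10, noise=0.02)
        test_set = make_planted_samples(cfg, 24, seed=11, noise=0.02)
        params, _ = M.train(train_set, cfg, seed=0)
        preds = M.predict(test_set, params, cfg)
        truth = np.array([s.target_ratio for s in test_set])
        assert np.corrcoef(preds, truth)[0, 1] > 0.7

    def test_empty_training_set_rejected(self, tiny_config):
        with pytest.raises(ValueError):
            M.train([], tiny_config)

    def test_checkpoint_roundtrip_bit_identical(self, tiny_config,
                                                planted_samples, tmp_path):
        params, _ = M.train(planted_samples[:8], tiny_config, seed=0)
        preds = M.predict(planted_samples, params, tiny_config)
        path = tmp_path / "ckpt.h5"
        uio.save_checkpoint(path, params.arrays, tiny_config)
        arrays, cfg = uio.load_checkpoint(path)
        restored = M.ModelParams(arrays)
        assert cfg == tiny_config
        assert np.array_equal(M.predict(planted_samples, restored, cfg), preds)
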