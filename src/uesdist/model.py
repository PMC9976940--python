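"""Attention-masked convolutional-recurrent regression network.

The estimator maps a swallow's cleaned tri-axial accelerometry -- a
sequence of T=90 per-frame chunks of 66 samples x 3 channels -- to the
normalized A-P UES opening maximal distension (a ratio in (0, 1)):

* a per-chunk 1-D CNN (16 length-5 filters per channel -> 48 channels,
  ReLU, max-pool 2/2, then one depthwise length-5 filter per channel,
  ReLU) produces a 1296-dimensional feature vector per frame (unpadded
  convolutions: 48 x 27 = 1296);
* two attention generators (identical two-layer dense networks, 2048
  hidden units, sigmoid output) transform the binary UES-opening mask
  into multiplicative gates of shape 90 x 1296 (applied to the CNN
  output) and 90 x 64 (applied to the RNN output);
* a 3-layer unidirectional GRU (64 units per layer) models temporal
  structure over the gated feature sequence;
* the gated RNN output sequence is flattened and passed through three
  128-unit ReLU layers (20% dropout after the first two) and a single
  sigmoid output unit.

Training minimizes mean squared error with Adam.  The whole network,
its backward pass and the optimizer are implemented on numpy arrays;
float32 is used for training and a float64 path supports numerical
gradient verification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .datasets import SwallowSample

__all__ = [
    "ModelConfig",
    "ModelParams",
    "init_params",
    "cnn_forward",
    "attention_forward",
    "rnn_forward",
    "head_forward",
    "forward",
    "predict",
    "mse_loss",
    "ape",
    "loss_and_gradients",
    "Adam",
    "train",
    "count_parameters",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    Defaults follow the published architecture; every field is
    overridable, and the derived dimensions (48 CNN channels, 1296
    features per chunk, 90 x 64 RNN output) follow from the fields.
    """

    chunk_len: int = 66
    channels_in: int = 3
    conv1_filters_per_channel: int = 16
    kernel_len: int = 5
    pool_size: int = 2
    pool_stride: int = 2
    T: int = 90
    gru_layers: int = 3
    gru_units: int = 64
    attn_hidden: int = 2048
    fc_units: int = 128
    fc_layers: int = 3
    dropout_rate: float = 0.20
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999

    # derived sizes -----------------------------------------------------
    @property
    def conv1_out_len(self) -> int:       # unpadded ("valid") convolution
        return self.chunk_len - self.kernel_len + 1

    @property
    def pool_out_len(self) -> int:
        return self.conv1_out_len // self.pool_stride

    @property
    def conv2_out_len(self) -> int:
        return self.pool_out_len - self.kernel_len + 1

    @property
    def cnn_channels(self) -> int:
        return self.conv1_filters_per_channel * self.channels_in

    @property
    def cnn_feature_dim(self) -> int:
        return self.cnn_channels * self.conv2_out_len

    @property
    def rnn_flat_dim(self) -> int:
        return self.T * self.gru_units

    def __post_init__(self):
        if self.conv2_out_len < 1:
            raise ValueError("chunk too short for two valid convolutions")


@dataclass
class ModelParams:
    """Learnable parameter collection plus the seed that initialized it."""

    arrays: dict
    seed: int = 0

    def copy(self) -> "ModelParams":
        return ModelParams({k: v.copy() for k, v in self.arrays.items()}, self.seed)

    def nbytes(self) -> int:
        return sum(v.nbytes for v in self.arrays.values())


def _arr(params) -> dict:
    return params.arrays if isinstance(params, ModelParams) else params


def count_parameters(params) -> int:
    return sum(v.size for v in _arr(params).values())


def _glorot(rng, shape, dtype):
    fan_in, fan_out = shape[0], shape[-1]
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def init_params(config: ModelConfig, seed: int = 0,
                dtype=np.float32) -> ModelParams:
    """Seeded Glorot-uniform initialization of every learnable array."""
    rng = np.random.default_rng(seed)
    c = config
    H, A, T, D = c.gru_units, c.attn_hidden, c.T, c.cnn_feature_dim
    p = {}
    p["conv1_w"] = _glorot(rng, (c.channels_in, c.conv1_filters_per_channel,
                                 c.kernel_len), dtype)
    p["conv1_b"] = np.zeros(c.cnn_channels, dtype=dtype)
    p["conv2_w"] = _glorot(rng, (c.cnn_channels, c.kernel_len), dtype)
    p["conv2_b"] = np.zeros(c.cnn_channels, dtype=dtype)
    for name, out_dim in (("attn_cnn", T * D), ("attn_rnn", T * H)):
        p[f"{name}_w1"] = _glorot(rng, (T, A), dtype)
        p[f"{name}_b1"] = np.zeros(A, dtype=dtype)
        p[f"{name}_w2"] = _glorot(rng, (A, out_dim), dtype)
        p[f"{name}_b2"] = np.zeros(out_dim, dtype=dtype)
    d_in = D
    for layer in range(c.gru_layers):
        p[f"gru{layer}_wx"] = _glorot(rng, (d_in, 3 * H), dtype)
        p[f"gru{layer}_wh_zr"] = _glorot(rng, (H, 2 * H), dtype)
        p[f"gru{layer}_wh_n"] = _glorot(rng, (H, H), dtype)
        p[f"gru{layer}_b"] = np.zeros(3 * H, dtype=dtype)
        d_in = H
    prev = c.rnn_flat_dim
    for layer in range(c.fc_layers):
        p[f"fc{layer}_w"] = _glorot(rng, (prev, c.fc_units), dtype)
        p[f"fc{layer}_b"] = np.zeros(c.fc_units, dtype=dtype)
        prev = c.fc_units
    p["out_w"] = _glorot(rng, (prev, 1), dtype)
    p["out_b"] = np.zeros(1, dtype=dtype)
    return ModelParams(p, seed)


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


# ---------------------------------------------------------------------------
# CNN
# ---------------------------------------------------------------------------

def _cnn_batch(x, params, config, cache=None):
    """Per-chunk CNN on a flat batch of chunks x: (N, chunk_len, C)."""
    p, c = _arr(params), config
    C, F, K = c.channels_in, c.conv1_filters_per_channel, c.kernel_len
    win1 = sliding_window_view(x, K, axis=1)          # (N, L1, C, K)
    z1 = np.einsum("nwck,cfk->nwcf", win1, p["conv1_w"], optimize=True)
    z1 += p["conv1_b"].reshape(C, F)
    a1 = np.maximum(z1, 0.0)
    Lp = c.pool_out_len
    a1p = a1[:, : Lp * c.pool_stride].reshape(-1, Lp, c.pool_stride, C, F)
    idx = np.argmax(a1p, axis=2)
    pooled = np.take_along_axis(a1p, idx[:, :, None], axis=2)[:, :, 0]
    pooled_flat = pooled.reshape(-1, Lp, c.cnn_channels)
    win2 = sliding_window_view(pooled_flat, K, axis=1)  # (N, L2, nch, K)
    z2 = np.einsum("nwck,ck->nwc", win2, p["conv2_w"], optimize=True)
    z2 += p["conv2_b"]
    a2 = np.maximum(z2, 0.0)
    feat = a2.reshape(-1, c.cnn_feature_dim)
    if cache is not None:
        cache.update(cnn_x=x, cnn_z1=z1, cnn_idx=idx, cnn_pooled=pooled_flat,
                     cnn_z2=z2)
    return feat


def _cnn_backward(dfeat, params, config, cache, grads):
    p, c = _arr(params), config
    C, F, K = c.channels_in, c.conv1_filters_per_channel, c.kernel_len
    Lp, L2 = c.pool_out_len, c.conv2_out_len
    N = dfeat.shape[0]
    dz2 = dfeat.reshape(N, L2, c.cnn_channels) * (cache["cnn_z2"] > 0)
    win2 = sliding_window_view(cache["cnn_pooled"], K, axis=1)
    grads["conv2_w"] = np.einsum("nwc,nwck->ck", dz2, win2, optimize=True)
    grads["conv2_b"] = dz2.sum(axis=(0, 1))
    dpool = np.zeros((N, Lp, c.cnn_channels), dtype=dz2.dtype)
    for k in range(K):
        dpool[:, k : k + L2] += dz2 * p["conv2_w"][:, k]
    dpool = dpool.reshape(N, Lp, C, F)
    da1p = np.zeros((N, Lp, c.pool_stride, C, F), dtype=dz2.dtype)
    np.put_along_axis(da1p, cache["cnn_idx"][:, :, None], dpool[:, :, None], axis=2)
    da1 = np.zeros((N, c.conv1_out_len, C, F), dtype=dz2.dtype)
    da1[:, : Lp * c.pool_stride] = da1p.reshape(N, Lp * c.pool_stride, C, F)
    dz1 = da1 * (cache["cnn_z1"] > 0)
    win1 = sliding_window_view(cache["cnn_x"], K, axis=1)
    grads["conv1_w"] = np.einsum("nwck,nwcf->cfk", win1, dz1, optimize=True)
    grads["conv1_b"] = dz1.sum(axis=(0, 1)).reshape(-1)


def cnn_forward(chunk, params, config: ModelConfig | None = None):
    """Feature vector (length ``cnn_feature_dim``) for one 66 x 3 chunk."""
    config = config or ModelConfig()
    chunk = np.asarray(chunk)
    if chunk.shape != (config.chunk_len, config.channels_in):
        raise ValueError(f"expected chunk of shape "
                         f"({config.chunk_len}, {config.channels_in})")
    return _cnn_batch(chunk[None], params, config)[0]


# ---------------------------------------------------------------------------
# attention generators
# ---------------------------------------------------------------------------

def _attn_batch(mask, params, config, name, out_dim, cache=None):
    p = _arr(params)
    h_pre = mask @ p[f"{name}_w1"] + p[f"{name}_b1"]
    h = np.maximum(h_pre, 0.0)
    s = h @ p[f"{name}_w2"] + p[f"{name}_b2"]
    a = _sigmoid(s)
    if cache is not None:
        cache[f"{name}_h"] = h
        cache[f"{name}_a"] = a
    return a.reshape(mask.shape[0], config.T, out_dim)


def _attn_backward(dA, mask, params, config, name, cache, grads):
    p = _arr(params)
    a = cache[f"{name}_a"]
    h = cache[f"{name}_h"]
    ds = dA.reshape(a.shape) * a * (1.0 - a)
    grads[f"{name}_w2"] = h.T @ ds
    grads[f"{name}_b2"] = ds.sum(axis=0)
    dh = (ds @ p[f"{name}_w2"].T) * (h > 0)
    grads[f"{name}_w1"] = mask.T @ dh
    grads[f"{name}_b1"] = dh.sum(axis=0)


def attention_forward(mask, params, config: ModelConfig | None = None):
    """CNN- and RNN-level attention gates for one binary mask (length T).

    Returns ``(cnn_attn, rnn_attn)`` of shapes (T, cnn_feature_dim) and
    (T, gru_units), entries strictly in (0, 1).
    """
    config = config or ModelConfig()
    mask = np.asarray(mask, dtype=np.result_type(np.float32, mask))
    if mask.shape != (config.T,):
        raise ValueError(f"expected mask of length {config.T}")
    a_cnn = _attn_batch(mask[None], params, config, "attn_cnn",
                        config.cnn_feature_dim)[0]
    a_rnn = _attn_batch(mask[None], params, config, "attn_rnn",
                        config.gru_units)[0]
    return a_cnn, a_rnn


# ---------------------------------------------------------------------------
# GRU stack
# ---------------------------------------------------------------------------

def _gru_layer_forward(x, params, config, layer, cache=None):
    """One unidirectional GRU layer over x: (B, T, D_in) -> (B, T, H).

    Cell equations (z = update gate, r = reset gate):
        z_t = sigmoid(W_xz x_t + W_hz h_{t-1} + b_z)
        r_t = sigmoid(W_xr x_t + W_hr h_{t-1} + b_r)
        n_t = tanh(W_xn x_t + W_hn (r_t * h_{t-1}) + b_n)
        h_t = (1 - z_t) * n_t + z_t * h_{t-1}
    with h_0 = 0.
    """
    p, H = _arr(params), config.gru_units
    B, T, _ = x.shape
    xw = x.reshape(B * T, -1) @ p[f"gru{layer}_wx"]
    xw = xw.reshape(B, T, 3 * H) + p[f"gru{layer}_b"]
    wh_zr, wh_n = p[f"gru{layer}_wh_zr"], p[f"gru{layer}_wh_n"]
    h = np.zeros((B, H), dtype=x.dtype)
    hs = np.empty((B, T, H), dtype=x.dtype)
    zs = np.empty_like(hs)
    rs = np.empty_like(hs)
    ns = np.empty_like(hs)
    hprev = np.empty_like(hs)
    for t in range(T):
        zr = _sigmoid(xw[:, t, : 2 * H] + h @ wh_zr)
        z, r = zr[:, :H], zr[:, H:]
        n = np.tanh(xw[:, t, 2 * H :] + (r * h) @ wh_n)
        hprev[:, t] = h
        h = (1.0 - z) * n + z * h
        hs[:, t], zs[:, t], rs[:, t], ns[:, t] = h, z, r, n
    if cache is not None:
        cache[f"gru{layer}_x"] = x
        cache[f"gru{layer}_state"] = (hprev, zs, rs, ns)
    return hs


def _gru_layer_backward(dH, params, config, layer, cache, grads):
    """BPTT through one GRU layer; returns gradient w.r.t. its input."""
    p, Hn = _arr(params), config.gru_units
    x = cache[f"gru{layer}_x"]
    hprev, zs, rs, ns = cache[f"gru{layer}_state"]
    wh_zr, wh_n = p[f"gru{layer}_wh_zr"], p[f"gru{layer}_wh_n"]
    B, T, _ = x.shape
    dxw = np.zeros((B, T, 3 * Hn), dtype=x.dtype)
    d_wh_zr = np.zeros_like(wh_zr)
    d_wh_n = np.zeros_like(wh_n)
    dh = np.zeros((B, Hn), dtype=x.dtype)
    for t in range(T - 1, -1, -1):
        dh_t = dH[:, t] + dh
        hp, z, r, n = hprev[:, t], zs[:, t], rs[:, t], ns[:, t]
        dz = dh_t * (hp - n)
        dn = dh_t * (1.0 - z)
        dh = dh_t * z
        dn_pre = dn * (1.0 - n * n)
        drh = dn_pre @ wh_n.T
        dr = drh * hp
        dh += drh * r
        dz_pre = dz * z * (1.0 - z)
        dr_pre = dr * r * (1.0 - r)
        dzr = np.concatenate([dz_pre, dr_pre], axis=1)
        dh += dzr @ wh_zr.T
        d_wh_zr += hp.T @ dzr
        d_wh_n += (r * hp).T @ dn_pre
        dxw[:, t, : 2 * Hn] = dzr
        dxw[:, t, 2 * Hn :] = dn_pre
    grads[f"gru{layer}_wh_zr"] = d_wh_zr
    grads[f"gru{layer}_wh_n"] = d_wh_n
    grads[f"gru{layer}_b"] = dxw.sum(axis=(0, 1))
    grads[f"gru{layer}_wx"] = x.reshape(B * T, -1).T @ dxw.reshape(B * T, -1)
    return (dxw.reshape(B * T, -1) @ p[f"gru{layer}_wx"].T).reshape(x.shape)


def _gru_stack_forward(x, params, config, cache=None):
    out = x
    for layer in range(config.gru_layers):
        out = _gru_layer_forward(out, params, config, layer, cache)
    return out


def rnn_forward(x_seq, params, config: ModelConfig | None = None):
    """Per-step outputs (T, gru_units) of the 3-layer GRU for one sequence."""
    config = config or ModelConfig()
    x_seq = np.asarray(x_seq)
    if x_seq.shape != (config.T, config.cnn_feature_dim):
        raise ValueError(f"expected input of shape "
                         f"({config.T}, {config.cnn_feature_dim})")
    return _gru_stack_forward(x_seq[None], params, config)[0]


# ---------------------------------------------------------------------------
# fully connected head
# ---------------------------------------------------------------------------

def _head_batch(u, params, config, cache=None, dropout_rng=None):
    """u: (B, rnn_flat_dim) -> predictions (B,).  Dropout (rate 20%) acts
    after the first two hidden layers only when ``dropout_rng`` is given
    (training); inference is deterministic."""
    p, c = _arr(params), config
    acts, masks = [], []
    h = u
    for layer in range(c.fc_layers):
        h = np.maximum(h @ p[f"fc{layer}_w"] + p[f"fc{layer}_b"], 0.0)
        acts.append(h)
        if dropout_rng is not None and layer < c.fc_layers - 1 and c.dropout_rate > 0:
            keep = (dropout_rng.random(h.shape) >= c.dropout_rate)
            m = keep.astype(h.dtype) / (1.0 - c.dropout_rate)
        else:
            m = None
        masks.append(m)
        if m is not None:
            h = h * m
    o = h @ p["out_w"] + p["out_b"]
    pred = _sigmoid(o[:, 0])
    if cache is not None:
        cache.update(head_u=u, head_acts=acts, head_masks=masks, head_pred=pred)
    return pred


def _head_backward(dpred, params, config, cache, grads):
    p, c = _arr(params), config
    pred = cache["head_pred"]
    acts, masks = cache["head_acts"], cache["head_masks"]
    do = (dpred * pred * (1.0 - pred))[:, None]
    last = acts[-1] if masks[-1] is None else acts[-1] * masks[-1]
    grads["out_w"] = last.T @ do
    grads["out_b"] = do.sum(axis=0)
    dh = do @ p["out_w"].T
    for layer in range(c.fc_layers - 1, -1, -1):
        if masks[layer] is not None:
            dh = dh * masks[layer]
        dh = dh * (acts[layer] > 0)
        below = cache["head_u"] if layer == 0 else (
            acts[layer - 1] if masks[layer - 1] is None
            else acts[layer - 1] * masks[layer - 1])
        grads[f"fc{layer}_w"] = below.T @ dh
        grads[f"fc{layer}_b"] = dh.sum(axis=0)
        dh = dh @ p[f"fc{layer}_w"].T
    return dh  # gradient w.r.t. the flattened gated RNN sequence


def head_forward(y_masked, params, config: ModelConfig | None = None) -> float:
    """Distension prediction in (0, 1) from one gated RNN output sequence
    ((T, gru_units) or already flattened)."""
    config = config or ModelConfig()
    u = np.asarray(y_masked).reshape(1, -1)
    if u.shape[1] != config.rnn_flat_dim:
        raise ValueError(f"expected {config.rnn_flat_dim} flattened features")
    return float(_head_batch(u, params, config)[0])


# ---------------------------------------------------------------------------
# full network
# ---------------------------------------------------------------------------

def _forward_batch(chunks, masks, params, config, cache=None, dropout_rng=None):
    """chunks: (B, T, chunk_len, C); masks: (B, T) -> predictions (B,)."""
    B, T = chunks.shape[:2]
    feat = _cnn_batch(chunks.reshape(B * T, config.chunk_len, config.channels_in),
                      params, config, cache)
    feat = feat.reshape(B, T, config.cnn_feature_dim)
    a_cnn = _attn_batch(masks, params, config, "attn_cnn",
                        config.cnn_feature_dim, cache)
    xm = feat * a_cnn
    ys = _gru_stack_forward(xm, params, config, cache)
    a_rnn = _attn_batch(masks, params, config, "attn_rnn", config.gru_units, cache)
    ym = ys * a_rnn
    if cache is not None:
        cache.update(feat=feat, a_cnn=a_cnn, ys=ys, a_rnn=a_rnn, masks=masks)
    return _head_batch(ym.reshape(B, -1), params, config, cache, dropout_rng)


def forward(sample: SwallowSample, params, config: ModelConfig | None = None) -> float:
    """End-to-end prediction for one swallow sample."""
    config = config or ModelConfig()
    return float(_forward_batch(sample.chunks[None].astype(_dtype_of(params)),
                                sample.mask[None].astype(_dtype_of(params)),
                                params, config)[0])


def _dtype_of(params):
    return next(iter(_arr(params).values())).dtype


def _stack(samples, dtype):
    X = np.stack([s.chunks for s in samples]).astype(dtype)
    M = np.stack([s.mask for s in samples]).astype(dtype)
    y = np.array([s.target_ratio for s in samples], dtype=dtype)
    return X, M, y


def predict(samples, params, config: ModelConfig | None = None,
            batch_size: int = 32) -> np.ndarray:
    """Deterministic (dropout-free) predictions for a list of samples."""
    config = config or ModelConfig()
    dtype = _dtype_of(params)
    out = []
    for i in range(0, len(samples), batch_size):
        X, M, _ = _stack(samples[i : i + batch_size], dtype)
        out.append(_forward_batch(X, M, params, config))
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# loss, metric
# ---------------------------------------------------------------------------

def mse_loss(preds, truths) -> float:
    """Mean squared error between predictions and ground-truth ratios."""
    preds = np.asarray(preds, dtype=float).ravel()
    truths = np.asarray(truths, dtype=float).ravel()
    if preds.size == 0 or preds.size != truths.size:
        raise ValueError("predictions and truths must be equal-length and non-empty")
    return float(np.mean((preds - truths) ** 2))


def ape(prediction, truth):
    """Absolute percentage error: |prediction - truth| * 100 / truth."""
    prediction = np.asarray(prediction, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if np.any(truth <= 0):
        raise ValueError("APE is undefined for non-positive ground truth")
    result = np.abs(prediction - truth) * 100.0 / truth
    return float(result) if result.ndim == 0 else result


# ---------------------------------------------------------------------------
# backward pass
# ---------------------------------------------------------------------------

def loss_and_gradients(chunks, masks, targets, params,
                       config: ModelConfig, dropout_rng=None):
    """MSE loss and gradients for a batch; dropout active only when a
    generator is supplied."""
    cache: dict = {}
    preds = _forward_batch(chunks, masks, params, config, cache, dropout_rng)
    B = preds.shape[0]
    loss = float(np.mean((preds - targets) ** 2))
    dpred = (2.0 / B) * (preds - targets)

    grads: dict = {}
    dym_flat = _head_backward(dpred, params, config, cache, grads)
    dym = dym_flat.reshape(B, config.T, config.gru_units)
    dys = dym * cache["a_rnn"]
    _attn_backward(dym * cache["ys"], cache["masks"], params, config,
                   "attn_rnn", cache, grads)
    dx = dys
    for layer in range(config.gru_layers - 1, -1, -1):
        dx = _gru_layer_backward(dx, params, config, layer, cache, grads)
    dfeat = dx * cache["a_cnn"]
    _attn_backward(dx * cache["feat"], cache["masks"], params, config,
                   "attn_cnn", cache, grads)
    _cnn_backward(dfeat.reshape(B * config.T, -1), params, config, cache, grads)
    return loss, preds, grads


# ---------------------------------------------------------------------------
# Adam optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with bias correction; large arrays are updated in slices to
    bound temporary memory."""

    _BLOCK = 1 << 22  # elements per update slice

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        a = _arr(params)
        self.m = {k: np.zeros_like(v) for k, v in a.items()}
        self.v = {k: np.zeros_like(v) for k, v in a.items()}

    def step(self, params, grads):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        scale = self.lr / bc1
        for k, w in _arr(params).items():
            g = grads[k].reshape(-1)
            wf = w.reshape(-1)
            mf, vf = self.m[k].reshape(-1), self.v[k].reshape(-1)
            for i in range(0, wf.size, self._BLOCK):
                s = slice(i, i + self._BLOCK)
                mf[s] *= self.b1
                mf[s] += (1.0 - self.b1) * g[s]
                vf[s] *= self.b2
                vf[s] += (1.0 - self.b2) * g[s] ** 2
                wf[s] -= scale * mf[s] / (np.sqrt(vf[s] / bc2) + self.eps)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train(samples, config: ModelConfig | None = None, seed: int = 0,
          params: ModelParams | None = None, dtype=np.float32,
          verbose: bool = False, callback=None):
    """Train on a list of :class:`SwallowSample` with Adam on MSE.

    Seeded initialization, epoch shuffling and dropout make runs with the
    same seed bit-reproducible.  Returns ``(params, history)`` where
    ``history`` has one record per epoch with the mean training MSE and
    mean training APE.  ``callback(epoch, params, record)`` runs after
    every epoch (e.g. for held-out monitoring).
    """
    if not samples:
        raise ValueError("empty training set")
    config = config or ModelConfig()
    rng = np.random.default_rng(seed)
    if params is None:
        params = init_params(config, seed=int(rng.integers(2**31)), dtype=dtype)
    opt = Adam(params, lr=config.learning_rate, beta1=config.beta1,
               beta2=config.beta2)
    X, M, y = _stack(samples, dtype)
    n = len(samples)
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses, all_preds, all_truth = [], [], []
        for i in range(0, n, config.batch_size):
            sel = order[i : i + config.batch_size]
            loss, preds, grads = loss_and_gradients(
                X[sel], M[sel], y[sel], params, config, dropout_rng=rng)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {i // config.batch_size}"
                )
            opt.step(params, grads)
            losses.append(loss)
            all_preds.append(preds)
            all_truth.append(y[sel])
        preds = np.concatenate(all_preds)
        truth = np.concatenate(all_truth)
        record = dict(epoch=epoch, mse=float(np.mean(losses)),
                      mean_ape=float(np.mean(ape(preds, truth))))
        history.append(record)
        if verbose:
            print(f"epoch {epoch:3d}  mse {record['mse']:.5f}  "
                  f"ape {record['mean_ape']:.2f}%")
        if callback is not None:
            callback(epoch, params, record)
    return params, history
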