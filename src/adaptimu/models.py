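"""Ensemble branches: quantized depthwise-separable 1D-CNN and pruned LSTM.

Both branches are small fixed topologies implemented directly in numpy with
hand-written backprop, which keeps inference dependency-free and makes the
int8 quantization and magnitude-pruning paths explicit:

* CNN — three blocks of depthwise-separable convolution (kernel sizes 5, 3,
  3; channels 32 -> 64 -> 128; stride 2 each) with batch normalization and
  ReLU, global temporal average pooling, and a linear projection to two
  logits.  Following the fused-block equation the pointwise (1x1) stage is
  applied before the depthwise stage by default; ``conv_order =
  "conventional"`` restores the usual depthwise-then-pointwise order.
* LSTM — two stacked layers (64 then 32 hidden units) with 0.2 dropout
  between them at training time, last-step readout to two logits, and
  magnitude-based unstructured pruning masks on the input and recurrent
  weight matrices (biases and projections exempt).

Quantization is post-training, symmetric, per-tensor for weights, with
per-layer activation scales calibrated on a held-out batch; batch norm is
folded into the convolution weights on the quantized path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

# ---------------------------------------------------------------------------
# quantization


@dataclass
class QuantizedTensor:
    q: np.ndarray           # int8 values in [-127, 127]
    scale: float
    zero_point: int = 0

    def dequantize(self) -> np.ndarray:
        return self.q.astype(np.float64) * self.scale


def quantize_tensor(x: np.ndarray) -> QuantizedTensor:
    """Symmetric per-tensor affine quantization to int8 in [-127, 127]."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("cannot quantize non-finite values")
    amax = float(np.max(np.abs(x))) if x.size else 0.0
    scale = amax / 127.0 if amax > 0 else 1.0
    q = np.clip(np.round(x / scale), -127, 127).astype(np.int8)
    return QuantizedTensor(q=q, scale=scale)


def dequantize(qt: QuantizedTensor) -> np.ndarray:
    return qt.dequantize()


def _fake_quant(x: np.ndarray, scale: float | None = None) -> np.ndarray:
    """Round-trip through the int8 grid (simulated-quantization arithmetic)."""
    if scale is None:
        return quantize_tensor(x).dequantize()
    return np.clip(np.round(x / scale), -127, 127) * scale


# ---------------------------------------------------------------------------
# CNN branch


@dataclass
class CnnBlock:
    Wp: np.ndarray          # pointwise kernel (C_in, C_out)
    Wd: np.ndarray          # depthwise kernel (k, C_dw)
    gamma: np.ndarray
    beta: np.ndarray
    run_mean: np.ndarray
    run_var: np.ndarray


@dataclass
class CnnParams:
    blocks: list[CnnBlock]
    Wc: np.ndarray          # classifier projection (C_last, 2)
    bc: np.ndarray
    conv_order: str = "as_printed"     # or "conventional"
    input_len: int = 40
    act_scales: list[float] | None = None  # input + per-block, calibration
    bn_eps: float = 1e-5

    @property
    def in_channels(self) -> int:
        b = self.blocks[0]
        return b.Wp.shape[0] if self.conv_order == "as_printed" else b.Wd.shape[1]


CNN_KERNELS = (5, 3, 3)
CNN_CHANNELS = (32, 64, 128)


def init_cnn(in_channels: int = 6, seed: int = 0,
             conv_order: str = "as_printed", input_len: int = 40,
             kernels=CNN_KERNELS, channels=CNN_CHANNELS,
             n_classes: int = 2) -> CnnParams:
    if conv_order not in ("as_printed", "conventional"):
        raise ValueError("conv_order must be 'as_printed' or 'conventional'")
    rng = np.random.default_rng(seed)
    blocks = []
    c_in = in_channels
    for k, c_out in zip(kernels, channels):
        if conv_order == "as_printed":
            wp = rng.standard_normal((c_in, c_out)) * np.sqrt(2.0 / c_in)
            wd = rng.standard_normal((k, c_out)) * np.sqrt(2.0 / k)
        else:
            wd = rng.standard_normal((k, c_in)) * np.sqrt(2.0 / k)
            wp = rng.standard_normal((c_in, c_out)) * np.sqrt(2.0 / c_in)
        blocks.append(CnnBlock(
            Wp=wp, Wd=wd,
            gamma=np.ones(c_out), beta=np.zeros(c_out),
            run_mean=np.zeros(c_out), run_var=np.ones(c_out)))
        c_in = c_out
    wc = rng.standard_normal((c_in, n_classes)) * np.sqrt(1.0 / c_in)
    return CnnParams(blocks=blocks, Wc=wc, bc=np.zeros(n_classes),
                     conv_order=conv_order, input_len=input_len)


def _same_pad(T: int, k: int, stride: int) -> tuple[int, int]:
    out = -(-T // stride)                      # ceil division
    total = max((out - 1) * stride + k - T, 0)
    left = total // 2
    return left, total - left


def _dwconv(z: np.ndarray, Wd: np.ndarray, stride: int) -> np.ndarray:
    """Depthwise 1D convolution of padded input z (N, Tp, C), Wd (k, C)."""
    k = Wd.shape[0]
    t_out = (z.shape[1] - k) // stride + 1
    out = np.zeros((z.shape[0], t_out, z.shape[2]))
    for j in range(k):
        out += Wd[j] * z[:, j:j + stride * t_out:stride, :]
    return out


def _dwconv_backward(dout: np.ndarray, z: np.ndarray, Wd: np.ndarray,
                     stride: int) -> tuple[np.ndarray, np.ndarray]:
    k = Wd.shape[0]
    t_out = dout.shape[1]
    dz = np.zeros_like(z)
    dWd = np.zeros_like(Wd)
    for j in range(k):
        sl = slice(j, j + stride * t_out, stride)
        dz[:, sl, :] += Wd[j] * dout
        dWd[j] = np.sum(z[:, sl, :] * dout, axis=(0, 1))
    return dz, dWd


def depthwise_separable_conv(h: np.ndarray, Wd: np.ndarray, Wp: np.ndarray,
                             stride: int = 2,
                             order: str = "as_printed") -> np.ndarray:
    """One depthwise-separable convolution with ReLU, 'same' padding.

    ``as_printed`` applies the pointwise (1x1) kernel first and the
    depthwise kernel second, ReLU(Wd * (Wp * h)); ``conventional`` swaps
    the two stages.  Temporal length maps to ceil(T / stride).
    """
    h = np.asarray(h, dtype=float)
    squeeze = h.ndim == 2
    if squeeze:
        h = h[None]
    k = Wd.shape[0]
    if h.shape[1] < k:
        raise ValueError("input shorter than the depthwise kernel")
    left, right = _same_pad(h.shape[1], k, stride)

    def pad(x):
        return np.pad(x, ((0, 0), (left, right), (0, 0)))

    if order == "as_printed":
        out = _dwconv(pad(h @ Wp), Wd, stride)
    elif order == "conventional":
        out = _dwconv(pad(h), Wd, stride) @ Wp
    else:
        raise ValueError("order must be 'as_printed' or 'conventional'")
    out = np.maximum(out, 0.0)
    return out[0] if squeeze else out


def cnn_forward_batch(X: np.ndarray, params: CnnParams, training: bool = False,
                      momentum: float = 0.1):
    """Float forward pass on a batch (N, T, C); returns (logits, cache)."""
    X = np.asarray(X, dtype=float)
    h = X
    cache = {"X": X, "blocks": []}
    for blk in params.blocks:
        k, stride = blk.Wd.shape[0], 2
        bc = {}
        if params.conv_order == "as_printed":
            a = h @ blk.Wp
            left, right = _same_pad(a.shape[1], k, stride)
            ap = np.pad(a, ((0, 0), (left, right), (0, 0)))
            z = _dwconv(ap, blk.Wd, stride)
            bc.update(h_in=h, ap=ap, pad=(left, right))
        else:
            left, right = _same_pad(h.shape[1], k, stride)
            hp = np.pad(h, ((0, 0), (left, right), (0, 0)))
            d = _dwconv(hp, blk.Wd, stride)
            z = d @ blk.Wp
            bc.update(h_in=h, hp=hp, d=d, pad=(left, right))
        if training:
            mu = z.mean(axis=(0, 1))
            var = z.var(axis=(0, 1))
            blk.run_mean = (1 - momentum) * blk.run_mean + momentum * mu
            blk.run_var = (1 - momentum) * blk.run_var + momentum * var
        else:
            mu, var = blk.run_mean, blk.run_var
        inv_sd = 1.0 / np.sqrt(var + params.bn_eps)
        xhat = (z - mu) * inv_sd
        out = np.maximum(blk.gamma * xhat + blk.beta, 0.0)
        bc.update(z=z, xhat=xhat, inv_sd=inv_sd, out=out)
        cache["blocks"].append(bc)
        h = out
    pooled = h.mean(axis=1)
    logits = pooled @ params.Wc + params.bc
    cache.update(h_final=h, pooled=pooled)
    return logits, cache


def cnn_backward_batch(dlogits: np.ndarray, cache, params: CnnParams) -> dict:
    grads = {"Wc": cache["pooled"].T @ dlogits, "bc": dlogits.sum(axis=0)}
    t_final = cache["h_final"].shape[1]
    dh = (dlogits @ params.Wc.T)[:, None, :] * np.ones((1, t_final, 1)) / t_final
    for li in range(len(params.blocks) - 1, -1, -1):
        blk, bc = params.blocks[li], cache["blocks"][li]
        dout = dh * (bc["out"] > 0)
        # batch-norm backward (batch statistics)
        n_eff = dout.shape[0] * dout.shape[1]
        dgamma = np.sum(dout * bc["xhat"], axis=(0, 1))
        dbeta = np.sum(dout, axis=(0, 1))
        dxhat = dout * blk.gamma
        dz = bc["inv_sd"] * (
            dxhat - dxhat.mean(axis=(0, 1))
            - bc["xhat"] * np.mean(dxhat * bc["xhat"], axis=(0, 1)))
        _ = n_eff
        left, right = bc["pad"]
        if params.conv_order == "as_printed":
            dap, dWd = _dwconv_backward(dz, bc["ap"], blk.Wd, 2)
            da = dap[:, left:dap.shape[1] - right, :]
            dWp = np.einsum("ntc,ntd->cd", bc["h_in"], da)
            dh = da @ blk.Wp.T
        else:
            dd = dz @ blk.Wp.T
            dWp = np.einsum("ntc,ntd->cd", bc["d"], dz)
            dhp, dWd = _dwconv_backward(dd, bc["hp"], blk.Wd, 2)
            dh = dhp[:, left:dhp.shape[1] - right, :]
        grads[f"b{li}_Wp"] = dWp
        grads[f"b{li}_Wd"] = dWd
        grads[f"b{li}_gamma"] = dgamma
        grads[f"b{li}_beta"] = dbeta
    return grads


def calibrate_activation_scales(params: CnnParams, X_calib: np.ndarray) -> None:
    """Record per-layer activation scales from a held-out calibration batch."""
    X_calib = np.asarray(X_calib, dtype=float)
    scales = [max(float(np.max(np.abs(X_calib))), 1e-12) / 127.0]
    h = X_calib
    for blk in params.blocks:
        h = _bn_relu_block(h, blk, params)
        scales.append(max(float(np.max(np.abs(h))), 1e-12) / 127.0)
    params.act_scales = scales


def _bn_relu_block(h, blk: CnnBlock, params: CnnParams):
    k, stride = blk.Wd.shape[0], 2
    if params.conv_order == "as_printed":
        a = h @ blk.Wp
        left, right = _same_pad(a.shape[1], k, stride)
        z = _dwconv(np.pad(a, ((0, 0), (left, right), (0, 0))), blk.Wd, stride)
    else:
        left, right = _same_pad(h.shape[1], k, stride)
        z = _dwconv(np.pad(h, ((0, 0), (left, right), (0, 0))), blk.Wd, stride) @ blk.Wp
    inv_sd = 1.0 / np.sqrt(blk.run_var + params.bn_eps)
    return np.maximum(blk.gamma * (z - blk.run_mean) * inv_sd + blk.beta, 0.0)


def _fold_bn(blk: CnnBlock, params: CnnParams):
    """Fold batch norm into the block's final conv stage: returns
    (Wp', Wd', bias) such that relu(stage(x) + bias) matches bn+relu."""
    s = blk.gamma / np.sqrt(blk.run_var + params.bn_eps)
    bias = blk.beta - blk.run_mean * s
    if params.conv_order == "as_printed":
        return blk.Wp, blk.Wd * s, bias      # depthwise is last; scale (k, C)
    return blk.Wp * s, blk.Wd, bias          # pointwise is last; scale cols


def cnn_forward_quantized(X: np.ndarray, params: CnnParams) -> np.ndarray:
    """Simulated-int8 inference: int8 weights (batch norm folded) and
    per-layer int8 activations with calibrated scales."""
    if params.act_scales is None:
        raise ValueError("quantized path requires activation calibration "
                         "(call calibrate_activation_scales first)")
    X = np.asarray(X, dtype=float)
    squeeze = X.ndim == 2
    if squeeze:
        X = X[None]
    h = _fake_quant(X, params.act_scales[0])
    for li, blk in enumerate(params.blocks):
        wp, wd, bias = _fold_bn(blk, params)
        wp_q, wd_q = _fake_quant(wp), _fake_quant(wd)
        k, stride = wd.shape[0], 2
        if params.conv_order == "as_printed":
            a = h @ wp_q
            left, right = _same_pad(a.shape[1], k, stride)
            z = _dwconv(np.pad(a, ((0, 0), (left, right), (0, 0))), wd_q, stride)
        else:
            left, right = _same_pad(h.shape[1], k, stride)
            z = _dwconv(np.pad(h, ((0, 0), (left, right), (0, 0))), wd_q, stride) @ wp_q
        h = np.maximum(z + bias, 0.0)
        h = _fake_quant(h, params.act_scales[li + 1])
    pooled = h.mean(axis=1)
    logits = pooled @ _fake_quant(params.Wc) + params.bc
    return logits[0] if squeeze else logits


def cnn_forward(window: np.ndarray, params: CnnParams,
                quantized: bool = False) -> np.ndarray:
    """Class logits for one window (input_len x channels)."""
    window = np.asarray(window, dtype=float)
    if window.shape[0] != params.input_len:
        raise ValueError(
            f"window length {window.shape[0]} != expected {params.input_len}")
    if quantized:
        return cnn_forward_quantized(window, params)
    logits, _ = cnn_forward_batch(window[None], params, training=False)
    return logits[0]


def cnn_shape_trace(params: CnnParams) -> list[tuple[int, int]]:
    """Temporal length / channel count after each block (ceil(L/2) rule)."""
    t = params.input_len
    trace = []
    for blk in params.blocks:
        t = -(-t // 2)
        c = blk.Wd.shape[1] if params.conv_order == "as_printed" else blk.Wp.shape[1]
        trace.append((t, c))
    return trace


# ---------------------------------------------------------------------------
# LSTM branch


@dataclass
class LstmLayer:
    W: np.ndarray           # input weights (C_in, 4H), gate order i,f,g,o
    U: np.ndarray           # recurrent weights (H, 4H)
    b: np.ndarray
    mask_W: np.ndarray = field(default=None)
    mask_U: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.mask_W is None:
            self.mask_W = np.ones_like(self.W)
        if self.mask_U is None:
            self.mask_U = np.ones_like(self.U)

    @property
    def hidden(self) -> int:
        return self.U.shape[0]


@dataclass
class LstmParams:
    layers: list[LstmLayer]
    Wl: np.ndarray          # readout projection (H_last, 2)
    bl: np.ndarray
    dropout: float = 0.2

    @property
    def hidden_sizes(self) -> tuple[int, ...]:
        return tuple(layer.hidden for layer in self.layers)


LSTM_HIDDEN = (64, 32)


def init_lstm(in_channels: int = 6, hidden=LSTM_HIDDEN, seed: int = 0,
              dropout: float = 0.2, n_classes: int = 2) -> LstmParams:
    rng = np.random.default_rng(seed)
    layers = []
    c_in = in_channels
    for h in hidden:
        w = rng.standard_normal((c_in, 4 * h)) / np.sqrt(c_in)
        u = rng.standard_normal((h, 4 * h)) / np.sqrt(h)
        b = np.zeros(4 * h)
        b[h:2 * h] = 1.0     # forget-gate bias
        layers.append(LstmLayer(W=w, U=u, b=b))
        c_in = h
    wl = rng.standard_normal((c_in, n_classes)) / np.sqrt(c_in)
    return LstmParams(layers=layers, Wl=wl, bl=np.zeros(n_classes),
                      dropout=dropout)


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _cell_step(x, h, c, layer: LstmLayer):
    hdim = layer.hidden
    gates = x @ (layer.W * layer.mask_W) + h @ (layer.U * layer.mask_U) + layer.b
    i = _sigmoid(gates[..., :hdim])
    f = _sigmoid(gates[..., hdim:2 * hdim])
    g = np.tanh(gates[..., 2 * hdim:3 * hdim])
    o = _sigmoid(gates[..., 3 * hdim:])
    c_new = f * c + i * g
    h_new = o * np.tanh(c_new)
    return h_new, c_new, (i, f, g, o)


def lstm_forward(x_t: np.ndarray, state, params: LstmParams):
    """One recurrent step through both layers (inference, no dropout).

    ``state`` is ((h1, c1), (h2, c2)); pass None for a zero state.
    Returns (h_top, new_state)."""
    x_t = np.asarray(x_t, dtype=float)
    if state is None:
        state = tuple((np.zeros(layer.hidden), np.zeros(layer.hidden))
                      for layer in params.layers)
    if len(state) != len(params.layers) or any(
            s[0].shape[-1] != layer.hidden
            for s, layer in zip(state, params.layers)):
        raise ValueError("state dimensions do not match LSTM topology")
    new_state = []
    inp = x_t
    for layer, (h, c) in zip(params.layers, state):
        h, c, _ = _cell_step(inp, h, c, layer)
        new_state.append((h, c))
        inp = h
    return inp, tuple(new_state)


def lstm_logits(h_top: np.ndarray, params: LstmParams) -> np.ndarray:
    return h_top @ params.Wl + params.bl


def lstm_forward_seq(X: np.ndarray, params: LstmParams, training: bool = False,
                     rng: np.random.Generator | None = None):
    """Full-sequence forward on a batch (N, T, C) with last-step readout."""
    X = np.asarray(X, dtype=float)
    n, t, _ = X.shape
    cache = {"X": X, "layers": []}
    inp = X
    for li, layer in enumerate(params.layers):
        hdim = layer.hidden
        h = np.zeros((n, hdim))
        c = np.zeros((n, hdim))
        steps = []
        H = np.empty((n, t, hdim))
        for ti in range(t):
            h_prev, c_prev = h, c
            h, c, gates = _cell_step(inp[:, ti], h, c, layer)
            H[:, ti] = h
            steps.append((inp[:, ti], h_prev, c_prev, c, gates))
        drop_mask = None
        out = H
        if training and params.dropout > 0 and li < len(params.layers) - 1:
            if rng is None:
                rng = np.random.default_rng(0)
            keep = 1.0 - params.dropout
            drop_mask = (rng.uniform(size=H.shape) < keep) / keep
            out = H * drop_mask
        cache["layers"].append(
            {"steps": steps, "H": H, "drop_mask": drop_mask, "inp": inp})
        inp = out
    logits = inp[:, -1] @ params.Wl + params.bl
    cache["h_last"] = inp[:, -1]
    return logits, cache


def _lstm_layer_backward(dH: np.ndarray, lc, layer: LstmLayer):
    n, t, hdim = dH.shape
    Wm = layer.W * layer.mask_W
    Um = layer.U * layer.mask_U
    dW = np.zeros_like(layer.W)
    dU = np.zeros_like(layer.U)
    db = np.zeros_like(layer.b)
    dX = np.empty((n, t, layer.W.shape[0]))
    dh_next = np.zeros((n, hdim))
    dc_next = np.zeros((n, hdim))
    for ti in range(t - 1, -1, -1):
        x_t, h_prev, c_prev, c, (i, f, g, o) = lc["steps"][ti]
        dh = dH[:, ti] + dh_next
        tc = np.tanh(c)
        do = dh * tc
        dc = dh * o * (1 - tc * tc) + dc_next
        di, df, dg = dc * g, dc * c_prev, dc * i
        dc_next = dc * f
        dgates = np.concatenate([
            di * i * (1 - i), df * f * (1 - f),
            dg * (1 - g * g), do * o * (1 - o)], axis=1)
        dW += x_t.T @ dgates
        dU += h_prev.T @ dgates
        db += dgates.sum(axis=0)
        dX[:, ti] = dgates @ Wm.T
        dh_next = dgates @ Um.T
    # gradients of masked weights are masked: pruned entries stay zero
    return dW * layer.mask_W, dU * layer.mask_U, db, dX


def lstm_backward_seq(dlogits: np.ndarray, cache, params: LstmParams) -> dict:
    grads = {"Wl": cache["h_last"].T @ dlogits, "bl": dlogits.sum(axis=0)}
    top = len(params.layers) - 1
    n, t = cache["layers"][0]["H"].shape[:2]
    dH_above = None
    for li in range(top, -1, -1):
        lc = cache["layers"][li]
        hdim = params.layers[li].hidden
        dH = np.zeros((n, t, hdim))
        if li == top:
            dH[:, -1] = dlogits @ params.Wl.T
        else:
            dH = dH_above
            if lc["drop_mask"] is not None:
                dH = dH * lc["drop_mask"]
        dW, dU, db, dX = _lstm_layer_backward(dH, lc, params.layers[li])
        grads[f"l{li}_W"] = dW
        grads[f"l{li}_U"] = dU
        grads[f"l{li}_b"] = db
        dH_above = dX
    return grads


# ---------------------------------------------------------------------------
# magnitude pruning


def prune_mask(w: np.ndarray, ratio: float) -> np.ndarray:
    """Mask zeroing the floor(ratio * n) smallest-magnitude entries of w."""
    if not (0.0 <= ratio < 1.0):
        raise ValueError("prune ratio must be in [0, 1)")
    n = w.size
    n_zero = int(np.floor(ratio * n))
    mask = np.ones(n)
    if n_zero > 0:
        order = np.argsort(np.abs(w).ravel(), kind="stable")
        mask[order[:n_zero]] = 0.0
    return mask.reshape(w.shape)


def magnitude_prune(params: LstmParams, ratio: float) -> LstmParams:
    """Re-prune from the (dense) weights: returns a copy whose input and
    recurrent matrices carry fresh magnitude masks at ``ratio``."""
    layers = [replace(layer,
                      W=layer.W.copy(), U=layer.U.copy(),
                      mask_W=prune_mask(layer.W, ratio),
                      mask_U=prune_mask(layer.U, ratio))
              for layer in params.layers]
    return replace(params, layers=layers, Wl=params.Wl.copy(),
                   bl=params.bl.copy())


def sparsity(params: LstmParams) -> float:
    """Fraction of prunable (input + recurrent) weights currently masked."""
    zeros = total = 0
    for layer in params.layers:
        zeros += (layer.mask_W == 0).sum() + (layer.mask_U == 0).sum()
        total += layer.mask_W.size + layer.mask_U.size
    return zeros / total


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    lr: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 30
    patience: int = 5
    class_weights: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


class Adam:
    """Adaptive-moment optimizer over a dict of named parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        if self.lr == 0.0:
            return
        self.t += 1
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _cnn_param_dict(params: CnnParams) -> dict[str, np.ndarray]:
    d = {"Wc": params.Wc, "bc": params.bc}
    for li, blk in enumerate(params.blocks):
        d[f"b{li}_Wp"] = blk.Wp
        d[f"b{li}_Wd"] = blk.Wd
        d[f"b{li}_gamma"] = blk.gamma
        d[f"b{li}_beta"] = blk.beta
    return d


def _lstm_param_dict(params: LstmParams) -> dict[str, np.ndarray]:
    d = {"Wl": params.Wl, "bl": params.bl}
    for li, layer in enumerate(params.layers):
        d[f"l{li}_W"] = layer.W
        d[f"l{li}_U"] = layer.U
        d[f"l{li}_b"] = layer.b
    return d


def weighted_ce_loss(logits: np.ndarray, y: np.ndarray,
                     class_weights: np.ndarray | None):
    """Weighted softmax cross-entropy; returns (loss, dlogits)."""
    n = logits.shape[0]
    z = logits - logits.max(axis=1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=1, keepdims=True)
    w = np.ones(n) if class_weights is None else np.asarray(class_weights)[y]
    ll = -np.log(np.clip(p[np.arange(n), y], 1e-12, None))
    loss = float(np.mean(w * ll))
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits *= (w / n)[:, None]
    return loss, dlogits


def train_branch(X: np.ndarray, y: np.ndarray, branch: str,
                 config: TrainConfig,
                 X_val: np.ndarray | None = None,
                 y_val: np.ndarray | None = None,
                 params=None):
    """Train one ensemble branch with Adam, weighted cross-entropy, and
    early stopping on validation loss.  The LSTM keeps its prune masks
    through every update.  Returns (params, history)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(config.seed)
    if params is None:
        if branch == "cnn":
            params = init_cnn(in_channels=X.shape[2], seed=config.seed,
                              input_len=X.shape[1])
        elif branch == "lstm":
            params = init_lstm(in_channels=X.shape[2], seed=config.seed)
        else:
            raise ValueError("branch must be 'cnn' or 'lstm'")

    def fwd_bwd(xb, yb, training):
        if branch == "cnn":
            logits, cache = cnn_forward_batch(xb, params, training=training)
            loss, dlogits = weighted_ce_loss(logits, yb, config.class_weights)
            grads = cnn_backward_batch(dlogits, cache, params) if training else None
        else:
            logits, cache = lstm_forward_seq(xb, params, training=training,
                                             rng=rng)
            loss, dlogits = weighted_ce_loss(logits, yb, config.class_weights)
            grads = lstm_backward_seq(dlogits, cache, params) if training else None
        return loss, grads

    pdict = _cnn_param_dict(params) if branch == "cnn" else _lstm_param_dict(params)
    opt = Adam(pdict, lr=config.lr)
    history = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_state = {k: v.copy() for k, v in pdict.items()}
    bad_epochs = 0
    n = X.shape[0]
    for _epoch in range(config.max_epochs):
        perm = rng.permutation(n)
        losses = []
        for i0 in range(0, n, config.batch_size):
            idx = perm[i0:i0 + config.batch_size]
            loss, grads = fwd_bwd(X[idx], y[idx], training=True)
            opt.step(grads)
            if branch == "lstm":
                for layer in params.layers:
                    layer.W *= layer.mask_W
                    layer.U *= layer.mask_U
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        if X_val is not None and len(X_val):
            vloss, _ = fwd_bwd(X_val, np.asarray(y_val, dtype=int), False)
        else:
            vloss = history["train_loss"][-1]
        history["val_loss"].append(vloss)
        if vloss < best_val - 1e-6:
            best_val = vloss
            best_state = {k: v.copy() for k, v in pdict.items()}
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                break
    for k, v in pdict.items():
        v[...] = best_state[k]
    return params, history


def predict_proba(X: np.ndarray, params, branch: str,
                  quantized: bool = False) -> np.ndarray:
    if branch == "cnn":
        if quantized:
            logits = cnn_forward_quantized(np.asarray(X, dtype=float), params)
        else:
            logits, _ = cnn_forward_batch(X, params, training=False)
    else:
        logits, _ = lstm_forward_seq(X, params, training=False)
    z = logits - logits.max(axis=-1, keepdims=True)
    p = np.exp(z)
    return p / p.sum(axis=-1, keepdims=True)
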