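"""Numerical core of the CNN+LSTM chronnectome network.

Everything here is plain NumPy with hand-written backward passes: length-
preserving 1D convolutions over the window axis (edges as input channels),
rectifier, inverted dropout, non-overlapping temporal max-pooling, a stacked
LSTM and an affine head, plus an Adam optimizer.  A fixed seed gives
bit-identical training trajectories on a given platform, which is what the
surrogate experiments need for reproducibility.

Array layout is channels-last throughout: ``(batch, windows, features)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ChronnectomeNetwork", "Adam", "sigmoid", "softmax"]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _same_pad(kernel: int) -> tuple[int, int]:
    # 'same' padding for stride-1 conv; even kernels pad one extra on the right
    return (kernel - 1) // 2, kernel // 2


def conv1d_forward(x: np.ndarray, weight: np.ndarray, bias: np.ndarray):
    """Length-preserving 1D convolution along axis 1.

    ``x``: (B, W, E); ``weight``: (E, k, C) — one k-tap filter per input
    edge and output channel; ``bias``: (C,).  Returns the pre-activation
    (B, W, C) and the im2col matrix for backward.
    """
    b, w, e = x.shape
    _, k, c = weight.shape
    pl, pr = _same_pad(k)
    xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
    cols = sliding_window_view(xp, k, axis=1)          # (B, W, E, k) view
    cols = cols.reshape(b * w, e * k)                  # copies into C order
    z = cols @ weight.reshape(e * k, c) + bias
    return z.reshape(b, w, c), cols


def conv1d_backward(dz: np.ndarray, cols: np.ndarray, weight: np.ndarray,
                    x_shape: tuple[int, int, int]):
    """Gradients of :func:`conv1d_forward` w.r.t. input, weight and bias."""
    b, w, e = x_shape
    _, k, c = weight.shape
    dz2 = dz.reshape(b * w, c)
    d_weight = (cols.T @ dz2).reshape(e, k, c)
    d_bias = dz2.sum(axis=0)
    dx = conv1d_input_gradient(dz, weight, x_shape)
    return dx, d_weight, d_bias


def conv1d_input_gradient(upstream: np.ndarray, weight: np.ndarray,
                          x_shape: tuple[int, int, int]) -> np.ndarray:
    """Project a (B, W, C) signal back to input space through transposed filters."""
    b, w, e = x_shape
    _, k, c = weight.shape
    pl, pr = _same_pad(k)
    dcols = (upstream.reshape(b * w, c) @ weight.reshape(e * k, c).T)
    dcols = dcols.reshape(b, w, e, k)
    dxp = np.zeros((b, w + pl + pr, e), dtype=upstream.dtype)
    for j in range(k):
        dxp[:, j : j + w, :] += dcols[:, :, :, j]
    return dxp[:, pl : pl + w, :]


def maxpool_forward(x: np.ndarray, kernel: int):
    """Non-overlapping max over blocks of ``kernel`` windows; remainder dropped."""
    b, w, f = x.shape
    if w < kernel:
        raise ValueError(f"sequence length {w} shorter than pool kernel {kernel}")
    wp = w // kernel
    blocks = x[:, : wp * kernel].reshape(b, wp, kernel, f)
    arg = blocks.argmax(axis=2)
    out = np.take_along_axis(blocks, arg[:, :, None, :], axis=2)[:, :, 0, :]
    return out, (arg, x.shape)


def maxpool_backward(dout: np.ndarray, cache, kernel: int) -> np.ndarray:
    arg, x_shape = cache
    b, w, f = x_shape
    wp = w // kernel
    dblocks = np.zeros((b, wp, kernel, f), dtype=dout.dtype)
    np.put_along_axis(dblocks, arg[:, :, None, :], dout[:, :, None, :], axis=2)
    dx = np.zeros(x_shape, dtype=dout.dtype)
    dx[:, : wp * kernel] = dblocks.reshape(b, wp * kernel, f)
    return dx


def lstm_forward(x: np.ndarray, wx: np.ndarray, wh: np.ndarray, b: np.ndarray):
    """One LSTM layer over a full sequence; gate order [i, f, g, o].

    ``x``: (B, T, F); ``wx``: (F, 4H); ``wh``: (H, 4H); ``b``: (4H,).
    Initial hidden and cell states are zero.  Returns the hidden sequence
    (B, T, H) and a cache for backward.
    """
    bsz, t_len, _ = x.shape
    h_dim = wh.shape[0]
    h = np.zeros((bsz, h_dim), dtype=x.dtype)
    c = np.zeros((bsz, h_dim), dtype=x.dtype)
    hs = np.empty((bsz, t_len, h_dim), dtype=x.dtype)
    cache = []
    for t in range(t_len):
        a = x[:, t] @ wx + h @ wh + b
        i = sigmoid(a[:, :h_dim])
        f = sigmoid(a[:, h_dim : 2 * h_dim])
        g = np.tanh(a[:, 2 * h_dim : 3 * h_dim])
        o = sigmoid(a[:, 3 * h_dim :])
        c_prev = c
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h_prev = h
        h = o * tc
        hs[:, t] = h
        cache.append((i, f, g, o, c_prev, tc, h_prev))
    return hs, cache


def lstm_backward(dhs: np.ndarray, x: np.ndarray, wx: np.ndarray, wh: np.ndarray,
                  cache):
    """Backpropagation through time for :func:`lstm_forward`."""
    bsz, t_len, _ = x.shape
    h_dim = wh.shape[0]
    d_wx = np.zeros_like(wx)
    d_wh = np.zeros_like(wh)
    d_b = np.zeros(4 * h_dim, dtype=wx.dtype)
    dx = np.empty_like(x)
    dh_next = np.zeros((bsz, h_dim), dtype=x.dtype)
    dc_next = np.zeros((bsz, h_dim), dtype=x.dtype)
    for t in range(t_len - 1, -1, -1):
        i, f, g, o, c_prev, tc, h_prev = cache[t]
        dh = dhs[:, t] + dh_next
        do = dh * tc
        dc = dc_next + dh * o * (1.0 - tc * tc)
        di = dc * g
        dg = dc * i
        df = dc * c_prev
        dc_next = dc * f
        da = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        d_wx += x[:, t].T @ da
        d_wh += h_prev.T @ da
        d_b += da.sum(axis=0)
        dx[:, t] = da @ wx.T
        dh_next = da @ wh.T
    return dx, d_wx, d_wh, d_b


class ChronnectomeNetwork:
    """Multi-scale Conv1D -> dropout -> max-pool -> stacked LSTM -> mean -> affine.

    ``n_outputs`` is 2 for the two-way classification head (softmax applied
    at inference by the caller) and 1 for the regression head.  With
    ``dense_lstm=True`` every LSTM layer after the first also sees the
    pooled conv features concatenated onto the previous layer's outputs
    (DenseNet-style skip wiring); the default is a plain stack.
    """

    def __init__(
        self,
        n_edges: int,
        n_outputs: int = 2,
        conv_kernels: tuple[int, ...] = (4, 8, 16),
        conv_channels: int = 32,
        pool_kernel: int = 5,
        lstm_hidden: int = 32,
        lstm_layers: int = 2,
        dropout: float = 0.5,
        conv_activation: str = "relu",
        dropout_position: str = "pre_pool",
        dense_lstm: bool = False,
        dtype=np.float32,
        seed: int = 0,
    ):
        if conv_activation not in ("relu", "linear"):
            raise ValueError("conv_activation must be 'relu' or 'linear'")
        if dropout_position not in ("pre_pool", "post_pool"):
            raise ValueError("dropout_position must be 'pre_pool' or 'post_pool'")
        self.n_edges = int(n_edges)
        self.n_outputs = int(n_outputs)
        self.conv_kernels = tuple(int(k) for k in conv_kernels)
        self.conv_channels = int(conv_channels)
        self.pool_kernel = int(pool_kernel)
        self.lstm_hidden = int(lstm_hidden)
        self.lstm_layers = int(lstm_layers)
        self.dropout = float(dropout)
        self.conv_activation = conv_activation
        self.dropout_position = dropout_position
        self.dense_lstm = bool(dense_lstm)
        self.dtype = np.dtype(dtype)
        self.params: dict[str, np.ndarray] = {}
        self._init_params(np.random.default_rng(seed))

    # -- initialization ----------------------------------------------------
    def _uniform(self, rng, shape, fan_in):
        bound = 1.0 / np.sqrt(fan_in)
        return rng.uniform(-bound, bound, size=shape).astype(self.dtype)

    @property
    def feature_width(self) -> int:
        return self.conv_channels * len(self.conv_kernels)

    def _lstm_in_dim(self, layer: int) -> int:
        if layer == 0:
            return self.feature_width
        if self.dense_lstm:
            return self.feature_width + self.lstm_hidden
        return self.lstm_hidden

    def _init_params(self, rng) -> None:
        p = self.params
        for k in self.conv_kernels:
            fan = k * self.n_edges
            p[f"conv{k}_w"] = self._uniform(rng, (self.n_edges, k, self.conv_channels), fan)
            p[f"conv{k}_b"] = self._uniform(rng, (self.conv_channels,), fan)
        h = self.lstm_hidden
        for layer in range(self.lstm_layers):
            f_in = self._lstm_in_dim(layer)
            p[f"lstm{layer}_wx"] = self._uniform(rng, (f_in, 4 * h), h)
            p[f"lstm{layer}_wh"] = self._uniform(rng, (h, 4 * h), h)
            p[f"lstm{layer}_b"] = self._uniform(rng, (4 * h,), h)
        p["head_w"] = self._uniform(rng, (h, self.n_outputs), h)
        p["head_b"] = self._uniform(rng, (self.n_outputs,), h)

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False,
                dropout_rng: np.random.Generator | None = None):
        """Return ``(output, cache)``; ``output`` is (B, n_outputs) pre-softmax."""
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 2 and x.ndim != 3:
            raise ValueError("conv bank: expected (B, W, E) or (W, E) input")
        if x.ndim == 2:
            x = x[None]
        b, w, e = x.shape
        if e != self.n_edges:
            raise ValueError(f"conv bank: {e} edges, model expects {self.n_edges}")
        if w < max(self.conv_kernels):
            raise ValueError(
                f"conv bank: {w} windows < largest kernel {max(self.conv_kernels)}"
            )
        cache: dict = {"x_shape": x.shape}
        # multi-scale conv bank, feature-axis concatenation
        feats = []
        for k in self.conv_kernels:
            z, cols = conv1d_forward(x, self.params[f"conv{k}_w"], self.params[f"conv{k}_b"])
            cache[f"cols{k}"] = cols
            cache[f"z{k}"] = z
            feats.append(np.maximum(z, 0.0) if self.conv_activation == "relu" else z)
        feat = np.concatenate(feats, axis=2)                       # (B, W, 3C)

        def apply_dropout(arr, tag):
            if train and self.dropout > 0.0:
                rng = dropout_rng or np.random.default_rng()
                mask = (rng.random(arr.shape) >= self.dropout).astype(self.dtype)
                cache[tag] = mask
                return arr * mask / (1.0 - self.dropout)
            cache[tag] = None
            return arr

        if self.dropout_position == "pre_pool":
            feat = apply_dropout(feat, "drop_mask")
        pooled, pool_cache = maxpool_forward(feat, self.pool_kernel)  # (B, W', 3C)
        cache["pool"] = pool_cache
        if self.dropout_position == "post_pool":
            pooled = apply_dropout(pooled, "drop_mask")
        cache["pooled"] = pooled

        seq = pooled
        for layer in range(self.lstm_layers):
            inp = (np.concatenate([pooled, seq], axis=2)
                   if (self.dense_lstm and layer > 0) else seq)
            cache[f"lstm{layer}_in"] = inp
            seq, lcache = lstm_forward(
                inp,
                self.params[f"lstm{layer}_wx"],
                self.params[f"lstm{layer}_wh"],
                self.params[f"lstm{layer}_b"],
            )
            cache[f"lstm{layer}_cache"] = lcache
            cache[f"lstm{layer}_out"] = seq

        mean_h = seq.mean(axis=1)                                   # (B, H)
        cache["t_steps"] = seq.shape[1]
        cache["mean_h"] = mean_h
        out = mean_h @ self.params["head_w"] + self.params["head_b"]
        return out, cache

    def backward(self, cache, dout: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss w.r.t. every parameter given d(output)."""
        grads: dict[str, np.ndarray] = {}
        dout = dout.astype(self.dtype)
        grads["head_w"] = cache["mean_h"].T @ dout
        grads["head_b"] = dout.sum(axis=0)
        dmean = dout @ self.params["head_w"].T
        t_steps = cache["t_steps"]
        dseq = np.repeat(dmean[:, None, :], t_steps, axis=1) / t_steps

        dpooled_extra = 0.0
        for layer in range(self.lstm_layers - 1, -1, -1):
            dx, dwx, dwh, db = lstm_backward(
                dseq,
                cache[f"lstm{layer}_in"],
                self.params[f"lstm{layer}_wx"],
                self.params[f"lstm{layer}_wh"],
                cache[f"lstm{layer}_cache"],
            )
            grads[f"lstm{layer}_wx"] = dwx
            grads[f"lstm{layer}_wh"] = dwh
            grads[f"lstm{layer}_b"] = db
            if self.dense_lstm and layer > 0:
                fw = self.feature_width
                dpooled_extra = dpooled_extra + dx[:, :, :fw]
                dseq = dx[:, :, fw:]
            else:
                dseq = dx
        dpooled = dseq + dpooled_extra

        mask = cache["drop_mask"]
        if self.dropout_position == "post_pool" and mask is not None:
            dpooled = dpooled * mask / (1.0 - self.dropout)
        dfeat = maxpool_backward(dpooled, cache["pool"], self.pool_kernel)
        if self.dropout_position == "pre_pool" and mask is not None:
            dfeat = dfeat * mask / (1.0 - self.dropout)

        c = self.conv_channels
        for idx, k in enumerate(self.conv_kernels):
            dz = dfeat[:, :, idx * c : (idx + 1) * c]
            if self.conv_activation == "relu":
                dz = dz * (cache[f"z{k}"] > 0.0)
            _, dw, db = conv1d_backward(
                dz, cache[f"cols{k}"], self.params[f"conv{k}_w"], cache["x_shape"]
            )
            grads[f"conv{k}_w"] = dw
            grads[f"conv{k}_b"] = db
        return grads

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params_(self, params: dict[str, np.ndarray]) -> None:
        self.params = {k: v.copy() for k, v in params.items()}


class Adam:
    """Adam optimizer over a named parameter dict, with optional L2 penalty."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0):
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = float(weight_decay)
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for key, g in grads.items():
            if self.weight_decay > 0.0:
                g = g + self.weight_decay * params[key]
            m = self.m[key] = self.b1 * self.m[key] + (1.0 - self.b1) * g
            v = self.v[key] = self.b2 * self.v[key] + (1.0 - self.b2) * (g * g)
            params[key] -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
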