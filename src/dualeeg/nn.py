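"""Minimal NumPy neural-network layers with hand-written backpropagation.

Implements exactly the pieces the dual-stream seizure classifier needs:
1D/2D cross-correlation ("convolution") layers via im2col + BLAS matmul,
batch normalization, ReLU, squeeze-and-excitation channel attention,
max-pooling, an LSTM, a fully connected layer, softmax cross-entropy and
Adam.  Every layer is a single-use-per-forward object: ``forward`` caches
what ``backward`` needs; ``params``/``grads`` expose tensors by name for
the optimizer.  Gradients are finite-difference-checked in the test suite.

Convolutions follow the valid cross-correlation convention
``out[co] = bias[co] + sum_ci weight[co, ci] * input[ci]`` with optional
symmetric zero padding so "same" geometry is available.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base: parameterless layers inherit the empty dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.training = True

    def param_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))


# ---------------------------------------------------------------------------
# convolutions

class Conv1d(Layer):
    """Cross-correlation over (B, C_in, L) -> (B, C_out, L_out)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, pad: int | None = None,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.pad = kernel // 2 if pad is None else pad
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (c_in * kernel))  # He init for ReLU stacks
        self.params = {
            "W": (rng.standard_normal((c_out, c_in * kernel)) * scale).astype(dtype),
            "b": np.zeros(c_out, dtype=dtype),
        }

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        self._xp_shape = x.shape
        cols = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=2)
        # (B, C, L_out, k) -> (B, L_out, C*k)
        return np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(
            x.shape[0], -1, self.c_in * self.kernel)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 3 or x.shape[1] != self.c_in:
            raise ValueError(f"expected (B,{self.c_in},L), got {x.shape}")
        cols = self._im2col(x)
        self._cols = cols
        out = cols @ self.params["W"].T + self.params["b"]
        return out.transpose(0, 2, 1)  # (B, C_out, L_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = dout.transpose(0, 2, 1)                       # (B, L_out, C_out)
        B, L_out, _ = d.shape
        d2 = d.reshape(-1, self.c_out)
        self.grads["W"] = d2.T @ self._cols.reshape(-1, self.c_in * self.kernel)
        self.grads["b"] = d2.sum(axis=0)
        dcols = (d @ self.params["W"]).reshape(B, L_out, self.c_in, self.kernel)
        dxp = np.zeros(self._xp_shape, dtype=dout.dtype)
        for t in range(self.kernel):
            dxp[:, :, t:t + L_out] += dcols[:, :, :, t].transpose(0, 2, 1)
        return dxp[:, :, self.pad:dxp.shape[2] - self.pad] if self.pad else dxp


class Conv2d(Layer):
    """Cross-correlation over (B, C_in, H, W) -> (B, C_out, H_out, W_out)."""

    def __init__(self, c_in: int, c_out: int, kernel=(3, 3), pad=None,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.kh, self.kw = kernel
        self.ph, self.pw = (self.kh // 2, self.kw // 2) if pad is None else pad
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (c_in * self.kh * self.kw))
        self.params = {
            "W": (rng.standard_normal((c_out, c_in * self.kh * self.kw))
                  * scale).astype(dtype),
            "b": np.zeros(c_out, dtype=dtype),
        }

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.c_in:
            raise ValueError(f"expected (B,{self.c_in},H,W), got {x.shape}")
        if self.ph or self.pw:
            x = np.pad(x, ((0, 0), (0, 0), (self.ph, self.ph), (self.pw, self.pw)))
        self._xp_shape = x.shape
        cols = np.lib.stride_tricks.sliding_window_view(x, (self.kh, self.kw),
                                                        axis=(2, 3))
        B, _, Ho, Wo, _, _ = cols.shape
        self._out_hw = (Ho, Wo)
        cols = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(
            B, Ho * Wo, self.c_in * self.kh * self.kw)
        self._cols = cols
        out = cols @ self.params["W"].T + self.params["b"]
        return out.transpose(0, 2, 1).reshape(B, self.c_out, Ho, Wo)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, _, Ho, Wo = dout.shape
        d = dout.reshape(B, self.c_out, Ho * Wo).transpose(0, 2, 1)
        d2 = d.reshape(-1, self.c_out)
        self.grads["W"] = d2.T @ self._cols.reshape(-1, self._cols.shape[2])
        self.grads["b"] = d2.sum(axis=0)
        dcols = (d @ self.params["W"]).reshape(B, Ho, Wo, self.c_in,
                                               self.kh, self.kw)
        dxp = np.zeros(self._xp_shape, dtype=dout.dtype)
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, :, i:i + Ho, j:j + Wo] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2)
        h, w = dxp.shape[2], dxp.shape[3]
        return dxp[:, :, self.ph:h - self.ph or None, self.pw:w - self.pw or None]


# ---------------------------------------------------------------------------
# normalization / activations / pooling

class BatchNorm(Layer):
    """Per-channel batch normalization; channel axis 1, reduce the rest."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params = {"gamma": np.ones(channels, dtype=dtype),
                       "beta": np.zeros(channels, dtype=dtype)}
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def _bshape(self, ndim: int):
        return (1, -1) + (1,) * (ndim - 2)

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = (0,) + tuple(range(2, x.ndim))
        shp = self._bshape(x.ndim)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(self.running_mean.dtype)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shp)) * inv.reshape(shp)
        self._cache = (xhat, inv, axes, shp)
        return self.params["gamma"].reshape(shp) * xhat + self.params["beta"].reshape(shp)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, axes, shp = self._cache
        n = dout.size // dout.shape[1]
        self.grads["gamma"] = (dout * xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        dxhat = dout * self.params["gamma"].reshape(shp)
        if not self.training:
            return dxhat * inv.reshape(shp)
        mean_d = dxhat.mean(axis=axes).reshape(shp)
        mean_dx = (dxhat * xhat).mean(axis=axes).reshape(shp)
        return inv.reshape(shp) * (dxhat - mean_d - xhat * mean_dx)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2d(Layer):
    """Non-overlapping (kh, kw) pooling; spatial dims must divide evenly."""

    def __init__(self, kernel=(3, 1)):
        super().__init__()
        self.kh, self.kw = kernel

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        if H % self.kh or W % self.kw:
            raise ValueError(f"pooling {self.kh}x{self.kw} does not tile {H}x{W}")
        r = x.reshape(B, C, H // self.kh, self.kh, W // self.kw, self.kw)
        r = r.transpose(0, 1, 2, 4, 3, 5).reshape(
            B, C, H // self.kh, W // self.kw, self.kh * self.kw)
        self._arg = r.argmax(axis=4)
        self._in_shape = x.shape
        return r.max(axis=4)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, Ho, Wo = dout.shape
        flat = np.zeros((B, C, Ho, Wo, self.kh * self.kw), dtype=dout.dtype)
        np.put_along_axis(flat, self._arg[..., None], dout[..., None], axis=4)
        flat = flat.reshape(B, C, Ho, Wo, self.kh, self.kw).transpose(
            0, 1, 2, 4, 3, 5)
        return flat.reshape(self._in_shape)


class ChannelAttention(Layer):
    """Squeeze-and-excitation gate: global average over non-channel axes,
    two-layer bottleneck (C -> C/r -> C) with ReLU then sigmoid, channelwise
    rescaling of the input."""

    def __init__(self, channels: int, reduction: int = 16,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        hidden = max(1, channels // reduction)
        rng = rng or np.random.default_rng()
        self.params = {
            "W1": (rng.standard_normal((channels, hidden))
                   * np.sqrt(2.0 / channels)).astype(dtype),
            "b1": np.zeros(hidden, dtype=dtype),
            "W2": (rng.standard_normal((hidden, channels))
                   * np.sqrt(1.0 / hidden)).astype(dtype),
            "b2": np.zeros(channels, dtype=dtype),
        }

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = tuple(range(2, x.ndim))
        s = x.mean(axis=axes)                       # (B, C)
        h = s @ self.params["W1"] + self.params["b1"]
        hr = np.maximum(h, 0.0)
        g = sigmoid(hr @ self.params["W2"] + self.params["b2"])  # (B, C)
        shp = (x.shape[0], x.shape[1]) + (1,) * (x.ndim - 2)
        self._cache = (x, s, h, hr, g, axes, shp)
        return x * g.reshape(shp)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, s, h, hr, g, axes, shp = self._cache
        dg = (dout * x).sum(axis=axes)              # (B, C)
        dx = dout * g.reshape(shp)
        dz2 = dg * g * (1.0 - g)
        self.grads["W2"] = hr.T @ dz2
        self.grads["b2"] = dz2.sum(axis=0)
        dhr = dz2 @ self.params["W2"].T
        dh = dhr * (h > 0)
        self.grads["W1"] = s.T @ dh
        self.grads["b1"] = dh.sum(axis=0)
        ds = dh @ self.params["W1"].T               # (B, C)
        n_spatial = x.size // (x.shape[0] * x.shape[1])
        dx += ds.reshape(shp) / n_spatial
        return dx

    def gates(self, x: np.ndarray) -> np.ndarray:
        """Per-channel gate values in (0, 1) for inspection/testing."""
        s = x.mean(axis=tuple(range(2, x.ndim)))
        hr = np.maximum(s @ self.params["W1"] + self.params["b1"], 0.0)
        return sigmoid(hr @ self.params["W2"] + self.params["b2"])


# ---------------------------------------------------------------------------
# LSTM

class LSTM(Layer):
    """Single-layer LSTM over (B, L, D) -> all hidden states (B, L, H).

    Gate order in the packed weight matrices is (input i, forget f,
    candidate g, output o); the update is the standard
    ``c_t = f_t c_{t-1} + i_t tanh(W_c x + U_c h + b_c)``,
    ``h_t = o_t tanh(c_t)`` with h_0 = c_0 = 0.
    """

    def __init__(self, d_in: int, hidden: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        self.d_in, self.hidden = d_in, hidden
        rng = rng or np.random.default_rng()
        k = np.sqrt(1.0 / hidden)
        self.params = {
            "Wx": (rng.uniform(-k, k, (d_in, 4 * hidden))).astype(dtype),
            "Wh": (rng.uniform(-k, k, (hidden, 4 * hidden))).astype(dtype),
            "b": np.zeros(4 * hidden, dtype=dtype),
        }

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not np.all(np.isfinite(self.params["Wx"])) or \
           not np.all(np.isfinite(self.params["Wh"])):
            raise ValueError("non-finite LSTM parameters")
        B, L, D = x.shape
        H = self.hidden
        h = np.zeros((B, H), dtype=x.dtype)
        c = np.zeros((B, H), dtype=x.dtype)
        xz = x @ self.params["Wx"] + self.params["b"]   # (B, L, 4H)
        caches = []
        hs = np.empty((B, L, H), dtype=x.dtype)
        for t in range(L):
            z = xz[:, t] + h @ self.params["Wh"]
            i = sigmoid(z[:, :H])
            f = sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            caches.append((h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            hs[:, t] = h
        self._cache = (x, caches)
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        x, caches = self._cache
        B, L, D = x.shape
        H = self.hidden
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros_like(self.params["b"])
        dx = np.empty_like(x)
        dh_next = np.zeros((B, H), dtype=x.dtype)
        dc_next = np.zeros((B, H), dtype=x.dtype)
        for t in range(L - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = caches[t]
            dh = dhs[:, t] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g ** 2),
                do * o * (1.0 - o),
            ], axis=1)                                   # (B, 4H)
            dWx += x[:, t].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ Wx.T
            dh_next = dz @ Wh.T
            dc_next = dc * f
        self.grads = {"Wx": dWx, "Wh": dWh, "b": db}
        return dx


# ---------------------------------------------------------------------------
# classifier head and loss

class Linear(Layer):
    def __init__(self, d_in: int, d_out: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        k = np.sqrt(1.0 / d_in)
        self.params = {"W": rng.uniform(-k, k, (d_in, d_out)).astype(dtype),
                       "b": np.zeros(d_out, dtype=dtype)}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy and its gradient wrt the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = np.finfo(p.dtype).tiny
    loss = float(-np.log(p[np.arange(n), labels] + eps).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


# ---------------------------------------------------------------------------
# optimizer

class Adam:
    """Adam over a list of (params, grads) dicts shared with the layers."""

    def __init__(self, layers, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in self.layers]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for l, m, v in zip(self.layers, self.m, self.v):
            for k, p in l.params.items():
                g = l.grads[k]
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                p -= self.lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)
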