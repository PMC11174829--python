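import numpy as np
import pytest

import dualeeg as de


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Featurized synthetic dataset shared by read-only tests."""
    cfg = de.SynthConfig(n_per_class=12, seed=7)
    return de.featurize_windows(de.generate_dataset(cfg))


def naive_dft(x):
    """Brute-force O(N^2) DFT, the independent spectral oracle."""
    x = np.asarray(x, dtype=float)
    n = x.size
    k = np.arange(n)
    ph = np.exp(-2j * np.pi * np.outer(k, k) / n)
    return ph @ x


def naive_conv1d(x, w, b):
    """Triple-loop valid cross-correlation; x (C_in, L_pad), w (C_out, C_in, k)."""
    c_out, c_in, k = w.shape
    L = x.shape[1] - k + 1
    out = np.zeros((c_out, L))
    for co in range(c_out):
        for ci in range(c_in):
            for t in range(L):
                out[co, t] += np.dot(w[co, ci], x[ci, t:t + k])
        out[co] += b[co]
    return out


def naive_conv2d(x, w, b):
    """Four-loop valid 2D cross-correlation; x (C_in, H, W), w (C_out, C_in, kh, kw)."""
    c_out, c_in, kh, kw = w.shape
    H = x.shape[1] - kh + 1
    W = x.shape[2] - kw + 1
    out = np.zeros((c_out, H, W))
    for co in range(c_out):
        for ci in range(c_in):
            for i in range(H):
                for j in range(W):
                    out[co, i, j] += np.sum(w[co, ci] * x[ci, i:i + kh, j:j + kw])
        out[co] += b[co]
    return out


def naive_lstm(x, Wx, Wh, b):
    """Scalar-loop LSTM recurrence; x (L, D); returns all hidden states (L, H)."""
    sigm = lambda v: 1.0 / (1.0 + np.exp(-v))
    H = Wh.shape[0]
    L = x.shape[0]
    h = np.zeros(H)
    c = np.zeros(H)
    hs = np.zeros((L, H))
    for t in range(L):
        z = x[t] @ Wx + h @ Wh + b
        i, f, g, o = z[:H], z[H:2 * H], z[2 * H:3 * H], z[3 * H:]
        i, f, o = sigm(i), sigm(f), sigm(o)
        g = np.tanh(g)
        c = f * c + i * g
        h = o * np.tanh(c)
        hs[t] = h
    return hs
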