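"""Multimodal dual-stream seizure classifier.

Two parallel streams share a fused softmax head:

* **Time-series stream** — the 5x356 feature matrix passes through three
  1D-convolution blocks (5 -> 64 -> 128 -> 256 channels, kernel 3,
  length-preserving padding, each conv + batch norm + ReLU) with
  squeeze-and-excitation channel attention after the third block, giving
  ``y1`` (256x356).  A residual branch applies BN + ReLU to ``y1`` and adds
  a 1x1-convolution projection ``y2`` (5 -> 256) of the input, giving
  ``y3``.  ``y1`` also feeds a 4-unit LSTM over its 356 time steps, keeping
  every per-step hidden state: ``y4`` (356x4).
* **Spectrogram stream** — the 33x19 STFT magnitude passes through three
  3x3 2D-convolution blocks (1 -> 64 -> 128 -> 256, shape-preserving, each
  conv + BN + ReLU), a (3,1) max-pool, a valid (1,2) convolution at
  constant channels and channel attention, giving ``y5`` (256x11x18).

``y3``, ``y4`` and ``y5`` are flattened, concatenated (full variant:
91,136 + 1,424 + 50,688 = 143,248 features) and classified by a single
fully connected layer + softmax.  Ablation variants drop the LSTM head
(``no_lstm``), the spectrogram stream (``no_2dconv``) or both
(``no_both``); the fused layer resizes accordingly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import nn

VARIANTS = ("full", "no_lstm", "no_2dconv", "no_both")


@dataclass
class ModelConfig:
    in_channels: int = 5
    seq_len: int = 356
    conv1d_channels: tuple = (64, 128, 256)
    conv1d_kernel: int = 3
    lstm_hidden: int = 4
    conv2d_channels: tuple = (64, 128, 256)
    conv2d_kernel: int = 3
    attention_reduction: int = 16
    n_classes: int = 2
    spec_shape: tuple = (33, 19)
    variant: str = "full"

    def __post_init__(self) -> None:
        self.conv1d_channels = tuple(self.conv1d_channels)
        self.conv2d_channels = tuple(self.conv2d_channels)
        self.spec_shape = tuple(self.spec_shape)
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.conv1d_channels[-1] != 256 or self.conv2d_channels[-1] != 256:
            raise ValueError("conv channel progressions must end in 256")

    @property
    def use_lstm(self) -> bool:
        return self.variant in ("full", "no_2dconv")

    @property
    def use_2d(self) -> bool:
        return self.variant in ("full", "no_lstm")

    def fused_dim(self) -> int:
        c = self.conv1d_channels[-1]
        d = c * self.seq_len
        if self.use_lstm:
            d += self.seq_len * self.lstm_hidden
        if self.use_2d:
            h, w = self.spec_shape
            d += self.conv2d_channels[-1] * (h // 3) * (w - 1)
        return d


@dataclass
class StreamOutputs:
    """Intermediate and final activations for one forward pass."""

    y1: np.ndarray
    y3: np.ndarray
    y4: Optional[np.ndarray]
    y5: Optional[np.ndarray]
    fused: np.ndarray
    logits: np.ndarray
    probs: np.ndarray


class DualStreamModel:
    """The network, its parameters and its manual backward pass."""

    def __init__(self, cfg: ModelConfig | None = None, seed: int = 0,
                 dtype=np.float32):
        self.cfg = cfg or ModelConfig()
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        c = self.cfg

        chans = (c.in_channels,) + c.conv1d_channels
        self.blocks1d = []
        for ci, co in zip(chans[:-1], chans[1:]):
            self.blocks1d.append((
                nn.Conv1d(ci, co, c.conv1d_kernel, rng=rng, dtype=dtype),
                nn.BatchNorm(co, dtype=dtype), nn.ReLU()))
        self.att1d = nn.ChannelAttention(chans[-1], c.attention_reduction,
                                         rng=rng, dtype=dtype)
        self.bn_res = nn.BatchNorm(chans[-1], dtype=dtype)
        self.relu_res = nn.ReLU()
        self.conv_res = nn.Conv1d(c.in_channels, chans[-1], 1, rng=rng,
                                  dtype=dtype)
        self.lstm = (nn.LSTM(chans[-1], c.lstm_hidden, rng=rng, dtype=dtype)
                     if c.use_lstm else None)

        self.blocks2d = []
        self.pool = self.conv_reduce = self.att2d = None
        if c.use_2d:
            chans2 = (1,) + c.conv2d_channels
            for ci, co in zip(chans2[:-1], chans2[1:]):
                self.blocks2d.append((
                    nn.Conv2d(ci, co, (c.conv2d_kernel,) * 2, rng=rng, dtype=dtype),
                    nn.BatchNorm(co, dtype=dtype), nn.ReLU()))
            self.pool = nn.MaxPool2d((3, 1))
            self.conv_reduce = nn.Conv2d(chans2[-1], chans2[-1], (1, 2),
                                         pad=(0, 0), rng=rng, dtype=dtype)
            self.att2d = nn.ChannelAttention(chans2[-1], c.attention_reduction,
                                             rng=rng, dtype=dtype)
        self.fc = nn.Linear(c.fused_dim(), c.n_classes, rng=rng, dtype=dtype)

    # -- plumbing ----------------------------------------------------------
    def layers(self) -> list[nn.Layer]:
        out: list[nn.Layer] = []
        for conv, bn, relu in self.blocks1d:
            out += [conv, bn, relu]
        out += [self.att1d, self.bn_res, self.relu_res, self.conv_res]
        if self.lstm is not None:
            out.append(self.lstm)
        for conv, bn, relu in self.blocks2d:
            out += [conv, bn, relu]
        for l in (self.pool, self.conv_reduce, self.att2d):
            if l is not None:
                out.append(l)
        out.append(self.fc)
        return out

    def set_training(self, training: bool) -> None:
        for l in self.layers():
            l.training = training

    def param_count(self) -> int:
        return sum(l.param_count() for l in self.layers())

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {}
        for i, l in enumerate(self.layers()):
            for k, v in l.params.items():
                state[f"layer{i}.{k}"] = v
            if isinstance(l, nn.BatchNorm):
                state[f"layer{i}.running_mean"] = l.running_mean
                state[f"layer{i}.running_var"] = l.running_var
        return state

    # -- forward / backward ------------------------------------------------
    def forward(self, features: np.ndarray,
                spectrograms: np.ndarray | None = None) -> StreamOutputs:
        """Run a batch: features (B,5,356); spectrograms (B,33,19) or (B,1,33,19)."""
        c = self.cfg
        x = np.asarray(features, dtype=self.dtype)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != (c.in_channels, c.seq_len):
            raise ValueError(
                f"expected feature batch (B,{c.in_channels},{c.seq_len}), "
                f"got {x.shape}")
        a = x
        for conv, bn, relu in self.blocks1d:
            a = relu.forward(bn.forward(conv.forward(a)))
        y1 = self.att1d.forward(a)
        y3 = self.relu_res.forward(self.bn_res.forward(y1)) \
            + self.conv_res.forward(x)
        y4 = self.lstm.forward(y1.transpose(0, 2, 1)) if self.lstm else None

        y5 = None
        if c.use_2d:
            if spectrograms is None:
                raise ValueError(f"variant {c.variant!r} requires spectrograms")
            s = np.asarray(spectrograms, dtype=self.dtype)
            if s.ndim == 2:
                s = s[None]
            if s.ndim == 3:
                s = s[:, None]
            if s.shape[1:] != (1,) + c.spec_shape:
                raise ValueError(
                    f"expected spectrogram batch (B,1,{c.spec_shape[0]},"
                    f"{c.spec_shape[1]}), got {s.shape}")
            for conv, bn, relu in self.blocks2d:
                s = relu.forward(bn.forward(conv.forward(s)))
            y5 = self.att2d.forward(
                self.conv_reduce.forward(self.pool.forward(s)))

        B = x.shape[0]
        parts = [y3.reshape(B, -1)]
        if y4 is not None:
            parts.append(y4.reshape(B, -1))
        if y5 is not None:
            parts.append(y5.reshape(B, -1))
        fused = np.concatenate(parts, axis=1)
        logits = self.fc.forward(fused)
        return StreamOutputs(y1, y3, y4, y5, fused, logits, nn.softmax(logits))

    def backward(self, dlogits: np.ndarray, out: StreamOutputs) -> None:
        c = self.cfg
        B = dlogits.shape[0]
        dfused = self.fc.backward(dlogits)
        n3 = out.y3[0].size
        dy3 = dfused[:, :n3].reshape(out.y3.shape)
        pos = n3
        dy1 = self.bn_res.backward(self.relu_res.backward(dy3))
        # conv_res grads; its input gradient dies at the raw input
        self.conv_res.backward(dy3)
        if self.lstm is not None:
            n4 = out.y4[0].size
            dy4 = dfused[:, pos:pos + n4].reshape(out.y4.shape)
            pos += n4
            dy1 += self.lstm.backward(dy4).transpose(0, 2, 1)
        d = self.att1d.backward(dy1)
        for conv, bn, relu in reversed(self.blocks1d):
            d = conv.backward(bn.backward(relu.backward(d)))
        if c.use_2d:
            dy5 = dfused[:, pos:].reshape(out.y5.shape)
            d2 = self.pool.backward(self.conv_reduce.backward(
                self.att2d.backward(dy5)))
            for conv, bn, relu in reversed(self.blocks2d):
                d2 = conv.backward(bn.backward(relu.backward(d2)))

    # -- checkpointing -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        state = {k: np.asarray(v) for k, v in self.state_arrays().items()}
        cfg_json = json.dumps(asdict(self.cfg))
        np.savez(path, __config__=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
                 **state)

    @classmethod
    def load(cls, path: str | Path) -> "DualStreamModel":
        path = Path(path)
        if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
            path = path.with_suffix(path.suffix + ".npz")
        with np.load(path) as z:
            cfg_dict = json.loads(bytes(z["__config__"]).decode())
            state = {k: z[k] for k in z.files if k != "__config__"}
        model = cls(ModelConfig(**cfg_dict))
        model.load_state(state)
        return model

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_arrays()
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ValueError(f"checkpoint does not match model config "
                             f"(mismatched keys: {sorted(missing)[:4]}...)")
        for i, l in enumerate(self.layers()):
            for k in l.params:
                src = state[f"layer{i}.{k}"]
                if l.params[k].shape != src.shape:
                    raise ValueError(
                        f"checkpoint shape mismatch at layer{i}.{k}: "
                        f"{src.shape} vs {l.params[k].shape}")
                l.params[k] = src.astype(self.dtype)
            if isinstance(l, nn.BatchNorm):
                l.running_mean = state[f"layer{i}.running_mean"].astype(self.dtype)
                l.running_var = state[f"layer{i}.running_var"].astype(self.dtype)

    def snapshot(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.state_arrays().items()}


def build_model(cfg: ModelConfig | None = None, seed: int = 0,
                dtype=np.float32) -> DualStreamModel:
    """Construct a seeded model for the given (possibly ablated) config."""
    return DualStreamModel(cfg, seed=seed, dtype=dtype)
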