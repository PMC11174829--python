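"""Window extraction and the two input modalities for seizure detection.

A raw single-channel EEG recording is sliced into fixed-length windows.
Each window is expanded into

* a 5-row *feature matrix* ``[x, |DFT(x)|, arg DFT(x), Δx, Δ²x]`` stacking
  the raw samples with their full two-sided amplitude spectrum, phase
  spectrum, and first/second forward differences, and
* an STFT magnitude *spectrogram* (one-sided, Hann-windowed by default),

the two streams consumed by :mod:`dualeeg.model`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as sps

# Canonical geometry: a 356-sample window (~2.05 s at the Bonn rate of
# 173.61 Hz) with a 64/16 STFT recipe, so the model input shapes are
# 5x356 and 33x19 exactly.
WINDOW_LEN = 356
STFT_WINDOW = 64
STFT_HOP = 16

LABELS = ("interictal", "ictal", "preictal", "unknown")


@dataclass
class RawSegment:
    """One single-channel EEG recording."""

    samples: np.ndarray
    fs: float
    label: str = "unknown"
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.size < 1:
            raise ValueError("segment has no samples")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class EEGWindow:
    """Fixed-length window with a binary class label (0 interictal, 1 ictal)."""

    samples: np.ndarray
    fs: float
    label: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.label not in (0, 1):
            raise ValueError(f"window label must be 0 or 1, got {self.label}")


@dataclass
class FeatureMatrix:
    """5xN matrix with fixed row order (raw, amplitude, phase, diff1, diff2)."""

    values: np.ndarray
    channel_order: tuple = ("raw", "amplitude", "phase", "diff1", "diff2")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != 5:
            raise ValueError(f"feature matrix must be 5xN, got {self.values.shape}")


@dataclass
class Spectrogram:
    """One-sided STFT magnitude matrix with explicit axes."""

    magnitudes: np.ndarray
    freq_axis: np.ndarray
    time_axis: np.ndarray
    window_kind: str = "hann"
    window_len: int = STFT_WINDOW
    hop: int = STFT_HOP

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        if np.any(self.magnitudes < 0):
            raise ValueError("spectrogram magnitudes must be nonnegative")


# ---------------------------------------------------------------------------
# windowing

def slice_windows(segment: RawSegment, window_len: int = WINDOW_LEN,
                  hop: int | None = None) -> list[EEGWindow]:
    """Slice a segment into non-overlapping (or hopped) fixed-length windows.

    Yields ``floor((len - window_len)/hop) + 1`` windows; any trailing
    remainder shorter than ``window_len`` is dropped.  Each window carries
    the segment's class label (interictal -> 0, ictal -> 1).
    """
    if hop is None:
        hop = window_len
    if window_len < 8:
        raise ValueError(f"window_len must be >= 8, got {window_len}")
    if hop < 1:
        raise ValueError(f"hop must be >= 1, got {hop}")
    n = len(segment)
    if n < window_len:
        raise ValueError(
            f"segment too short: {n} samples < window_len {window_len}"
        )
    label = {"interictal": 0, "ictal": 1}.get(segment.label)
    if label is None:
        raise ValueError(
            f"cannot window a segment labelled {segment.label!r}; "
            "only interictal/ictal segments have a binary class"
        )
    count = (n - window_len) // hop + 1
    return [
        EEGWindow(segment.samples[m * hop:m * hop + window_len], segment.fs, label)
        for m in range(count)
    ]


# ---------------------------------------------------------------------------
# spectra and differences

def amplitude_spectrum(x: Sequence[float]) -> np.ndarray:
    """Full two-sided DFT magnitude |X[k]|, k = 0..N-1."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("amplitude_spectrum needs at least 2 samples")
    return np.abs(np.fft.fft(x))


def phase_spectrum(x: Sequence[float]) -> np.ndarray:
    """Principal-value argument of the DFT coefficients, in (-pi, pi].

    Phase is numerically meaningless at bins whose magnitude is ~0; values
    there are whatever the arctangent returns and should not be interpreted.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("phase_spectrum needs at least 2 samples")
    return np.angle(np.fft.fft(x))


def first_difference(x: Sequence[float]) -> np.ndarray:
    """Forward difference x[n+1] - x[n], zero-padded at the tail to length N."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("first_difference needs at least 2 samples")
    out = np.zeros_like(x)
    out[:-1] = x[1:] - x[:-1]
    return out


def second_difference(x: Sequence[float]) -> np.ndarray:
    """Forward second difference x[n+2] - 2x[n+1] + x[n], zero-padded (2) at the tail."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 3:
        raise ValueError("second_difference needs at least 3 samples")
    out = np.zeros_like(x)
    out[:-2] = x[2:] - 2.0 * x[1:-1] + x[:-2]
    return out


def standardize(x: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Per-window z-score; an (almost) constant window is only centred."""
    x = np.asarray(x, dtype=float)
    mu = x.mean()
    sd = x.std()
    if sd < eps:
        return x - mu
    return (x - mu) / sd


def build_feature_matrix(window: EEGWindow, standardize_raw: bool = True) -> FeatureMatrix:
    """Stack raw, amplitude, phase, diff1, diff2 rows for one window.

    With ``standardize_raw`` (the default) the raw samples are z-scored
    first and all five rows are derived from the standardized signal, so
    the matrix is invariant to the recording's amplitude scale.
    """
    x = standardize(window.samples) if standardize_raw else np.asarray(
        window.samples, dtype=float)
    return FeatureMatrix(np.stack([
        x,
        amplitude_spectrum(x),
        phase_spectrum(x),
        first_difference(x),
        second_difference(x),
    ]))


# ---------------------------------------------------------------------------
# STFT

def _stft_window(kind: str, length: int) -> np.ndarray:
    if kind == "rect":
        return np.ones(length)
    return sps.get_window(kind, length, fftbins=True)


def stft(x: Sequence[float], window_len: int = STFT_WINDOW, hop: int = STFT_HOP,
         window_kind: str = "hann", fs: float = 1.0) -> Spectrogram:
    """One-sided STFT magnitude of ``x``.

    Frame ``m`` covers samples ``m*hop .. m*hop + window_len - 1``; bin ``k``
    is ``|sum_n x[n] w[n - m*hop] exp(-2pi i k n / window_len)|`` for
    ``k = 0..window_len//2``.  No centring or tail padding: frames that do
    not fit are dropped, giving ``floor((N - window_len)/hop) + 1`` frames.
    """
    x = np.asarray(x, dtype=float).ravel()
    if hop < 1:
        raise ValueError(f"hop must be >= 1, got {hop}")
    if window_len > x.size:
        raise ValueError(
            f"STFT window ({window_len}) longer than signal ({x.size})"
        )
    w = _stft_window(window_kind, window_len)
    n_frames = (x.size - window_len) // hop + 1
    frames = np.lib.stride_tricks.sliding_window_view(x, window_len)[::hop][:n_frames]
    mags = np.abs(np.fft.rfft(frames * w, n=window_len, axis=1)).T  # F x T
    freqs = np.fft.rfftfreq(window_len, d=1.0 / fs)
    times = (np.arange(n_frames) * hop + window_len / 2.0) / fs
    return Spectrogram(mags, freqs, times, window_kind, window_len, hop)


def bandpass_filter(segment: RawSegment, low: float, high: float,
                    transition: float = 0.1) -> RawSegment:
    """Zero-phase band-limited copy of a segment (optional utility).

    Mirrors the 0.5-70 Hz acquisition band of clinical scalp EEG; disabled
    by default in the featurization pipeline.  Implemented as an FFT-domain
    mask with raised-cosine transitions (``transition`` is the relative
    width of each edge), which is exactly zero-phase and length-preserving
    and avoids the long start-up transients an IIR high-pass develops at
    sub-hertz edges.
    """
    if not (0.0 < low < high < segment.fs / 2.0):
        raise ValueError(
            f"band edges must satisfy 0 < low < high < fs/2; "
            f"got low={low}, high={high}, fs={segment.fs}"
        )
    x = segment.samples
    freqs = np.fft.rfftfreq(x.size, d=1.0 / segment.fs)
    gain = np.ones_like(freqs)
    lo_w = max(transition * low, 1e-9)
    hi_w = max(transition * high, 1e-9)
    gain[freqs <= low - lo_w] = 0.0
    gain[freqs >= high + hi_w] = 0.0
    rise = (freqs > low - lo_w) & (freqs < low + lo_w)
    gain[rise] = 0.5 * (1 - np.cos(np.pi * (freqs[rise] - (low - lo_w)) / (2 * lo_w)))
    fall = (freqs > high - hi_w) & (freqs < high + hi_w)
    gain[fall] = 0.5 * (1 + np.cos(np.pi * (freqs[fall] - (high - hi_w)) / (2 * hi_w)))
    filtered = np.fft.irfft(np.fft.rfft(x) * gain, n=x.size)
    return RawSegment(filtered, segment.fs, segment.label, segment.source_id)


# ---------------------------------------------------------------------------
# window container (NPZ + JSON sidecar)

@dataclass
class FeaturizedDataset:
    """In-memory form of the window container written by the CLI."""

    features: np.ndarray      # n x 5 x window_len
    spectrograms: np.ndarray  # n x F x T
    labels: np.ndarray        # n
    fs: float
    params: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.labels.size


def featurize_windows(windows: Sequence[EEGWindow],
                      stft_window: int = STFT_WINDOW, stft_hop: int = STFT_HOP,
                      window_kind: str = "hann",
                      standardize_raw: bool = True) -> FeaturizedDataset:
    """Expand windows into the feature-matrix and spectrogram arrays."""
    if not windows:
        raise ValueError("no windows to featurize")
    feats, specs, labels = [], [], []
    for w in windows:
        x = standardize(w.samples) if standardize_raw else w.samples
        fm = build_feature_matrix(EEGWindow(x, w.fs, w.label), standardize_raw=False)
        sp = stft(x, stft_window, stft_hop, window_kind, fs=w.fs)
        feats.append(fm.values)
        specs.append(sp.magnitudes)
        labels.append(w.label)
    fs = windows[0].fs
    params = {
        "window_len": int(feats[0].shape[1]), "stft_window": stft_window,
        "stft_hop": stft_hop, "window_kind": window_kind,
        "standardize": standardize_raw, "fs": fs,
    }
    return FeaturizedDataset(np.stack(feats), np.stack(specs),
                             np.asarray(labels, dtype=int), fs, params)


def save_container(path: str | Path, ds: FeaturizedDataset) -> None:
    """Write the NPZ container (keys: features, spectrograms, labels, fs) + JSON sidecar."""
    path = Path(path)
    np.savez(path, features=ds.features, spectrograms=ds.spectrograms,
             labels=ds.labels, fs=np.asarray(ds.fs))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(ds.params, indent=2, sort_keys=True))


def load_container(path: str | Path) -> FeaturizedDataset:
    path = Path(path)
    if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
        path = path.with_suffix(path.suffix + ".npz")
    with np.load(path) as z:
        ds = FeaturizedDataset(z["features"], z["spectrograms"],
                               z["labels"].astype(int), float(z["fs"]))
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        ds.params = json.loads(sidecar.read_text())
    return ds
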