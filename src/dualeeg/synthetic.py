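"""Seeded two-class synthetic single-channel EEG.

Interictal background = a sum of five band-limited sinusoids (delta 0.5-4,
theta 4-8, alpha 8-12, beta 12-30, gamma >30 Hz) with per-window random
frequency and phase, plus white Gaussian noise.  Ictal windows add a
periodic spike-and-wave train (default 3 Hz, the classic absence-seizure
motif): each period is one narrow positive half-sine spike followed by a
slow opposite-sign half-wave, with peak amplitude ``ictal_gain`` times the
background RMS.  This reproduces the spectral contrast the classifier
exploits — excess low-frequency (2-4 Hz) power during seizures — without
any claim of physiological realism beyond band structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_features import EEGWindow

# (low, high) Hz edges of the five conventional EEG bands; the gamma upper
# edge is capped at 0.45*fs at generation time to respect Nyquist.
BANDS = ((0.5, 4.0), (4.0, 8.0), (8.0, 12.0), (12.0, 30.0), (30.0, np.inf))


@dataclass
class SynthConfig:
    """Generator parameters; defaults mirror the Bonn recording geometry."""

    fs: float = 173.61
    n_per_class: int = 200
    window_len: int = 356
    band_amplitudes: tuple = (1.0, 0.8, 1.0, 0.5, 0.2)
    spike_rate: float = 3.0
    ictal_gain: float = 4.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.window_len < 8:
            raise ValueError("window_len must be >= 8")
        if len(self.band_amplitudes) != 5 or any(a < 0 for a in self.band_amplitudes):
            raise ValueError("band_amplitudes must be 5 nonnegative reals")
        if self.ictal_gain <= 1:
            raise ValueError("ictal_gain must be > 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.spike_rate <= 0:
            raise ValueError("spike_rate must be positive")


def _background(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(cfg.window_len) / cfg.fs
    x = np.zeros(cfg.window_len)
    for amp, (lo, hi) in zip(cfg.band_amplitudes, BANDS):
        hi = min(hi, 0.45 * cfg.fs)
        # one fresh frequency per band per window, so windows are
        # exchangeable draws rather than copies of one template
        f = rng.uniform(lo, max(hi, lo + 1e-9))
        phi = rng.uniform(0.0, 2.0 * np.pi)
        x += amp * np.sin(2.0 * np.pi * f * t + phi)
    if cfg.noise_sd > 0:
        x += rng.normal(0.0, cfg.noise_sd, cfg.window_len)
    return x


def _spike_wave_train(cfg: SynthConfig, rng: np.random.Generator,
                      peak: float) -> np.ndarray:
    """Periodic spike-and-wave at ``spike_rate`` Hz with random onset phase."""
    n = cfg.window_len
    period = cfg.fs / cfg.spike_rate                     # samples per cycle
    spike_w = max(2, int(round(cfg.fs / (8.0 * cfg.spike_rate))))
    offset = rng.uniform(0.0, period)
    phase = ((np.arange(n) + offset) % period) / period  # in [0, 1)
    frac_spike = spike_w / period
    train = np.zeros(n)
    in_spike = phase < frac_spike
    # narrow positive half-sine spike ...
    train[in_spike] = np.sin(np.pi * phase[in_spike] / frac_spike)
    # ... then a slow opposite-sign half-wave over the rest of the period
    rest = ~in_spike
    train[rest] = -0.5 * np.sin(
        np.pi * (phase[rest] - frac_spike) / (1.0 - frac_spike))
    return peak * train


def generate_window(cfg: SynthConfig, class_label: int,
                    rng: np.random.Generator) -> EEGWindow:
    """Draw one window of the given class from an explicit RNG state."""
    if class_label not in (0, 1):
        raise ValueError(f"class_label must be 0 or 1, got {class_label}")
    x = _background(cfg, rng)
    if class_label == 1:
        rms = float(np.sqrt(np.mean(x ** 2)))
        if rms == 0.0:
            rms = 1.0  # degenerate silent background; still emit spikes
        x = x + _spike_wave_train(cfg, rng, peak=cfg.ictal_gain * rms)
    return EEGWindow(x, cfg.fs, class_label)


def generate_dataset(cfg: SynthConfig) -> list[EEGWindow]:
    """Balanced, seed-shuffled list of 2*n_per_class windows."""
    rng = np.random.default_rng(cfg.seed)
    windows = [generate_window(cfg, 0, rng) for _ in range(cfg.n_per_class)]
    windows += [generate_window(cfg, 1, rng) for _ in range(cfg.n_per_class)]
    order = rng.permutation(len(windows))
    return [windows[i] for i in order]
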