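"""Loaders for the two public single-channel EEG dataset layouts.

Bonn layout: five subsets (Z, O healthy scalp; N, F interictal intracranial;
S ictal intracranial), 100 ASCII files each, one sample per line, 4097
samples at 173.61 Hz.  Z/O/N/F are labelled interictal (0) and S ictal (1).
The ictal subset is called both "S" and "E" in the literature; both names
are accepted.

New Delhi layout: class folders (pre-ictal / interictal / ictal) of MAT
files, each holding one 1024-sample recording at 200 Hz.  Binary experiments
use interictal vs ictal; pre-ictal is excluded by default.

File discovery is lexicographic so downstream splits are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.io import loadmat

from .signal_features import EEGWindow, RawSegment, slice_windows

BONN_FS = 173.61
BONN_SAMPLES = 4097
DELHI_FS = 200.0
DELHI_SAMPLES = 1024

# subset letter -> class label; E is a synonym for the ictal subset S
_BONN_CLASS = {"Z": "interictal", "O": "interictal", "N": "interictal",
               "F": "interictal", "S": "ictal", "E": "ictal"}


@dataclass
class DatasetManifest:
    layout: str
    root: Path
    class_map: dict
    fs: float
    n_segments: int


def _read_bonn_file(path: Path, strict: bool = True) -> np.ndarray:
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                values.append(float(line))
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric sample {line!r}") from exc
    x = np.asarray(values)
    if strict and x.size != BONN_SAMPLES:
        raise ValueError(
            f"{path}: expected {BONN_SAMPLES} samples, found {x.size} "
            "(pass strict_lengths=False to accept)")
    return x


def _bonn_subset_of(path: Path, root: Path) -> str | None:
    """Infer the subset letter from the parent directory or filename prefix."""
    for part in path.relative_to(root).parts[:-1]:
        letter = part[:1].upper()
        if letter in _BONN_CLASS:
            return letter
    letter = path.name[:1].upper()
    return letter if letter in _BONN_CLASS else None


def load_bonn(root: str | Path, strict_lengths: bool = True) -> list[RawSegment]:
    """Load every Z/O/N/F/S(/E) text file under ``root`` as a RawSegment."""
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"Bonn root {root} is not a directory")
    segments = []
    for path in sorted(root.rglob("*")):
        if not path.is_file() or path.suffix.lower() not in ("", ".txt", ".dat"):
            continue
        subset = _bonn_subset_of(path, root)
        if subset is None:
            continue
        samples = _read_bonn_file(path, strict=strict_lengths)
        segments.append(RawSegment(samples, BONN_FS, _BONN_CLASS[subset],
                                   source_id=str(path.relative_to(root))))
    if not segments:
        raise FileNotFoundError(f"no Bonn-layout files found under {root}")
    return segments


def _delhi_class_of(dirname: str) -> str | None:
    name = dirname.lower().replace("-", "").replace("_", "").replace(" ", "")
    if name.startswith("preictal"):
        return "preictal"
    if name.startswith("interictal"):
        return "interictal"
    if name.startswith("ictal"):
        return "ictal"
    return None


def _read_mat_signal(path: Path) -> np.ndarray:
    contents = loadmat(path)
    arrays = {k: np.asarray(v).squeeze() for k, v in contents.items()
              if not k.startswith("__") and np.asarray(v).size > 1}
    if len(arrays) != 1:
        raise ValueError(
            f"{path}: expected exactly one signal array, found "
            f"{sorted(arrays) or 'none'}")
    return next(iter(arrays.values())).astype(float).ravel()


def load_delhi(root: str | Path,
               classes: Iterable[str] = ("interictal", "ictal")) -> list[RawSegment]:
    """Load New Delhi MAT recordings for the requested class folders."""
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"New Delhi root {root} is not a directory")
    wanted = set(classes)
    unknown = wanted - {"preictal", "interictal", "ictal"}
    if unknown:
        raise ValueError(f"unknown classes {sorted(unknown)}")
    segments = []
    for sub in sorted(root.iterdir()):
        if not sub.is_dir():
            continue
        cls = _delhi_class_of(sub.name)
        if cls is None or cls not in wanted:
            continue
        for path in sorted(sub.rglob("*.mat")):
            samples = _read_mat_signal(path)
            segments.append(RawSegment(samples, DELHI_FS, cls,
                                       source_id=str(path.relative_to(root))))
    if not segments:
        raise FileNotFoundError(
            f"no MAT files for classes {sorted(wanted)} under {root}")
    return segments


# sliding a 356-sample window with hop 334 covers a 1024-sample New Delhi
# recording in 3 windows with near-full coverage and no resampling
DELHI_HOP = 334


def windows_from_manifest(segments: Sequence[RawSegment], window_len: int,
                          hop: int) -> list[EEGWindow]:
    """Window every segment; all segments must share one sampling rate."""
    if not segments:
        raise ValueError("no segments to window")
    rates = {round(s.fs, 6) for s in segments}
    if len(rates) > 1:
        raise ValueError(f"mixed sampling rates {sorted(rates)}")
    windows: list[EEGWindow] = []
    for seg in segments:
        windows.extend(slice_windows(seg, window_len, hop))
    return windows


def manifest_for(layout: str, root: str | Path,
                 segments: Sequence[RawSegment]) -> DatasetManifest:
    fs = BONN_FS if layout == "bonn" else DELHI_FS
    class_map = ({k: (0 if v == "interictal" else 1)
                  for k, v in _BONN_CLASS.items()} if layout == "bonn"
                 else {"interictal": 0, "ictal": 1})
    return DatasetManifest(layout, Path(root), class_map, fs, len(segments))
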