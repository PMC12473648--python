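"""Assemble per-pair motion vectors into fixed-length 6xN windows and derive
binary labels from fall-interval annotations."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .gloria_core import N_GENERATORS, MotionParameters
from .synthetic_scenes import MotionWindow

DEFAULT_WINDOW_LENGTH = 150
DEFAULT_MIN_OVERLAP = 8


@dataclass
class FallAnnotation:
    """Fall intervals as 0-based half-open (start_frame, end_frame) pairs."""

    intervals: list[tuple[int, int]]

    def __post_init__(self) -> None:
        iv = [(int(s), int(e)) for s, e in self.intervals]
        for s, e in iv:
            if s >= e:
                raise ValueError(f"interval ({s}, {e}) must have start < end")
        for (s1, e1), (s2, e2) in zip(iv, iv[1:]):
            if s2 < e1:
                raise ValueError("intervals must be sorted and non-overlapping")
        self.intervals = iv


def _to_array(seq) -> np.ndarray:
    if len(seq) and isinstance(seq[0], MotionParameters):
        arr = np.stack([m.a for m in seq], axis=0)
    else:
        arr = np.asarray(seq, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != N_GENERATORS:
        raise ValueError("motion sequence must be T x 6")
    return arr


def make_windows(
    seq: Sequence[MotionParameters] | np.ndarray,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    stride: Optional[int] = None,
) -> list[MotionWindow]:
    """Slice a motion sequence into 6xN windows.

    Stride defaults to the window length (non-overlapping subdivisions); any
    trailing remainder shorter than one window is dropped.  Window contents
    are exact slices — no interpolation or resampling.
    """
    arr = _to_array(seq)
    if stride is None:
        stride = window_length
    if window_length < 16:
        raise ValueError("window_length must be >= 16")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    n = arr.shape[0]
    if n < window_length:
        raise ValueError(f"sequence length {n} shorter than one window ({window_length})")
    starts = range(0, n - window_length + 1, stride)
    return [
        MotionWindow(values=arr[s : s + window_length].T, start_frame=s) for s in starts
    ]


def label_windows(
    windows: Sequence[MotionWindow],
    annotation: FallAnnotation,
    min_overlap_frames: int = DEFAULT_MIN_OVERLAP,
) -> list[MotionWindow]:
    """Label a window as fall iff its frame span overlaps any fall interval
    by at least ``min_overlap_frames`` frames."""
    out = []
    for w in windows:
        span = (w.start_frame, w.start_frame + w.values.shape[1])
        overlap = 0
        for s, e in annotation.intervals:
            overlap = max(overlap, min(span[1], e) - max(span[0], s))
        out.append(
            MotionWindow(
                values=w.values,
                start_frame=w.start_frame,
                label=int(overlap >= min_overlap_frames),
            )
        )
    return out


@dataclass
class ChannelStats:
    """Per-channel mean/std computed on a training set (leakage guard)."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64).reshape(N_GENERATORS)
        self.std = np.asarray(self.std, dtype=np.float64).reshape(N_GENERATORS)


def compute_stats(windows: Sequence[MotionWindow]) -> ChannelStats:
    stacked = np.concatenate([w.values for w in windows], axis=1)
    return ChannelStats(mean=stacked.mean(axis=1), std=stacked.std(axis=1))


def normalize_windows(
    windows: Sequence[MotionWindow],
    method: str = "per_channel_z",
    stats: Optional[ChannelStats] = None,
) -> list[MotionWindow]:
    """Standardize windows using *training-set* statistics only.

    ``per_channel_z``: (x - mean_c) / std_c per channel; ``global_scale``:
    divide everything by the largest channel std; ``none``: identity.
    """
    if method == "none":
        return list(windows)
    if stats is None:
        raise ValueError("training-set stats required unless method='none'")
    if method == "per_channel_z":
        if np.any(stats.std == 0):
            bad = [i for i, s in enumerate(stats.std) if s == 0]
            raise ValueError(f"zero std in channel(s) {bad}; cannot standardize")
        return [
            MotionWindow(
                values=(w.values - stats.mean[:, None]) / stats.std[:, None],
                start_frame=w.start_frame,
                label=w.label,
            )
            for w in windows
        ]
    if method == "global_scale":
        scale = float(stats.std.max())
        if scale == 0:
            raise ValueError("all channels constant; cannot scale")
        return [
            MotionWindow(values=w.values / scale, start_frame=w.start_frame, label=w.label)
            for w in windows
        ]
    raise ValueError(f"unknown normalization method {method!r}")
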