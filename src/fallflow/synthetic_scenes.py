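"""Synthetic textured scenes with known global motion, and labeled motion
windows, so every downstream stage is testable without external video data.

Two generators live here:

* image-space: seeded smooth textures warped frame-to-frame by a known
  schedule of six-parameter motions (ground truth for the solver);
* feature-space: labeled 6xN motion windows where positives carry one
  abrupt high-magnitude transient on all six channels over a smooth
  low-amplitude background, mimicking the signature of a fall.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d, map_coordinates

from .gloria_core import (
    N_GENERATORS,
    GeneratorBasis,
    MotionParameters,
    as_frame,
    make_generator_basis,
)

_BOUNDARY_MODES = {"reflect": "reflect", "wrap": "grid-wrap", "constant": "constant"}


@dataclass
class SyntheticSceneSpec:
    """A textured scene plus a per-step ground-truth motion schedule."""

    width: int = 64
    height: int = 64
    n_channels: int = 1
    texture_seed: int = 0
    texture_smoothness: float = 2.0
    schedule: Sequence[MotionParameters] = field(default_factory=list)
    noise_sigma: float = 0.0
    boundary_mode: Literal["reflect", "wrap", "constant"] = "reflect"

    def __post_init__(self) -> None:
        if self.width < 16 or self.height < 16:
            raise ValueError("scene must be at least 16x16")
        if self.n_channels not in (1, 3):
            raise ValueError("n_channels must be 1 or 3")
        if self.texture_smoothness <= 0:
            raise ValueError("texture_smoothness must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.boundary_mode not in _BOUNDARY_MODES:
            raise ValueError(f"unknown boundary_mode {self.boundary_mode!r}")


@dataclass
class TransientSpec:
    """Shape of the injected fall-like burst."""

    amplitude: float = 10.0  # in units of background std
    duration: int = 8
    onset: Literal["uniform"] = "uniform"


@dataclass
class MotionDatasetSpec:
    """Labeled 6xN window dataset: smooth background, optional transient."""

    n_windows: int = 100
    window_length: int = 150
    fall_fraction: float = 0.5
    fall_transient: TransientSpec = field(default_factory=TransientSpec)
    background_amplitude: float = 1.0
    background_correlation: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fall_fraction <= 1.0:
            raise ValueError("fall_fraction must be in [0, 1]")
        if self.fall_transient.duration >= self.window_length:
            raise ValueError("transient duration must be shorter than the window")
        if self.n_windows < 1:
            raise ValueError("need at least one window")


def render_texture(spec: SyntheticSceneSpec) -> np.ndarray:
    """Seeded smooth texture in [0, 1] with rich gradients almost everywhere.

    White noise blurred with a Gaussian of sigma ``texture_smoothness`` and
    recentered around 0.5; in the infinite-smoothness limit the frame tends
    to a constant, so the contrast is a direct function of the blur scale.
    """
    rng = np.random.default_rng(spec.texture_seed)
    noise = rng.standard_normal((spec.height, spec.width, spec.n_channels))
    tex = gaussian_filter(
        noise, sigma=(spec.texture_smoothness, spec.texture_smoothness, 0.0), mode="wrap"
    )
    tex = 0.5 + 2.0 * (tex - tex.mean(axis=(0, 1), keepdims=True))
    return np.clip(tex, 0.0, 1.0)


def warp_frame(
    frame: np.ndarray,
    params: MotionParameters | np.ndarray,
    boundary_mode: str = "reflect",
    basis: Optional[GeneratorBasis] = None,
) -> np.ndarray:
    """Apply the global flow of a six-parameter vector as a small displacement.

    The output is the input resampled (bilinear) at positions displaced by
    -v(x, y), so scene content moves by +v.  The generator basis defaults to
    the solver's convention (centered, normalized coordinates), which keeps
    warp amplitudes and recovered amplitudes in the same units.
    """
    f = as_frame(frame)
    a = params.a if isinstance(params, MotionParameters) else np.asarray(params, float)
    if boundary_mode not in _BOUNDARY_MODES:
        raise ValueError(f"unknown boundary_mode {boundary_mode!r}")
    if basis is None:
        basis = make_generator_basis(f.shape[0], f.shape[1])
    dx, dy = basis.displacement(a)
    ys, xs = np.mgrid[0 : f.shape[0], 0 : f.shape[1]].astype(np.float64)
    coords = np.stack([ys - dy, xs - dx])
    out = np.empty_like(f)
    for c in range(f.shape[2]):
        out[:, :, c] = map_coordinates(
            f[:, :, c], coords, order=1, mode=_BOUNDARY_MODES[boundary_mode], cval=0.0
        )
    return out


def render_sequence(
    spec: SyntheticSceneSpec,
) -> tuple[list[np.ndarray], list[MotionParameters]]:
    """Roll the schedule forward: frames[t+1] = warp(frames[t]) + noise.

    Returns len(schedule)+1 frames and the schedule itself as ground truth
    (no hidden rescaling).  Errors out if accumulated translation would push
    the whole texture out of frame.
    """
    if len(spec.schedule) < 1:
        raise ValueError("schedule must contain at least one step")
    basis = make_generator_basis(spec.height, spec.width)
    schedule = [
        p if isinstance(p, MotionParameters) else MotionParameters(a=np.asarray(p, float))
        for p in spec.schedule
    ]
    cum_tx = float(np.sum(np.abs([p.a[0] for p in schedule])))
    cum_ty = float(np.sum(np.abs([p.a[1] for p in schedule])))
    if cum_tx > spec.width or cum_ty > spec.height:
        raise ValueError("cumulative translation exceeds the frame extent")

    noise_rng = np.random.default_rng([spec.texture_seed, 0xF0F0])
    frames = [render_texture(spec)]
    for step in schedule:
        nxt = warp_frame(frames[-1], step, boundary_mode=spec.boundary_mode, basis=basis)
        if spec.noise_sigma > 0:
            nxt = nxt + spec.noise_sigma * noise_rng.standard_normal(nxt.shape)
        frames.append(nxt)
    return frames, schedule


@dataclass
class MotionWindow:
    """A 6xN slab of consecutive motion vectors with an optional label."""

    values: np.ndarray
    start_frame: int = 0
    label: Optional[int] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != N_GENERATORS:
            raise ValueError("window values must be 6xN")
        if self.values.shape[1] < 16:
            raise ValueError("window length must be >= 16")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("window contains non-finite values")


def _smooth_background(rng: np.random.Generator, spec: MotionDatasetSpec) -> np.ndarray:
    noise = rng.standard_normal((N_GENERATORS, spec.window_length))
    bg = gaussian_filter1d(noise, sigma=spec.background_correlation, axis=1, mode="wrap")
    # renormalize so the background std equals background_amplitude
    bg_std = bg.std()
    if bg_std > 0:
        bg = bg * (spec.background_amplitude / bg_std)
    return bg


def transient_profile(length: int) -> np.ndarray:
    """Half-sine burst envelope of the given length, peak 1."""
    return np.sin(np.pi * (np.arange(length) + 0.5) / length)


def simulate_motion_dataset(
    spec: MotionDatasetSpec,
) -> tuple[list[MotionWindow], np.ndarray]:
    """Labeled window set: positives carry one simultaneous six-channel burst.

    Exactly ``round(fall_fraction * n_windows)`` positives; transients are
    contained entirely within their window (no boundary-spanning events).
    """
    rng = np.random.default_rng(spec.seed)
    n_pos = int(round(spec.fall_fraction * spec.n_windows))
    labels = np.zeros(spec.n_windows, dtype=np.int64)
    labels[:n_pos] = 1
    rng.shuffle(labels)

    tr = spec.fall_transient
    amp = tr.amplitude * spec.background_amplitude
    profile = transient_profile(tr.duration)

    windows: list[MotionWindow] = []
    for i in range(spec.n_windows):
        vals = _smooth_background(rng, spec)
        if labels[i] == 1:
            onset = int(rng.integers(0, spec.window_length - tr.duration + 1))
            signs = rng.choice([-1.0, 1.0], size=N_GENERATORS)
            vals[:, onset : onset + tr.duration] += (
                amp * signs[:, np.newaxis] * profile[np.newaxis, :]
            )
        windows.append(MotionWindow(values=vals, start_frame=0, label=int(labels[i])))
    return windows, labels


def export_frames_png(frames: Sequence[np.ndarray], directory) -> list[str]:
    """Write frames as zero-padded 8-bit PNGs; returns the file paths."""
    import os

    import imageio.v3 as iio

    os.makedirs(directory, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        f = np.clip(as_frame(frame), 0.0, 1.0)
        img = (f * 255.0 + 0.5).astype(np.uint8)
        if img.shape[2] == 1:
            img = img[:, :, 0]
        path = os.path.join(directory, f"frame_{i:06d}.png")
        iio.imwrite(path, img)
        paths.append(path)
    return paths


def export_windows_csv(windows: Sequence[MotionWindow], path) -> None:
    """One row per window: label then the 6xN values in row-major order."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for w in windows:
            label = -1 if w.label is None else int(w.label)
            writer.writerow([label] + [format(v, ".17g") for v in w.values.ravel()])


def import_windows_csv(path) -> tuple[list[MotionWindow], np.ndarray]:
    """Inverse of :func:`export_windows_csv` (label -1 means unlabeled)."""
    import csv

    windows: list[MotionWindow] = []
    labels = []
    with open(path) as fh:
        for row in csv.reader(fh):
            if not row:
                continue
            label = int(row[0])
            vals = np.array([float(v) for v in row[1:]], dtype=np.float64)
            if vals.size % N_GENERATORS:
                raise ValueError("window row length not divisible by 6")
            vals = vals.reshape(N_GENERATORS, -1)
            windows.append(
                MotionWindow(values=vals, label=None if label < 0 else label)
            )
            labels.append(label)
    return windows, np.asarray(labels, dtype=np.int64)
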