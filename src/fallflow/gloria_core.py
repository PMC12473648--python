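"""Direct reconstruction of global motion parameters from frame pairs.

Instead of recovering a dense optical-flow field, the motion between two
consecutive frames is projected onto the six generators of the 2-D linear
non-homogeneous transformation group (translation x/y, dilation, rotation,
two shears).  Under brightness constancy the temporal derivative relates to
the flow field through ``dL/dt = -v . grad(L)``; restricting ``v`` to the
span of the six generator fields turns parameter recovery into a 6x6
least-squares problem whose normal equations are built from a generalized
structural tensor (Gram matrix of generator-projected gradients) and a
driving vector (correlation of the temporal derivative with the projected
gradients).

All channels of a multi-channel frame contribute to the same 6x6 system, so
color input tightens the solve rather than being averaged away.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

GENERATOR_NAMES = (
    "translation_x",
    "translation_y",
    "dilation",
    "rotation",
    "shear1",
    "shear2",
)

N_GENERATORS = 6


def as_frame(pixels: np.ndarray) -> np.ndarray:
    """Validate and canonicalize a frame to float64 H x W x Nc."""
    a = np.asarray(pixels, dtype=np.float64)
    if a.ndim == 2:
        a = a[:, :, np.newaxis]
    if a.ndim != 3:
        raise ValueError(f"frame must be HxW or HxWxNc, got ndim={a.ndim}")
    h, w, _ = a.shape
    if h < 8 or w < 8:
        raise ValueError(f"frame too small: {h}x{w}, need at least 8x8")
    if not np.all(np.isfinite(a)):
        raise ValueError("frame contains non-finite values")
    return a


@dataclass
class GradientField:
    """Spatial and temporal derivatives for one frame pair (H x W x Nc each)."""

    gx: np.ndarray
    gy: np.ndarray
    gt: np.ndarray

    def __post_init__(self) -> None:
        if not (self.gx.shape == self.gy.shape == self.gt.shape):
            raise ValueError("gradient component shapes differ")


@dataclass
class GeneratorBasis:
    """The six generator vector fields evaluated on a pixel grid.

    ``vx``/``vy`` have shape (6, H, W) in the order of :data:`GENERATOR_NAMES`.
    ``origin`` and ``scale`` record the coordinate convention so that warping
    and solving agree on units: translations are always in pixels/frame, the
    remaining rates are per frame in the (possibly normalized) coordinates.
    """

    vx: np.ndarray
    vy: np.ndarray
    origin: str
    scale: str
    coord_scale: float

    @property
    def height(self) -> int:
        return self.vx.shape[1]

    @property
    def width(self) -> int:
        return self.vx.shape[2]

    def displacement(self, params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-unit flow field (dx, dy) for a 6-vector of amplitudes."""
        a = np.asarray(params, dtype=np.float64).reshape(N_GENERATORS)
        dx = np.tensordot(a, self.vx, axes=(0, 0))
        dy = np.tensordot(a, self.vy, axes=(0, 0))
        return dx, dy


@dataclass
class MotionParameters:
    """Six global motion rates for one frame pair plus solver diagnostics."""

    a: np.ndarray = field(default_factory=lambda: np.zeros(N_GENERATORS))
    condition_number: float = 1.0
    residual_rms: float = 0.0
    degenerate_flag: bool = False

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.float64).reshape(N_GENERATORS)

    def as_dict(self) -> dict:
        d = {name: float(v) for name, v in zip(GENERATOR_NAMES, self.a)}
        d.update(
            condition_number=float(self.condition_number),
            residual_rms=float(self.residual_rms),
            degenerate=bool(self.degenerate_flag),
        )
        return d


@dataclass
class NormalSystem:
    """The 6x6 normal equations ``S a = H`` plus residual bookkeeping.

    ``gt_sq_sum`` and ``n_terms`` carry enough information to evaluate the
    RMS of the linearized brightness-constancy residual at the solution
    without re-touching the pixel grids.
    """

    S: np.ndarray
    H: np.ndarray
    gt_sq_sum: float = 0.0
    n_terms: int = 1

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=np.float64)
        self.H = np.asarray(self.H, dtype=np.float64).reshape(N_GENERATORS)
        if self.S.shape != (N_GENERATORS, N_GENERATORS):
            raise ValueError("S must be 6x6")


@dataclass
class GloriaConfig:
    """Settings for the frame-pair parameter solve."""

    smooth_sigma: float = 1.0
    origin: Literal["center", "corner"] = "center"
    scale: Literal["pixels", "normalized"] = "normalized"
    reg_epsilon: float = 1e-6
    cond_limit: float = 1e8


def spatial_gradients(
    frame_a: np.ndarray, frame_b: np.ndarray, smooth_sigma: float = 1.0
) -> GradientField:
    """Central-difference spatial gradients of the two-frame average and the
    forward temporal difference, per channel.

    Both frames are optionally Gaussian pre-smoothed (``smooth_sigma`` in
    pixels, 0 disables).  Border values use one-sided differences and are
    excluded later when the normal system is assembled.
    """
    a = as_frame(frame_a)
    b = as_frame(frame_b)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    if smooth_sigma > 0:
        sig = (smooth_sigma, smooth_sigma, 0.0)
        a = gaussian_filter(a, sigma=sig, mode="nearest")
        b = gaussian_filter(b, sigma=sig, mode="nearest")
    avg = 0.5 * (a + b)
    gy, gx = np.gradient(avg, axis=(0, 1))
    gt = b - a
    return GradientField(gx=gx, gy=gy, gt=gt)


def make_generator_basis(
    height: int,
    width: int,
    origin: Literal["center", "corner"] = "center",
    scale: Literal["pixels", "normalized"] = "normalized",
) -> GeneratorBasis:
    """Evaluate the six generator fields on an H x W grid.

    With ``origin='center'`` coordinates are measured from the frame center;
    ``scale='normalized'`` divides them by max(H, W)/2 so the non-translation
    amplitudes are resolution-independent rates.  Translation fields are unit
    vectors regardless of the convention.
    """
    if height < 8 or width < 8:
        raise ValueError("grid must be at least 8x8")
    ys, xs = np.mgrid[0:height, 0:width].astype(np.float64)
    if origin == "center":
        xs -= (width - 1) / 2.0
        ys -= (height - 1) / 2.0
    elif origin != "corner":
        raise ValueError(f"unknown origin {origin!r}")
    if scale == "normalized":
        coord_scale = max(height, width) / 2.0
        xs = xs / coord_scale
        ys = ys / coord_scale
    elif scale == "pixels":
        coord_scale = 1.0
    else:
        raise ValueError(f"unknown scale {scale!r}")

    one = np.ones((height, width))
    zero = np.zeros((height, width))
    # translation (1,0)/(0,1); dilation (x,y); rotation (y,-x);
    # shear1 = symmetric shear (y,x); shear2 = anisotropic stretch (x,-y).
    # Together with the translations these six fields are linearly
    # independent and span the full 2-D linear non-homogeneous group, so the
    # structural tensor is generically invertible.  (The naive pair
    # (0,x)/(y,0) would satisfy rotation = shear2 - shear1 identically and
    # force a singular system.)
    vx = np.stack([one, zero, xs, ys, ys, xs])
    vy = np.stack([zero, one, ys, -xs, xs, -ys])
    return GeneratorBasis(vx=vx, vy=vy, origin=origin, scale=scale, coord_scale=coord_scale)


def assemble_normal_system(grads: GradientField, basis: GeneratorBasis) -> NormalSystem:
    """Build the 6x6 Gram system over interior pixels and all channels.

    ``S_uv = sum (G_u L)(G_v L)`` and ``H_u = -sum (dL/dt)(G_u L)`` where
    ``G_u L = v^u_x gx + v^u_y gy`` is the generator-projected gradient.
    """
    h, w, nc = grads.gx.shape
    if (basis.height, basis.width) != (h, w):
        raise ValueError(
            f"basis grid {basis.height}x{basis.width} does not match gradients {h}x{w}"
        )
    sl = np.s_[1 : h - 1, 1 : w - 1]
    gx = grads.gx[sl]
    gy = grads.gy[sl]
    gt = grads.gt[sl]
    # (6, h-2, w-2, nc) projected gradients
    proj = (
        basis.vx[(slice(None),) + sl][..., np.newaxis] * gx[np.newaxis]
        + basis.vy[(slice(None),) + sl][..., np.newaxis] * gy[np.newaxis]
    )
    flat = proj.reshape(N_GENERATORS, -1)
    S = flat @ flat.T
    S = 0.5 * (S + S.T)  # enforce exact symmetry against round-off
    H = -(flat @ gt.reshape(-1))
    return NormalSystem(S=S, H=H, gt_sq_sum=float(np.sum(gt * gt)), n_terms=gt.size)


def solve_motion(
    system: NormalSystem, reg_epsilon: float = 1e-6, cond_limit: float = 1e8
) -> MotionParameters:
    """Solve the normal equations with graceful handling of degeneracy.

    Tikhonov damping ``lambda = reg_epsilon * trace(S)/6`` is engaged only
    when the condition number exceeds ``cond_limit``.  A structureless image
    (trace(S) = 0) yields a zero vector with ``degenerate_flag`` set instead
    of an error: velocities along directions of constant intensity are
    arbitrary, so there is nothing meaningful to solve for.
    """
    S, H = system.S, system.H
    if not np.all(np.isfinite(S)) or not np.all(np.isfinite(H)):
        raise ValueError("normal system contains non-finite values")
    if not np.allclose(S, S.T, rtol=0, atol=1e-8 * max(1.0, float(np.abs(S).max()))):
        raise ValueError("structural tensor is not symmetric")

    trace = float(np.trace(S))
    if trace <= 0.0:
        return MotionParameters(
            a=np.zeros(N_GENERATORS),
            condition_number=np.inf,
            residual_rms=float(np.sqrt(system.gt_sq_sum / system.n_terms)),
            degenerate_flag=True,
        )

    eigvals = np.linalg.eigvalsh(S)
    lam_max = float(eigvals[-1])
    lam_min = float(eigvals[0])
    cond = np.inf if lam_min <= 0 else lam_max / lam_min

    S_eff = S
    if cond > cond_limit:
        S_eff = S + (reg_epsilon * trace / N_GENERATORS) * np.eye(N_GENERATORS)
        a = np.linalg.solve(S_eff, H)
    else:
        a = np.linalg.solve(S, H)

    # residual of the linearized constraint at the solution, via the
    # expanded quadratic form sum(gt + sum_u a_u G_u L)^2
    sq = system.gt_sq_sum - 2.0 * float(a @ H) + float(a @ S @ a)
    sq = max(sq, 0.0)
    return MotionParameters(
        a=a,
        condition_number=max(cond, 1.0),
        residual_rms=float(np.sqrt(sq / system.n_terms)),
        degenerate_flag=False,
    )


def estimate_motion(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    config: GloriaConfig | None = None,
    basis: GeneratorBasis | None = None,
) -> MotionParameters:
    """Full per-pair solve: gradients -> normal system -> parameters."""
    config = config or GloriaConfig()
    a = as_frame(frame_a)
    b = as_frame(frame_b)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    if basis is None:
        basis = make_generator_basis(
            a.shape[0], a.shape[1], origin=config.origin, scale=config.scale
        )
    grads = spatial_gradients(a, b, smooth_sigma=config.smooth_sigma)
    system = assemble_normal_system(grads, basis)
    return solve_motion(system, reg_epsilon=config.reg_epsilon, cond_limit=config.cond_limit)


def motion_sequence(
    frames: Sequence[np.ndarray], config: GloriaConfig | None = None
) -> list[MotionParameters]:
    """One MotionParameters per consecutive frame pair, order preserved."""
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    config = config or GloriaConfig()
    first = as_frame(frames[0])
    basis = make_generator_basis(
        first.shape[0], first.shape[1], origin=config.origin, scale=config.scale
    )
    out: list[MotionParameters] = []
    prev = first
    for i in range(1, len(frames)):
        cur = as_frame(frames[i])
        if cur.shape != prev.shape:
            raise ValueError(
                f"frame {i} shape {cur.shape} differs from frame {i - 1} shape {prev.shape}"
            )
        out.append(estimate_motion(prev, cur, config=config, basis=basis))
        prev = cur
    return out


def motion_array(seq: Sequence[MotionParameters]) -> np.ndarray:
    """Stack a motion sequence into a (T, 6) array."""
    return np.stack([m.a for m in seq], axis=0)
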